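abbrev	tissue	name
cr	bone	cranium
md	bone	mandible
C1	bone	cervical vertebra 1
C2	bone	cervical vertebra 2
C3	bone	cervical vertebra 3
C4	bone	cervical vertebra 4
C5	bone	cervical vertebra 5
C6	bone	cervical vertebra 6
C7	bone	cervical vertebra 7
C8	bone	cervical vertebra 8
C9	bone	cervical vertebra 9
ts	bone	thoracic spine
ri	bone	ribs
st	bone	sternum
hy	bone	hyoid
sc	bone	scapula
cl	bone	clavicle
hu	bone	humerus
ty	other	thyroid cartilage
ln	ligament	nuchal ligament
asd	muscle	atlantoscapularis dorsalis
asv	muscle	atlantoscapularis ventralis
bc	muscle	biventer cervicis
cal	muscle	longus capitis
cc	muscle	cleidocervicalis
cm	muscle	cleidomastoideus
co	muscle	cleidooccipitalis
col	muscle	longus colli
cx	muscle	complexus
icc	muscle	iliocostalis cervicis
id	muscle	intertransversarii cervicis dorsales
im	muscle	intertransversarii cervicis mediales
is	muscle	interspinalis
iv	muscle	intertransversarii cervicis ventrales
lat	muscle	longus atlantis
lca	muscle	longissimus capitis
lce	muscle	longissimus cervicis
m	muscle	multifidi
oca	muscle	obliquus capitis caudalis
ocr	muscle	obliquus capitis cranialis
oh	muscle	omohyoideus
rca	muscle	rhomboideus capitis
rce	muscle	rhomboideus cervicis
rci	muscle	rectus capitis dorsalis intermedius
rh	muscle	rhomboideus
rl	muscle	rectus capitis lateralis
rma	muscle	rectus capitis dorsalis major
rmi	muscle	rectus capitis dorsalis minor
rv	muscle	rectus capitis ventralis
sce	muscle	spinalis cervicis
scm	muscle	sternocleidomastoideus
sd	muscle	scalenus dorsalis
sh	muscle	sternohyoideus
sm	muscle	scalenus medius
so	muscle	sternooccipitalis
sp	muscle	splenius
spca	muscle	splenius capitis
spce	muscle	splenius cervicis
ssca	muscle	semispinalis capitis
ssce	muscle	semispinalis cervicis
sth	muscle	sternothyroideus
stm	muscle	sternomastoideus
stx	muscle	sternomaxillaris
svc	muscle	serratus ventralis cervicis
sv	muscle	scalenus ventralis
tr	muscle	trapezius
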