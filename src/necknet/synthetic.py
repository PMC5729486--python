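"""Synthetic neck networks, calibrated trees and simulated trait matrices.

The network generator emulates the composition of mammalian neck
musculoskeletal networks: a serial bone backbone (cranium - C1..Cn -
thoracic spine) with girdle, ventral and accessory bones, plus bilateral
muscles attaching to 2-10 elements.  Fidelity is statistical -- the
default template produces node and link counts inside the empirically
observed ranges (N roughly 84-130, K roughly 219-397) -- not anatomical
truth for any particular species.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from .io import AnatomicalNetwork, NetworkValidationWarning, infer_node_metadata
from .trees import PhyloTree

__all__ = [
    "MuscleSpec",
    "NeckTemplate",
    "default_muscles",
    "generate_network",
    "generate_tree",
    "simulate_traits",
]


@dataclass(frozen=True)
class MuscleSpec:
    """One muscle of the blueprint.

    ``attachments`` lists element tokens: midline bones by abbreviation
    ('cr', 'st', 'ts', ...), cervical vertebrae as 'C3', and bilateral
    bones ('sc', 'cl', 'hu', 'ri') which resolve to the muscle's own side.
    """

    name: str
    attachments: tuple[str, ...]
    bilateral: bool = True
    presence: float = 1.0  # probability the species has this muscle


def _crange(lo: int, hi: int) -> tuple[str, ...]:
    return tuple(f"C{i}" for i in range(lo, hi + 1))


def default_muscles(n_cervical: int = 7) -> list[MuscleSpec]:
    """The default ~40-muscle blueprint, adapted to the vertebral count."""
    n = n_cervical
    mid = (n + 1) // 2  # mid/lower cervical boundary
    core = [
        # suboccipital / craniovertebral (cranio-pectoral region)
        MuscleSpec("rmi", ("cr", "C1")),
        MuscleSpec("rma", ("cr", "C2")),
        MuscleSpec("oca", ("C1", "C2")),
        MuscleSpec("ocr", ("cr", "C1")),
        MuscleSpec("cal", ("cr",) + _crange(1, min(3, n))),
        MuscleSpec("spca", ("cr", "C1", "ln", "ts")),
        # mid-cervical tract
        MuscleSpec("col", _crange(2, mid + 2) + ("ts",)),
        MuscleSpec("sce", _crange(2, mid + 1)),
        # lower-cervical tract
        MuscleSpec("lce", _crange(mid + 1, n) + ("ts",)),
        MuscleSpec("ssce", _crange(mid + 1, n) + ("ts",)),
        # thoracic / dorsal tract (attaches via thoracic spine and
        # nuchal ligament, not segmentally to the cervicals)
        MuscleSpec("bc", ("cr", "ln", "ts")),
        MuscleSpec("cx", ("cr", "ln", "ts")),
        MuscleSpec("lca", ("cr", "ts") + _crange(n - 1, n)),
        MuscleSpec("tr", ("cr", "ln", "ts", "sc")),
        MuscleSpec("rce", ("ln", "ts", "sc")),
        # girdle
        MuscleSpec("rca", ("cr", "sc")),
        MuscleSpec("asd", ("C1", "sc")),
        MuscleSpec("oh", ("sc", "hy")),
        MuscleSpec("svc", _crange(3, n) + ("sc",)),
        # ventral strap
        MuscleSpec("stm", ("st", "cr")),
        MuscleSpec("sh", ("st", "hy")),
        MuscleSpec("sth", ("st", "ty")),
        # scalenes (rib-anchored, ventral region)
        MuscleSpec("sd", ("ri", "st") + _crange(n - 2, n)),
        MuscleSpec("sv", ("ri", "st") + _crange(n - 1, n)),
        MuscleSpec("sm", ("ri",) + _crange(max(2, n - 4), n)),
    ]
    optional = [
        MuscleSpec("rci", ("cr", "C1", "C2"), presence=0.5),
        MuscleSpec("rl", ("cr", "C1"), presence=0.4),
        MuscleSpec("rv", ("cr", "C1"), presence=0.4),
        MuscleSpec("lat", _crange(1, min(3, n)), presence=0.5),
        MuscleSpec("icc", _crange(mid + 1, n) + ("ri",), presence=0.5),
        MuscleSpec("spce", ("ln",) + _crange(1, min(3, n)), presence=0.5),
        MuscleSpec("ssca", ("cr", "ln", "ts"), presence=0.5),
        MuscleSpec("so", ("st", "cr"), presence=0.5),
        MuscleSpec("asv", ("C1", "sc"), presence=0.4),
    ]
    serial = (
        [MuscleSpec(f"is{i}", (f"C{i}", f"C{i + 1}")) for i in range(1, n)]
        + [MuscleSpec(f"id{i}", (f"C{i}", f"C{i + 1}"), presence=0.35)
           for i in range(1, n)]
        + [MuscleSpec(f"iv{i}", (f"C{i}", f"C{i + 1}"), presence=0.45)
           for i in range(1, n)]
        + [MuscleSpec(f"m{i}", _crange(i, min(i + 2, n)), presence=0.6)
           for i in range(1, n - 1)]
    )
    return core + optional + serial


@dataclass(frozen=True)
class NeckTemplate:
    """Construction recipe for a synthetic neck network."""

    n_cervical: int = 7
    has_clavicle: bool = True
    has_mandible: bool = True
    has_humerus: bool = False
    has_nuchal_ligament: bool = True
    muscles: tuple[MuscleSpec, ...] | None = None  # None -> default blueprint
    attachment_noise: float = 0.3  # per-muscle prob. of +/- one vertebral attachment

    def __post_init__(self):
        if not 5 <= self.n_cervical <= 9:
            raise ValueError("n_cervical must be in 5..9")

    def blueprint(self) -> list[MuscleSpec]:
        base = list(self.muscles) if self.muscles is not None else \
            default_muscles(self.n_cervical)
        out = []
        for m in base:
            att = m.attachments
            if not self.has_clavicle and "cl" in att:
                continue
            if not self.has_mandible and "md" in att:
                continue
            if not self.has_humerus and "hu" in att:
                continue
            att = tuple(a for a in att
                        if a != "ln" or self.has_nuchal_ligament)
            if len(att) >= 2:
                out.append(replace(m, attachments=att))
        if self.has_clavicle:
            out += [
                MuscleSpec("cm", ("cr", "cl"), presence=0.7),
                MuscleSpec("co", ("cr", "cl"), presence=0.7),
                MuscleSpec("cc", ("cl",) + _crange(1, min(3, self.n_cervical)),
                           presence=0.7),
            ]
        if self.has_mandible:
            out.append(MuscleSpec("stx", ("st", "md"), presence=0.5))
        return out


def _bones(template: NeckTemplate) -> tuple[list[str], list[tuple[str, str]]]:
    n = template.n_cervical
    mid = ["cr", "hy", "ty", "st", "ts"] + [f"C{i}" for i in range(1, n + 1)]
    if template.has_mandible:
        mid.append("md")
    if template.has_nuchal_ligament:
        mid.append("ln")
    bilateral = ["sc", "ri"]
    if template.has_clavicle:
        bilateral.append("cl")
    if template.has_humerus:
        bilateral.append("hu")
    nodes = mid + [b + s for b in bilateral for s in ("l", "r")]
    chain = ["cr"] + [f"C{i}" for i in range(1, n + 1)] + ["ts"]
    edges = list(zip(chain, chain[1:]))
    edges.append(("hy", "ty"))
    for s in ("l", "r"):
        edges += [("st", "ri" + s), ("ts", "ri" + s)]
        if template.has_clavicle:
            edges += [("cl" + s, "sc" + s), ("cl" + s, "st")]
        if template.has_humerus:
            edges.append(("sc" + s, "hu" + s))
    if template.has_mandible:
        edges += [("cr", "md"), ("md", "hy")]
    if template.has_nuchal_ligament:
        edges += [("ln", "cr"), ("ln", "ts")]
    return nodes, edges


_BILATERAL_BONES = {"sc", "cl", "hu", "ri"}


def generate_network(
    template: NeckTemplate | None = None,
    seed: int = 0,
    species: str | None = None,
) -> AnatomicalNetwork:
    """Generate one synthetic neck network; reproducible given ``seed``.

    Bilateral muscles get mirrored left/right instances.  The attachment
    noise independently adds or drops one vertebral attachment per muscle
    instance (never below 2 attachments), so the two sides are nearly but
    not perfectly symmetric.  If random pruning ever disconnects the
    graph, stray components are reattached to the backbone with a warning.
    """
    template = template or NeckTemplate()
    rng = np.random.default_rng(seed)
    bone_nodes, bone_edges = _bones(template)
    nodes = list(bone_nodes)
    edges = list(bone_edges)
    n = template.n_cervical

    deterministic = template.attachment_noise == 0
    for spec in template.blueprint():
        # a zero-noise template is fully deterministic: the optional
        # muscles collapse to their majority outcome
        if deterministic:
            if spec.presence < 0.5:
                continue
        elif rng.random() >= spec.presence:
            continue
        sides = ("l", "r") if spec.bilateral else ("",)
        for side in sides:
            label = spec.name + side
            att = [a + side if a in _BILATERAL_BONES and side else a
                   for a in spec.attachments]
            verts = sorted(int(a[1:]) for a in att
                           if a.startswith("C") and a[1:].isdigit())
            if verts and rng.random() < template.attachment_noise:
                if rng.random() < 0.5 and len(att) > 2 and len(verts) > 1:
                    att.remove(f"C{verts[rng.integers(len(verts))]}")
                else:
                    candidates = [v for v in (verts[0] - 1, verts[-1] + 1)
                                  if 1 <= v <= n and f"C{v}" not in att]
                    if candidates:
                        att.append(f"C{int(rng.choice(candidates))}")
            nodes.append(label)
            edges += [(label, a) for a in att]

    node_objs = [infer_node_metadata(v) for v in nodes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NetworkValidationWarning)
        net = AnatomicalNetwork(
            species or f"synthetic_{seed}", node_objs, edges,
            check_connected=False,
        )
    if not net.is_connected():
        import networkx as nx

        comps = sorted(nx.connected_components(net.graph), key=len,
                       reverse=True)
        warnings.warn(
            "generated network was disconnected; reattaching to the backbone",
            NetworkValidationWarning,
            stacklevel=2,
        )
        for comp in comps[1:]:
            edges.append((sorted(comp)[0], "C1"))
        net = AnatomicalNetwork(species or f"synthetic_{seed}", node_objs,
                                edges)
    return net


def generate_tree(n_tips: int, seed: int = 0, root_age: float = 170.0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree rescaled to ``root_age``.

    Tips are labeled sp01, sp02, ...; the default root age matches the
    order of the mammalian crown age in Ma, so branch lengths are in Ma.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    from dendropy.model import birthdeath

    taxa = dendropy.TaxonNamespace(
        [f"sp{i + 1:02d}" for i in range(n_tips)]
    )
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    # the simulator stops at the n-th speciation, leaving zero-length tip
    # branches; extend every tip by one waiting-time draw so the present
    # falls strictly between speciation events (tree stays ultrametric)
    extra = random.Random(seed + 1).expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    scale = root_age / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return PhyloTree(tree)


def simulate_traits(
    tree: PhyloTree,
    model: str = "BM",
    rate=1.0,
    root=0.0,
    n_traits: int = 1,
    alpha: float | None = None,
    r: float | None = None,
    seed: int = 0,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate tip traits under BM, single-optimum OU, or Early burst.

    ``rate`` is the BM rate sigma^2 (scalar, per-trait vector, or a full
    trait covariance matrix); OU needs ``alpha`` > 0, EB needs ``r`` < 0.
    Returns a species x trait DataFrame in tree tip order.
    """
    from .phylo import _eb_transform, _ou_corr

    C = tree.vcv()
    T = float(np.max(np.diag(C)))
    if model == "BM":
        V = C
    elif model == "OU":
        if alpha is None or alpha <= 0:
            raise ValueError("OU requires alpha > 0")
        V = _ou_corr(C, T, alpha)
    elif model == "EB":
        if r is None or r >= 0:
            raise ValueError("EB requires r < 0")
        V = _eb_transform(C, r)
    else:
        raise ValueError(f"unknown model {model!r}")

    R = np.atleast_2d(np.asarray(rate, dtype=float))
    if R.shape == (1, 1):
        R = R[0, 0] * np.eye(n_traits)
    elif R.shape[0] == 1:
        R = np.diag(R[0])
    p = R.shape[0]
    if np.any(np.linalg.eigvalsh(R) < -1e-12) or np.any(np.diag(R) < 0):
        raise ValueError("rate matrix must be positive semi-definite")
    rng = np.random.default_rng(seed)
    Lc = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    w, U = np.linalg.eigh(R)
    Lr = U @ np.diag(np.sqrt(np.clip(w, 0, None)))
    Z = rng.standard_normal((len(V), p))
    X = np.asarray(root, dtype=float) + Lc @ Z @ Lr.T
    cols = names or [f"trait{i + 1}" for i in range(p)]
    return pd.DataFrame(X, index=tree.tip_labels, columns=cols)
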