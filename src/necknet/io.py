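"""Reading, writing and validation of anatomical networks, trees and covariates.

Anatomical networks are undirected simple graphs whose nodes are skeletal
elements (vertebrae, cranium, girdle bones), other passive elements
(ligaments, cartilages) and muscles, and whose links are physical contacts:
bone-bone articulations and muscle attachments.  On disk a network is a
labeled, symmetric 0/1 adjacency matrix; species collections may also be
stored as multi-sheet workbooks with one sheet per species.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AnatomicalNode",
    "AnatomicalNetwork",
    "SpeciesDataset",
    "NetworkValidationWarning",
    "load_vocabulary",
    "infer_node_metadata",
    "read_adjacency_matrix",
    "read_adjacency_workbook",
    "write_adjacency_matrix",
    "read_covariates",
    "read_tree",
]

TISSUES = ("bone", "muscle", "ligament", "other")
SIDES = ("left", "right", "midline")


class NetworkValidationWarning(UserWarning):
    """Raised (as a warning) for recoverable problems in network input."""


@dataclass(frozen=True)
class AnatomicalNode:
    """A single anatomical element.

    ``id`` follows the conventional abbreviation scheme (``C1``..``C9`` for
    cervical vertebrae, ``cr`` cranium, ``scl``/``scr`` left/right scapula,
    muscle abbreviations such as ``trr`` for the right trapezius).  A
    trailing ``l``/``r`` on the label marks the side of bilateral elements.
    """

    id: str
    tissue: str = "muscle"
    side: str = "midline"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} for node {self.id!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r} for node {self.id!r}")


class AnatomicalNetwork:
    """Undirected simple graph of anatomical elements for one species.

    Thin wrapper around :class:`networkx.Graph` carrying the species name and
    per-node tissue/side metadata.  Self-loops and parallel edges are
    rejected; a disconnected network is legal but triggers a validation
    warning because the mean shortest path length is only defined on
    connected graphs.
    """

    def __init__(
        self,
        species: str,
        nodes: Iterable[AnatomicalNode],
        edges: Iterable[tuple[str, str]],
        check_connected: bool = True,
    ):
        self.species = species
        g = nx.Graph()
        for node in nodes:
            if node.id in g:
                raise ValueError(f"duplicate node id {node.id!r}")
            g.add_node(node.id, tissue=node.tissue, side=node.side)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in g or v not in g:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            g.add_edge(u, v)
        self._graph = g
        if check_connected and g.number_of_nodes() and not nx.is_connected(g):
            n_comp = nx.number_connected_components(g)
            warnings.warn(
                f"network {species!r} has {n_comp} connected components",
                NetworkValidationWarning,
                stacklevel=2,
            )

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def nodes(self) -> list[AnatomicalNode]:
        return [
            AnatomicalNode(n, d.get("tissue", "muscle"), d.get("side", "midline"))
            for n, d in sorted(self._graph.nodes(data=True))
        ]

    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._graph.edges()}

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self._graph)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnatomicalNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.nodes() == other.nodes()
            and self.edges() == other.edges()
        )

    def __repr__(self) -> str:
        return (
            f"AnatomicalNetwork({self.species!r}, N={self.n_nodes}, K={self.n_edges})"
        )


@dataclass
class SpeciesDataset:
    """A collection of per-species networks with optional covariates.

    ``covariates`` is a table indexed by species with columns such as
    ``body_mass_kg``, ``neck_length`` and ``predatory`` (0/1).  Covariate
    species must be a subset of the network species.
    """

    networks: dict[str, AnatomicalNetwork]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.covariates is not None:
            extra = set(self.covariates.index) - set(self.networks)
            if extra:
                raise ValueError(
                    f"covariates reference unknown species: {sorted(extra)}"
                )

    @property
    def species(self) -> list[str]:
        return sorted(self.networks)


# ---------------------------------------------------------------------------
# label vocabulary

_SERIAL_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")


def load_vocabulary(path: str | Path | None = None) -> dict[str, str]:
    """Load the abbreviation -> tissue mapping.

    The packaged default covers the standard element abbreviations of the
    neck musculoskeletal system; pass ``path`` to use an edited copy.
    """
    if path is None:
        ref = resources.files("necknet").joinpath("data/element_vocabulary.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return dict(zip(table["abbrev"], table["tissue"]))


def infer_node_metadata(
    label: str, vocabulary: Mapping[str, str] | None = None
) -> AnatomicalNode:
    """Infer tissue and side of an element from its label.

    A trailing ``l``/``r`` is the side marker of bilateral elements; serial
    elements carry a segment number (``is3``, ``C5``, ``id2l``).  Lookup
    strips side and segment number.  Cervical vertebrae keep their number
    (``C1``..``C9`` are in the vocabulary directly).  Unknown labels default
    to ``muscle`` with a warning, since muscles are the open class.
    """
    vocab = load_vocabulary() if vocabulary is None else vocabulary
    if label in vocab:  # exact match first (covers C1..C9, iv, rh, ...)
        return AnatomicalNode(label, vocab[label], "midline")

    side = "midline"
    base = label
    if len(base) > 1 and base[-1] in ("l", "r") and not base[:-1].isdigit():
        candidate = base[:-1]
        # strip side only if the remainder (possibly minus a serial number)
        # is a known abbreviation; avoids eating the 'l' of e.g. "cal"
        stem = candidate
        m = _SERIAL_RE.match(candidate)
        if m and m.group(1) in vocab:
            stem = m.group(1)
        if stem in vocab:
            side = "left" if base[-1] == "l" else "right"
            base = candidate
    m = _SERIAL_RE.match(base)
    if m and m.group(1) in vocab and not base.startswith("C"):
        base = m.group(1)
    tissue = vocab.get(base)
    if tissue is None:
        warnings.warn(
            f"unknown element label {label!r}; assuming tissue='muscle'",
            NetworkValidationWarning,
            stacklevel=2,
        )
        tissue = "muscle"
    return AnatomicalNode(label, tissue, side)


# ---------------------------------------------------------------------------
# adjacency matrices


def _load_matrix(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    path = Path(source)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_adjacency_matrix(
    source,
    species: str = "unknown",
    vocabulary: Mapping[str, str] | None = None,
) -> AnatomicalNetwork:
    """Read a labeled 0/1 adjacency matrix into an :class:`AnatomicalNetwork`.

    The matrix must be square with identical row and column label sequences
    and contain only 0/1 cells.  Asymmetric cells are symmetrized by logical
    OR and nonzero diagonal entries are ignored, each with a warning.
    """
    m = _load_matrix(source)
    labels = [str(x) for x in m.index]
    cols = [str(x) for x in m.columns]
    if len(labels) != len(cols):
        raise ValueError(f"matrix is not square: {len(labels)}x{len(cols)}")
    if labels != cols:
        raise ValueError("row and column label sequences differ")
    if len(set(labels)) != len(labels):
        raise ValueError("node labels are not unique")
    a = m.to_numpy()
    if not np.isin(a, (0, 1)).all():
        bad = sorted({x for x in np.unique(a) if x not in (0, 1)})
        raise ValueError(f"adjacency cells must be 0/1; found {bad}")
    a = a.astype(int)
    if np.any(np.diag(a) != 0):
        warnings.warn(
            f"{species}: nonzero diagonal entries ignored",
            NetworkValidationWarning,
            stacklevel=2,
        )
        np.fill_diagonal(a, 0)
    if not np.array_equal(a, a.T):
        warnings.warn(
            f"{species}: asymmetric adjacency matrix symmetrized by logical OR",
            NetworkValidationWarning,
            stacklevel=2,
        )
        a = a | a.T
    vocab = load_vocabulary() if vocabulary is None else vocabulary
    nodes = [infer_node_metadata(lbl, vocab) for lbl in labels]
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = [(labels[i], labels[j]) for i, j in zip(iu, ju)]
    return AnatomicalNetwork(species, nodes, edges)


def read_adjacency_workbook(
    path: str | Path, vocabulary: Mapping[str, str] | None = None
) -> dict[str, AnatomicalNetwork]:
    """Read a multi-sheet workbook, one adjacency matrix per species sheet."""
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    vocab = load_vocabulary() if vocabulary is None else vocabulary
    return {
        name: read_adjacency_matrix(df, species=name, vocabulary=vocab)
        for name, df in sheets.items()
    }


def write_adjacency_matrix(net: AnatomicalNetwork, path: str | Path) -> None:
    """Write a network as a labeled symmetric 0/1 CSV/TSV adjacency matrix."""
    labels = sorted(net.graph.nodes())
    idx = {lbl: i for i, lbl in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)), dtype=int)
    for u, v in net.graph.edges():
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(a, index=labels, columns=labels).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# covariates and trees


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the per-species covariate table (body mass, neck length, diet).

    Expected columns: ``species``, ``body_mass_kg``, ``neck_length``,
    ``predatory`` (0/1).  Returns a DataFrame indexed by species.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("covariate table must have a 'species' column")
    df = df.set_index("species")
    if "predatory" in df.columns:
        vals = set(pd.unique(df["predatory"].dropna()))
        if not vals <= {0, 1, True, False}:
            raise ValueError("'predatory' must be binary (0/1)")
    return df


def read_tree(source: str | Path):
    """Read a Newick tree (file path or literal string) into a PhyloTree."""
    from .trees import PhyloTree

    text = None
    if isinstance(source, (str, Path)):
        p = Path(source)
        try:
            if p.exists():
                text = p.read_text()
        except OSError:  # a long newick literal is not a valid path
            pass
        if text is None:
            text = str(source)
    return PhyloTree.from_newick(text)
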