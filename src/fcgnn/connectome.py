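"""Graph representation of functional connectomes.

A subject's resting-state functional connectivity (FC) is a symmetric
region-by-region matrix of Fisher-transformed Pearson correlations between
BOLD time series. This module turns such a matrix, together with a parcel
lookup table, into the graph ``G = (V, E, W)`` used by the classifiers:

* nodes are atlas regions;
* each node's feature vector is its full (dense) row of the FC matrix —
  the nodal connectivity profile;
* edges are the union over nodes of each node's k strongest connections
  (a k-nearest-neighbour sparsification), weighted by the Fisher-z values.

Parcel membership is never computed from images here; it comes from a
lookup table (region name, hemisphere, 17-network label, coarse network
group). Region names follow the Schaefer-atlas convention, e.g.
``LH_SalVentAttnA_Ins_2``, whose 17-network token aggregates onto one of
eight large-scale groups: visual (VN), somatomotor (SM), dorsal attention
(DAN), salience/ventral attention (VAN), limbic (LMB), control (CN),
default mode (DMN) and temporal-parietal (TPN).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

NETWORK_GROUPS = ("VN", "SM", "DAN", "VAN", "LMB", "CN", "DMN", "TPN")

# 17-network name prefix -> coarse network group
_PREFIX_TO_GROUP = [
    ("Vis", "VN"),
    ("SomMot", "SM"),
    ("DorsAttn", "DAN"),
    ("SalVentAttn", "VAN"),
    ("Limbic", "LMB"),
    ("Cont", "CN"),
    ("Default", "DMN"),
    ("TempPar", "TPN"),
]

_PACKAGED_PARCELS = "schaefer100_17net_synthetic.tsv"


class RegionLookupError(KeyError):
    """Raised when a region name cannot be resolved in a parcel table."""


def network_group_from_name(region_name: str) -> str:
    """Classify a Schaefer-convention region name into its network group.

    The name's 17-network token (after the ``LH_``/``RH_`` hemisphere
    prefix) determines the group, e.g. ``RH_DefaultB_PFCv_1`` -> ``DMN``.
    """
    token = region_name
    if token.startswith(("LH_", "RH_")):
        token = token[3:]
    for prefix, group in _PREFIX_TO_GROUP:
        if token.startswith(prefix):
            return group
    raise RegionLookupError(
        f"region name {region_name!r} has no recognised 17-network prefix"
    )


@dataclass(frozen=True)
class ParcelTable:
    """Ordered region records for one parcellation.

    Attributes
    ----------
    names : list of region names, in matrix row order.
    hemisphere : per-region ``LH``/``RH``.
    network17 : per-region 17-network label (e.g. ``SalVentAttnA``).
    network_group : per-region coarse group (one of :data:`NETWORK_GROUPS`).
    """

    names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    network17: tuple[str, ...]
    network_group: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            dupes = [n for n in self.names if self.names.count(n) > 1]
            raise ValueError(f"duplicate region names: {sorted(set(dupes))}")
        n17_to_group = {}
        for n17, grp in zip(self.network17, self.network_group):
            if n17_to_group.setdefault(n17, grp) != grp:
                raise ValueError(
                    f"17-network label {n17!r} maps to multiple network groups"
                )
        object.__setattr__(self, "_index",
                           {n: i for i, n in enumerate(self.names)})

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, region_name: str) -> int:
        try:
            return self._index[region_name]
        except KeyError:
            close = difflib.get_close_matches(region_name, self.names, n=3)
            raise RegionLookupError(
                f"unknown region {region_name!r}; nearest candidates: {close}"
            ) from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcelTable":
        """Load a parcel table from TSV with columns
        region_index, region_name, hemisphere, network17, network_group."""
        df = pd.read_csv(path, sep="\t")
        required = {"region_index", "region_name", "hemisphere",
                    "network17", "network_group"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcel table missing columns: {sorted(missing)}")
        df = df.sort_values("region_index")
        if not np.array_equal(df["region_index"].to_numpy(), np.arange(len(df))):
            raise ValueError("region_index must be 0..n-1 without gaps")
        return cls(
            names=tuple(df["region_name"]),
            hemisphere=tuple(df["hemisphere"]),
            network17=tuple(df["network17"]),
            network_group=tuple(df["network_group"]),
        )

    @classmethod
    def schaefer100(cls) -> "ParcelTable":
        """The packaged 100-parcel table in Schaefer 17-network naming.

        This is a synthetic stand-in assembled from published region names
        plus convention-consistent fillers; network-group labels derive
        from the 17-network name prefixes (see module docstring), so the
        grouping logic does not depend on the filler rows.
        """
        with resources.as_file(
            resources.files("fcgnn.data") / _PACKAGED_PARCELS
        ) as p:
            return cls.from_tsv(p)


def network_group_of(region_name: str, table: ParcelTable) -> str:
    """Network group of a region, validated against a parcel table."""
    idx = table.index_of(region_name)
    return table.network_group[idx]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z FC matrix for one subject, zero diagonal."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"expected square matrix, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite entries in matrix for {self.subject_id!r}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError(f"matrix for {self.subject_id!r} is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError(f"matrix for {self.subject_id!r} has nonzero diagonal")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def fisher_z(r):
    """Fisher z transform, ``arctanh(r)``; variance-stabilizes correlations.

    Accepts scalars or arrays; every entry must satisfy ``|r| < 1`` (zero
    the diagonal of a correlation matrix before transforming).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1 for every entry")
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


@dataclass
class BrainGraph:
    """One subject's sparse k-NN brain graph.

    ``node_features`` keeps the *dense* FC rows (including the zeroed
    diagonal) even though the edge set is sparsified — perturbation-based
    scoring probes connections through the feature matrix regardless of
    their presence among the sparse edges.
    """

    node_features: np.ndarray          # (n, n) dense FC rows
    edges: list                        # [(i, j), ...] with i < j
    edge_weights: dict                 # {(i, j): w}
    n_nodes: int
    subject_id: str = ""

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency of the sparse edge set."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in self.edge_weights.items():
            A[i, j] = A[j, i] = w
        return A


def build_graph(matrix: ConnectivityMatrix, k: int,
                rank: str = "signed") -> BrainGraph:
    """k-nearest-neighbour sparsification of a connectivity matrix.

    Each node selects its ``k`` most strongly connected neighbours —
    largest signed Fisher-z by default (``rank='absolute'`` ranks by
    magnitude instead) — and the directed selections are symmetrized by
    union. Ties are broken toward the lower region index. Edge weights are
    the matrix values; node features keep the full dense rows.
    """
    n = matrix.n_regions
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_regions={n}, got {k}")
    if rank not in ("signed", "absolute"):
        raise ValueError(f"rank must be 'signed' or 'absolute', got {rank!r}")
    W = matrix.values
    strength = np.abs(W) if rank == "absolute" else W.copy()
    np.fill_diagonal(strength, -np.inf)  # never self-select
    edges: set[tuple[int, int]] = set()
    order = np.arange(n)
    for i in range(n):
        # stable sort on (-strength, index): ties go to the lower index
        nbrs = order[np.lexsort((order, -strength[i]))][:k]
        for j in nbrs:
            edges.add((min(i, j), max(i, j)))
    edge_list = sorted(edges)
    weights = {(i, j): W[i, j] for i, j in edge_list}
    return BrainGraph(node_features=W.copy(), edges=edge_list,
                      edge_weights=weights, n_nodes=n,
                      subject_id=matrix.subject_id)


def write_edge_list(graph: BrainGraph, path: str | Path) -> None:
    """Export a graph's edges as TSV (i, j, weight), 0-based, i < j."""
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for (i, j) in graph.edges:
            fh.write(f"{i}\t{j}\t{graph.edge_weights[(i, j)]:.17g}\n")
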