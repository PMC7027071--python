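"""Spatial clustering statistics for residue sets.

The clustering degree of a residue set is the mean inverse Cα-Cα
distance over all pairs,

    Ms = (1 / N_pairs) * sum_{i<j} 1 / r_ij ,   N_pairs = Ns (Ns - 1) / 2,

in 1/Å: larger Ms means more compact.  Being an average of inverse
distances, Ms is insensitive to one or a few outlying members.

For an interface the ratio

    rho = Ms,cons / Ms,int

compares the conserved subset with the whole interface; rho > 1 means
the conserved residues are clustered within the interface.  Interfaces
whose conserved subset has fewer than two members are flagged excluded
(the isolated-conserved-residue rule).

Conserved residues are decomposed into sub-clusters by agglomerative
average-linkage on Cα distances, cutting the dendrogram strictly below
a 20 Å threshold (half the mean of the maximum conserved-pair distances
over a reference interface set; recomputable via :func:`auto_threshold`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .structure import ResId

DEFAULT_SUBCLUSTER_THRESHOLD = 20.0  # Å


@dataclass
class ResidueSet:
    """Residue ids paired with their Cα coordinates."""

    ids: list[ResId]
    coords: np.ndarray  # (N, 3) Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.ids), 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in residue set")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[ResId]) -> "ResidueSet":
        index = {rid: i for i, rid in enumerate(self.ids)}
        missing = [rid for rid in ids if rid not in index]
        if missing:
            raise ValueError(f"ids not in set: {missing[:5]}")
        rows = [index[rid] for rid in ids]
        return ResidueSet(ids=list(ids), coords=self.coords[rows])


def clustering_degree(residue_set: ResidueSet | np.ndarray) -> float:
    """Ms of a residue set (1/Å); NaN when fewer than two members."""
    coords = residue_set.coords if isinstance(residue_set, ResidueSet) else \
        np.asarray(residue_set, dtype=float)
    if len(coords) < 2:
        return math.nan
    d = pdist(coords)
    if np.any(d == 0.0):
        raise ValueError("coincident Cα pair: clustering degree undefined")
    return float(np.mean(1.0 / d))


@dataclass
class ClusterReport:
    ms_int: float
    ms_cons: float
    rho: float
    subclusters: list[list[ResId]]
    subcluster_sizes: list[int] = field(init=False)
    excluded: bool = False

    def __post_init__(self):
        self.subcluster_sizes = [len(c) for c in self.subclusters]


def clustering_ratio(
    interface: ResidueSet,
    conserved_ids: list[ResId],
    subcluster_threshold: float = DEFAULT_SUBCLUSTER_THRESHOLD,
) -> ClusterReport:
    """rho = Ms,cons / Ms,int plus the conserved sub-cluster decomposition.

    ``conserved_ids`` must be a subset of the interface.  Interfaces
    with fewer than two conserved residues are reported as excluded
    (rho = NaN).
    """
    if len(interface) < 2:
        raise ValueError("interface needs at least two residues")
    conserved = interface.subset(conserved_ids)
    ms_int = clustering_degree(interface)
    if len(conserved) < 2:
        return ClusterReport(
            ms_int=ms_int, ms_cons=math.nan, rho=math.nan,
            subclusters=average_linkage_subclusters(conserved, subcluster_threshold),
            excluded=True,
        )
    ms_cons = clustering_degree(conserved)
    return ClusterReport(
        ms_int=ms_int, ms_cons=ms_cons, rho=ms_cons / ms_int,
        subclusters=average_linkage_subclusters(conserved, subcluster_threshold),
    )


def average_linkage_subclusters(
    residue_set: ResidueSet,
    threshold: float = DEFAULT_SUBCLUSTER_THRESHOLD,
) -> list[list[ResId]]:
    """Average-linkage sub-clusters of a residue set, cut at ``threshold`` Å.

    Clusters are the maximal groups whose merge heights are strictly
    below the threshold.  A singleton input yields one cluster of size
    one; an empty set yields an empty list.  Clusters are ordered by
    their lowest member index, members in input order.
    """
    n = len(residue_set)
    if n == 0:
        return []
    if n == 1:
        return [[residue_set.ids[0]]]
    z = linkage(residue_set.coords, method="average")
    # fcluster's distance criterion merges at heights <= t; strict "<"
    # is obtained by stepping the threshold down one ulp
    labels = fcluster(z, t=np.nextafter(threshold, -np.inf), criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    ordered = sorted(clusters.values(), key=lambda idxs: idxs[0])
    return [[residue_set.ids[i] for i in idxs] for idxs in ordered]


def auto_threshold(conserved_sets: list[np.ndarray]) -> float:
    """Half the mean of the maximum pairwise Cα distances over a set of
    conserved-residue coordinate sets (the rule behind the 20 Å default)."""
    maxima = []
    for coords in conserved_sets:
        coords = np.asarray(coords, dtype=float)
        if len(coords) >= 2:
            maxima.append(pdist(coords).max())
    if not maxima:
        raise ValueError("no set with at least two residues")
    return 0.5 * float(np.mean(maxima))
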