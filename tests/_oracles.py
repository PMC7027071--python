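"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: SASA uses an
equal-area latitude-band point lattice (not the golden spiral) and
plain double loops; average linkage is a naive O(n^3) agglomeration;
entropies are direct per-symbol tallies.
"""

from __future__ import annotations

import math

import numpy as np


def latitude_band_points(n: int) -> np.ndarray:
    """Equal-area z/phi lattice on the unit sphere (distinct from the
    golden-spiral set used by the implementation under test).

    Cells uniform in z and phi all carry equal area (Archimedes), so
    equally weighted points give an unbiased area estimate.
    """
    n_z = max(3, int(round(math.sqrt(n))))
    n_phi = max(3, int(round(n / n_z)))
    pts = []
    for b in range(n_z):
        z = 1.0 - (2.0 * b + 1.0) / n_z
        r = math.sqrt(max(0.0, 1.0 - z * z))
        # stagger phi offsets between bands to avoid meridian alignment
        off = 0.5 + 0.37 * b
        for j in range(n_phi):
            phi = 2.0 * math.pi * (j + off) / n_phi
            pts.append((r * math.cos(phi), r * math.sin(phi), z))
    return np.asarray(pts)


def brute_force_sasa(coords, radii, probe=1.4, n_points=10000) -> np.ndarray:
    """Per-atom SASA by point rejection against every other atom (no
    neighbour search), on the lat-long lattice."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    pts = latitude_band_points(n_points)
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        ri = radii[i] + probe
        x = coords[i] + ri * pts
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            rj = radii[j] + probe
            exposed &= ((x - coords[j]) ** 2).sum(axis=1) >= rj * rj
        out[i] = 4.0 * math.pi * ri * ri * exposed.mean()
    return out


def brute_force_ms(coords) -> float:
    """Mean inverse pairwise distance by explicit double loop."""
    coords = np.asarray(coords, float)
    n = len(coords)
    total = 0.0
    pairs = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            total += 1.0 / float(np.linalg.norm(coords[i] - coords[j]))
            pairs += 1
    return total / pairs


def naive_average_linkage(coords, threshold) -> set[frozenset]:
    """Agglomerative average linkage, merging strictly below threshold."""
    coords = np.asarray(coords, float)
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        best_d = math.inf
        for a in range(len(clusters) - 1):
            for b in range(a + 1, len(clusters)):
                avg = float(np.mean([d[i, j] for i in clusters[a] for j in clusters[b]]))
                if avg < best_d:
                    best_d = avg
                    best = (a, b)
        if best_d >= threshold:
            break
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def tally_entropy(symbols, class_of) -> float:
    """-sum p log2 p over classes, from a direct symbol tally."""
    counts: dict[int, int] = {}
    for ch in symbols:
        c = class_of.get(ch)
        if c is not None:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return math.nan
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def twenty_type_entropy(symbols, alphabet="ACDEFGHIKLMNPQRSTVWY") -> float:
    return tally_entropy(symbols, {aa: i for i, aa in enumerate(alphabet)})
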