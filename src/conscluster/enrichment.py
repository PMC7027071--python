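"""Residue-type enrichment in conserved clusters and hot-spot overlap.

The relative enrichment of amino-acid type X in the conserved
interface subset versus the whole interface is

    E_X = (n_X,cons / N_cons) / (n_X,int / N_int),

undefined when X is absent from the interface.  By construction the
interface-composition-weighted mean of E_X equals 1.

Alanine-scanning hot spots (ddG >= 1.0 / 1.5 / 2.0 kcal/mol) are mapped
onto the structure and their overlap with the conserved residue
clusters is the fraction k/m, with m the residues meeting the ddG
threshold and k those belonging to a conserved sub-cluster.  "In a
cluster" means membership of the conserved set after isolated-residue
removal (sub-cluster size >= 2); an optional proximity mode instead
accepts residues within a distance of any cluster member.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import SEVEN_CLASSES
from .structure import THREE_TO_ONE, ResId

logger = logging.getLogger(__name__)

DDG_THRESHOLDS = (1.0, 1.5, 2.0)  # kcal/mol

#: seven-class membership by one-letter code, class index 1..7
CLASS_OF_ONE = {aa: c for c, aas in SEVEN_CLASSES.items() for aa in aas}


@dataclass
class HotspotRecord:
    resid: ResId
    wt_aa: str  # one-letter
    ddg: float  # kcal/mol

    @property
    def seven_class(self) -> int:
        return CLASS_OF_ONE[self.wt_aa]

    def is_hotspot(self, threshold: float) -> bool:
        return self.ddg >= threshold


# ---------------------------------------------------------------------------
# enrichment


def relative_enrichment(
    conserved_counts: Counter | dict[str, int],
    interface_counts: Counter | dict[str, int],
) -> pd.DataFrame:
    """E_X per amino-acid type; NaN where the type is absent from the
    interface."""
    n_cons = sum(conserved_counts.values())
    n_int = sum(interface_counts.values())
    if n_int == 0:
        raise ValueError("empty interface composition")
    if n_cons == 0:
        raise ValueError("empty conserved subset")
    rows = []
    for aa in sorted(set(conserved_counts) | set(interface_counts)):
        ci = conserved_counts.get(aa, 0)
        ii = interface_counts.get(aa, 0)
        if ii == 0:
            e = math.nan
            if ci > 0:
                raise ValueError(f"type {aa} conserved but absent from interface")
        else:
            e = (ci / n_cons) / (ii / n_int)
        rows.append({"aa": aa, "n_cons": ci, "n_int": ii, "E_X": e})
    return pd.DataFrame(rows)


def composition(aa_types: list[str]) -> Counter:
    """Amino-acid composition counter; accepts one- or three-letter codes."""
    out: Counter = Counter()
    for aa in aa_types:
        aa = aa.upper()
        if len(aa) == 3:
            aa = THREE_TO_ONE.get(aa, "X")
        out[aa] += 1
    return out


# ---------------------------------------------------------------------------
# hot-spot input and overlap


def read_ddg_tsv(path: str | Path) -> pd.DataFrame:
    """Headered ddG table: pdb_id, chain, resnum, icode, wt_aa, ddg_kcal_mol."""
    df = pd.read_csv(path, sep="\t", dtype={"icode": str})
    required = {"pdb_id", "chain", "resnum", "icode", "wt_aa", "ddg_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddG table missing columns: {sorted(missing)}")
    df["icode"] = df["icode"].fillna("").astype(str).str.strip()
    return df


def hotspots_from_table(
    df: pd.DataFrame,
    structure_ids: set[ResId] | None = None,
) -> list[HotspotRecord]:
    """Build hot-spot records; rows that fail to match the structure are
    reported and skipped."""
    records = []
    skipped = []
    for _, row in df.iterrows():
        rid: ResId = (str(row["chain"]), int(row["resnum"]), str(row["icode"]))
        if structure_ids is not None and rid not in structure_ids:
            skipped.append(rid)
            continue
        aa = str(row["wt_aa"]).upper()
        if len(aa) == 3:
            aa = THREE_TO_ONE.get(aa, "X")
        if aa not in CLASS_OF_ONE:
            skipped.append(rid)
            continue
        records.append(HotspotRecord(resid=rid, wt_aa=aa, ddg=float(row["ddg_kcal_mol"])))
    if skipped:
        logger.warning("hotspots_from_table: %d rows did not match the structure "
                       "and were skipped: %s", len(skipped), skipped[:5])
    return records


def hotspot_overlap(
    hotspots: list[HotspotRecord],
    subclusters: list[list[ResId]],
    threshold: float,
    min_cluster_size: int = 2,
    proximity: float | None = None,
    cluster_coords: dict[ResId, np.ndarray] | None = None,
) -> tuple[int, int, float]:
    """(k, m, k/m): hot spots at ``threshold`` inside conserved clusters.

    Cluster membership means belonging to a sub-cluster of at least
    ``min_cluster_size`` conserved residues.  With ``proximity`` set, a
    hot spot within that distance (Å) of any cluster member also
    counts (requires ``cluster_coords``).  Returns (0, 0, NaN) when no
    residue meets the threshold.
    """
    cluster_members = {rid for cl in subclusters if len(cl) >= min_cluster_size
                       for rid in cl}
    selected = [h for h in hotspots if h.is_hotspot(threshold)]
    m = len(selected)
    if m == 0:
        return (0, 0, math.nan)
    if proximity is not None:
        if cluster_coords is None:
            raise ValueError("proximity mode requires cluster member coordinates")
        member_xyz = np.array([cluster_coords[rid] for rid in cluster_members])

        def in_cluster(h: HotspotRecord) -> bool:
            if h.resid in cluster_members:
                return True
            if h.resid not in cluster_coords or len(member_xyz) == 0:
                return False
            d = np.linalg.norm(member_xyz - cluster_coords[h.resid], axis=1)
            return bool(np.any(d <= proximity))
    else:
        def in_cluster(h: HotspotRecord) -> bool:
            return h.resid in cluster_members

    k = sum(1 for h in selected if in_cluster(h))
    return (k, m, k / m)


def seven_class_table(
    hotspots: list[HotspotRecord],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-class totals, hot-spot counts at ``threshold`` and percentages.

    Classes with zero scanned residues get NaN percentages.
    """
    rows = []
    for cls in sorted(SEVEN_CLASSES):
        members = [h for h in hotspots if h.seven_class == cls]
        total = len(members)
        hot = sum(1 for h in members if h.is_hotspot(threshold))
        pct = 100.0 * hot / total if total else math.nan
        rows.append({
            "class": cls,
            "residues": "".join(SEVEN_CLASSES[cls]),
            "n_total": total,
            "n_hotspot": hot,
            "pct_hotspot": pct,
        })
    return pd.DataFrame(rows)
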