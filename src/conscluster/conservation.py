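"""Sequence conservation from homolog alignments.

Per-column conservation is the Shannon entropy of the distribution of
seven amino-acid classes,

    s(i) = - sum_k p_i(k) * log2 p_i(k),

where p_i(k) is the probability of class k at alignment column i among
the non-gap, standard residues.  The classes group residues by the
similarity of their structural environment:

    1: Thr Gly Ser          2: Val Ala Ile Cys Met Leu
    3: Gln Asn              4: Glu Asp
    5: Trp Tyr Phe Pro      6: His
    7: Lys Arg

s(i) ranges from 0 (one class only) to log2(7) ~ 2.81 bits (all seven
classes equiprobable); low entropy means high conservation.

Alignments are filtered before use: homologs below 45% identity to the
query, or with more than five missing residues (gaps at query-covered
columns), are removed, and a chain is usable only when more than five
homologs survive.

Conserved interface residues are selected at three stringency levels
against the interface mean entropy <s>_int:

    C1: s < <s>_int        C2: s < <s>_int / 2        C3: s == 0
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .structure import ComplexStructure, RegionTable, ResId

logger = logging.getLogger(__name__)

#: amino-acid classes by one-letter code
SEVEN_CLASSES: dict[int, str] = {
    1: "TGS",
    2: "VAICML",
    3: "QN",
    4: "ED",
    5: "WYFP",
    6: "H",
    7: "KR",
}
CLASS_OF: dict[str, int] = {aa: c for c, aas in SEVEN_CLASSES.items() for aa in aas}
N_CLASSES = 7
MAX_ENTROPY = math.log2(N_CLASSES)

GAP_CHARS = "-."
UNKNOWN_CHARS = "XBZJUO*"


# ---------------------------------------------------------------------------
# alignment container and filtering


@dataclass
class Msa:
    """Aligned sequences; the query row is the structure's chain sequence."""

    query_id: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if self.query_id not in self.ids:
            raise ValueError(f"query {self.query_id!r} missing from alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        allowed = set(CLASS_OF) | set(GAP_CHARS) | set(UNKNOWN_CHARS)
        for sid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - allowed
            if bad:
                raise ValueError(f"sequence {sid}: unexpected symbols {sorted(bad)}")
        self.rows = [r.upper().replace(".", "-") for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def query_row(self) -> str:
        return self.rows[self.ids.index(self.query_id)]

    def homolog_ids(self) -> list[str]:
        return [i for i in self.ids if i != self.query_id]


def read_fasta_msa(path, query_id: str | None = None) -> Msa:
    """Read an aligned FASTA file (path or open handle); the first record
    is the query by default."""
    source = path if hasattr(path, "read") else str(path)
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    return Msa(query_id=query_id or ids[0], ids=ids, rows=rows)


@dataclass
class FilterResult:
    msa: Msa
    n_input_homologs: int
    n_removed_identity: int
    n_removed_missing: int
    usable: bool


def sequence_identity(query_row: str, row: str) -> float:
    """Identity to query: exact matches at columns where both rows are
    non-gap, divided by the query's non-gap length."""
    q_len = sum(1 for q in query_row if q not in GAP_CHARS)
    if q_len == 0:
        raise ValueError("query row is all gaps")
    matches = sum(
        1 for q, h in zip(query_row, row)
        if q not in GAP_CHARS and h not in GAP_CHARS and q == h
    )
    return matches / q_len


def missing_residues(query_row: str, row: str) -> int:
    """Gap characters in the homolog at columns covered by the query."""
    return sum(1 for q, h in zip(query_row, row)
               if q not in GAP_CHARS and h in GAP_CHARS)


def filter_msa(
    msa: Msa,
    min_identity: float = 0.45,
    max_missing: int = 5,
    min_homologs: int = 5,
) -> FilterResult:
    """Drop weak homologs; flag the alignment usable when more than
    ``min_homologs`` non-query homologs survive."""
    q = msa.query_row
    keep_ids, keep_rows = [], []
    removed_identity = removed_missing = 0
    for sid, row in zip(msa.ids, msa.rows):
        if sid == msa.query_id:
            keep_ids.append(sid)
            keep_rows.append(row)
            continue
        if sequence_identity(q, row) < min_identity:
            removed_identity += 1
            continue
        if missing_residues(q, row) > max_missing:
            removed_missing += 1
            continue
        keep_ids.append(sid)
        keep_rows.append(row)
    filtered = Msa(query_id=msa.query_id, ids=keep_ids, rows=keep_rows)
    n_kept = len(keep_ids) - 1
    logger.info(
        "filter_msa: %d homologs in, %d removed by identity, %d by missing "
        "residues, %d kept (usable=%s)",
        len(msa.ids) - 1, removed_identity, removed_missing, n_kept,
        n_kept > min_homologs,
    )
    return FilterResult(
        msa=filtered,
        n_input_homologs=len(msa.ids) - 1,
        n_removed_identity=removed_identity,
        n_removed_missing=removed_missing,
        usable=n_kept > min_homologs,
    )


# ---------------------------------------------------------------------------
# entropy


def column_entropy(msa: Msa, column: int, class_map: dict[str, int] | None = None) -> float:
    """Seven-class Shannon entropy of one alignment column, in bits.

    Gaps and unknown symbols are excluded from the counts.  Returns NaN
    (undefined) when the column has no countable characters.
    """
    class_map = class_map or CLASS_OF
    if not 0 <= column < msa.n_columns:
        raise IndexError(f"column {column} out of range")
    counts = Counter()
    for row in msa.rows:
        ch = row[column]
        cls = class_map.get(ch)
        if cls is not None:
            counts[cls] += 1
    total = sum(counts.values())
    if total == 0:
        return math.nan
    s = 0.0
    for c in counts.values():
        p = c / total
        s -= p * math.log2(p)
    return s


# ---------------------------------------------------------------------------
# mapping onto the structure


@dataclass
class ConservationProfile:
    """Entropies of query positions mapped onto structure residues."""

    entropies: np.ndarray                 # per ungapped query position, bits
    residue_ids: list[ResId]              # same length; mapped structure residues
    by_residue: dict[ResId, float] = field(init=False)

    def __post_init__(self):
        self.entropies = np.asarray(self.entropies, dtype=float)
        if len(self.entropies) != len(self.residue_ids):
            raise ValueError("entropies and residue ids differ in length")
        finite = self.entropies[np.isfinite(self.entropies)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > MAX_ENTROPY + 1e-9):
            raise ValueError("entropy outside [0, log2 7]")
        self.by_residue = dict(zip(self.residue_ids, self.entropies))


def map_query_to_chain(
    msa: Msa,
    structure: ComplexStructure,
    chain_id: str,
    allow_alignment_fallback: bool = True,
) -> list[ResId]:
    """Map ungapped query positions to residues of one structure chain.

    Exact full-sequence match is tried first, then a substring match
    (query covering part of the chain or vice versa), then an optional
    global alignment fallback for constructs with tags.  Mismatches are
    reported in the raised error rather than silently skipped.
    """
    query_seq = "".join(ch for ch in msa.query_row if ch not in GAP_CHARS)
    chain = structure.chain_residues(chain_id)
    if not chain:
        raise ValueError(f"chain {chain_id} has no residues")
    chain_seq = structure.chain_sequence(chain_id)
    if query_seq == chain_seq:
        return [r.id for r in chain]
    pos = chain_seq.find(query_seq)
    if pos >= 0:
        return [r.id for r in chain[pos:pos + len(query_seq)]]
    if query_seq.find(chain_seq) >= 0:
        # chain covers a substring of the query: map that window
        start = query_seq.find(chain_seq)
        ids: list[ResId | None] = [None] * len(query_seq)
        for i, r in enumerate(chain):
            ids[start + i] = r.id
        return [rid for rid in ids if rid is not None]
    if allow_alignment_fallback:
        from Bio import Align
        aligner = Align.PairwiseAligner(
            mode="global", match_score=2, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-0.5,
        )
        aln = aligner.align(query_seq, chain_seq)[0]
        mapped: list[ResId] = []
        mismatches = 0
        q_aln, c_aln = aln[0], aln[1]
        ci = qi = 0
        pairs: dict[int, int] = {}
        for qa, ca in zip(q_aln, c_aln):
            if qa != "-" and ca != "-":
                pairs[qi] = ci
                if qa != ca:
                    mismatches += 1
            if qa != "-":
                qi += 1
            if ca != "-":
                ci += 1
        if mismatches > 0.2 * len(pairs):
            raise ValueError(
                f"query/chain alignment too divergent for chain {chain_id}: "
                f"{mismatches} mismatches over {len(pairs)} aligned positions"
            )
        logger.warning(
            "map_query_to_chain: fell back to alignment for chain %s "
            "(%d aligned positions, %d mismatches)", chain_id, len(pairs), mismatches,
        )
        return [chain[pairs[i]].id for i in sorted(pairs)]
    raise ValueError(f"query sequence does not match chain {chain_id}")


def build_profile(
    msa: Msa,
    structure: ComplexStructure,
    chain_id: str,
    class_map: dict[str, int] | None = None,
) -> ConservationProfile:
    """Compute s(i) for every query position and map onto one chain."""
    q = msa.query_row
    query_cols = [i for i, ch in enumerate(q) if ch not in GAP_CHARS]
    entropies = np.array([column_entropy(msa, i, class_map) for i in query_cols])
    rids = map_query_to_chain(msa, structure, chain_id)
    if len(rids) != len(entropies):
        # partial mapping (alignment fallback): keep the mapped prefix rule out
        raise ValueError(
            f"mapped {len(rids)} residues but query has {len(entropies)} positions"
        )
    return ConservationProfile(entropies=entropies, residue_ids=rids)


def chain_mean_entropy(profile: ConservationProfile) -> float:
    """<s>: arithmetic mean of s(i) over mapped structure positions."""
    vals = profile.entropies[np.isfinite(profile.entropies)]
    if vals.size == 0:
        raise ValueError("no mapped positions with defined entropy")
    if vals.size < len(profile.entropies):
        logger.warning("chain_mean_entropy: %d undefined positions excluded",
                       len(profile.entropies) - vals.size)
    return float(vals.mean())


# ---------------------------------------------------------------------------
# conserved interface residues


@dataclass
class InterfaceConservation:
    interface_ids: list[ResId]
    n: int
    mean_entropy_int: float
    c1: list[ResId]
    c2: list[ResId]
    c3: list[ResId]

    def __post_init__(self):
        if not (set(self.c3) <= set(self.c2) <= set(self.c1) <= set(self.interface_ids)):
            raise ValueError("criterion subsets are not nested")

    def conserved(self, criterion: str) -> list[ResId]:
        try:
            return {"C1": self.c1, "C2": self.c2, "C3": self.c3}[criterion.upper()]
        except KeyError:
            raise ValueError(f"unknown criterion {criterion!r}") from None


def select_conserved(
    profile: ConservationProfile,
    region_table: RegionTable,
) -> InterfaceConservation:
    """Mean interface entropy and the three nested conserved subsets.

    C1/C2 use strict inequalities; C3 is exact equality with zero.
    Interface residues without a mapped entropy are excluded with a
    warning.
    """
    interface = region_table.interface_ids
    if not interface:
        raise ValueError("empty interface: no residues to select from")
    mapped = [rid for rid in interface
              if rid in profile.by_residue and math.isfinite(profile.by_residue[rid])]
    dropped = len(interface) - len(mapped)
    if dropped:
        logger.warning("select_conserved: %d interface residues without mapped entropy "
                       "excluded", dropped)
    if not mapped:
        raise ValueError("no interface residue has a mapped entropy")
    s = np.array([profile.by_residue[rid] for rid in mapped])
    mean_int = float(s.mean())
    c1 = [rid for rid, v in zip(mapped, s) if v < mean_int]
    c2 = [rid for rid, v in zip(mapped, s) if v < mean_int / 2.0]
    c3 = [rid for rid, v in zip(mapped, s) if v == 0.0]
    # exact zeros sit below any positive threshold; enforce nesting when
    # mean_int is 0 (then C1 and C2 are empty by strictness)
    c2 = [rid for rid in c2 if rid in set(c1)] if mean_int == 0 else c2
    c3 = [rid for rid in c3 if rid in set(c2)]
    return InterfaceConservation(
        interface_ids=mapped, n=len(mapped), mean_entropy_int=mean_int,
        c1=c1, c2=c2, c3=c3,
    )


def conservation_table(
    profile: ConservationProfile,
    region_table: RegionTable,
    selection: InterfaceConservation | None = None,
) -> pd.DataFrame:
    """Per-residue TSV-ready table: entropy, region, conserved flags."""
    rows = []
    c1 = set(selection.c1) if selection else set()
    c2 = set(selection.c2) if selection else set()
    c3 = set(selection.c3) if selection else set()
    for rid, s in profile.by_residue.items():
        chain, resnum, icode = rid
        label = region_table.labels.get(rid)
        rows.append({
            "chain": chain, "resnum": resnum, "icode": icode,
            "aa": region_table.records[rid].aa_type if rid in region_table.records else "?",
            "s": s,
            "region": label.value if label else "UNMAPPED",
            "conserved_C1": rid in c1,
            "conserved_C2": rid in c2,
            "conserved_C3": rid in c3,
        })
    return pd.DataFrame(rows)
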