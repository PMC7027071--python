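"""Synthetic complexes, alignments and ddG tables with known ground truth.

The generator emulates, at coarse grain, the inputs of the interface
conservation analysis so that every pipeline stage can be exercised
against planted truth:

* geometry: a protein rendered as Cα-only pseudo-atoms packed randomly
  in a sphere (minimum separation 3.8 Å, pseudo-radius 3.0 Å, so the
  chain forms a solid blob with a well-defined surface), and an RNA
  rendered as a planar slab of P pseudo-atoms placed against one face;
  the slab offset is solved so that a target fraction of protein
  residues is in contact.  The ground-truth interface is geometric:
  residues whose Cα lies within a contact cutoff of any RNA
  pseudo-atom.  Residues for which the geometric rule and the
  SASA-loss rule would disagree ambiguously (an RNA-occluded area in
  the open interval (0, 1) Å², or contact without SASA loss) are
  removed during generation, so the planted truth is recoverable
  exactly at the 0.1 Å² classification threshold.

* conservation: positions are either conserved (all alignment rows
  carry the query residue, entropy exactly 0) or variable (rows drawn
  uniformly over the seven classes, entropy near log2 7).  Three
  planting modes control where the conserved interface residues sit:
  CLUSTERED (a disc around a random interface seed), SCATTERED (a
  uniform random interface subset) and UNIFORM (one Bernoulli rate
  over the whole solvent-exposed surface, interface included) — the
  null for patch-ranking calibration.

* ddG: alanine-scan values drawn so that the hot-spot probability
  (ddG >= 2 kcal/mol) inside conserved clusters is ``enrichment_ratio``
  times the outside rate.

All randomness flows from the single spec seed through named
``numpy.random.SeedSequence`` children (geometry, sequence,
conservation, msa, ddg), so each artifact is independently
reproducible.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .structure import (
    ONE_TO_THREE,
    Atom,
    ComplexStructure,
    RadiusTable,
    RegionTable,
    Residue,
    ResId,
    classify_regions,
)

MIN_SEPARATION = 3.8       # Å between pseudo-Cα centers
PSEUDO_RADIUS = 3.0        # Å, coarse pseudo-atom radius
COARSE_PROBE = 1.4         # Å
COARSE_N_POINTS = 480
RNA_SPACING = 5.0          # Å grid spacing of the P-atom slab
#: center distance below which two pseudo-atom solvent spheres overlap
OCCLUSION_DISTANCE = 2.0 * (PSEUDO_RADIUS + COARSE_PROBE)   # 8.8 Å
#: geometric contact cutoff defining the ground-truth interface
CONTACT_CUTOFF = 8.6       # Å
#: minimum RNA-occluded area for an unambiguous interface residue
DELTA_MARGIN = 1.0         # Å²

#: reference SASA of an isolated pseudo-residue sphere (coarse mode)
COARSE_REFERENCE_AREA = 4.0 * math.pi * (PSEUDO_RADIUS + COARSE_PROBE) ** 2

# approximate background amino-acid frequencies (UniProt-like), percent
_AA_BACKGROUND = {
    "A": 8.3, "R": 5.5, "N": 4.1, "D": 5.5, "C": 1.4, "Q": 3.9, "E": 6.7,
    "G": 7.1, "H": 2.3, "I": 5.9, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.4, "W": 1.1, "Y": 2.9, "V": 6.9,
}

from .conservation import SEVEN_CLASSES

_CLASS_OF = {aa: c for c, aas in SEVEN_CLASSES.items() for aa in aas}


@dataclass
class CoarseSettings:
    """SASA settings matched to the Cα-only pseudo-atom representation."""

    radius_table: RadiusTable
    reference_table: dict[str, float]
    probe_radius: float = COARSE_PROBE
    n_points: int = COARSE_N_POINTS


def coarse_settings() -> CoarseSettings:
    radius_table = RadiusTable(
        by_element={"C": PSEUDO_RADIUS, "P": PSEUDO_RADIUS},
        by_name={"CA": PSEUDO_RADIUS, "P": PSEUDO_RADIUS},
    )
    reference = {aa3: COARSE_REFERENCE_AREA for aa3 in ONE_TO_THREE.values()}
    return CoarseSettings(radius_table=radius_table, reference_table=reference)


def classify_coarse(structure: ComplexStructure,
                    settings: CoarseSettings | None = None) -> RegionTable:
    settings = settings or coarse_settings()
    return classify_regions(
        structure,
        reference_table=settings.reference_table,
        probe_radius=settings.probe_radius,
        n_points=settings.n_points,
    )


@dataclass
class SyntheticComplexSpec:
    seed: int
    n_protein_residues: int = 160
    packing_radius: float | None = None
    interface_fraction: float = 0.12
    conservation_mode: str = "CLUSTERED"    # CLUSTERED | SCATTERED | UNIFORM
    conserved_fraction: float = 0.5
    cluster_disc_radius: float = 8.0
    interior_conserved_fraction: float = 0.85
    surface_conserved_fraction: float = 0.25
    n_msa_rows: int = 50
    hotspot_enrichment_ratio: float = 3.0
    hotspot_base_rate: float = 0.12

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic output")
        for name in ("interface_fraction", "conserved_fraction",
                     "interior_conserved_fraction", "surface_conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_msa_rows < 6:
            raise ValueError("n_msa_rows must be at least 6 (>5 homologs rule)")
        if self.conservation_mode not in ("CLUSTERED", "SCATTERED", "UNIFORM"):
            raise ValueError(f"unknown conservation mode {self.conservation_mode!r}")
        if self.hotspot_enrichment_ratio < 1.0:
            raise ValueError("hotspot enrichment ratio must be >= 1")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("geometry", "sequence", "conservation", "msa", "ddg")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticComplex:
    spec: SyntheticComplexSpec
    structure: ComplexStructure
    pdb_text: str
    sequence: str                        # one-letter, protein chain
    true_interface: set[ResId]
    region_table: RegionTable            # coarse classification at generation
    conserved_residues: set[ResId]       # planted conserved, protein chain
    conserved_positions: set[int]        # same, as 0-based chain indices
    coarse: CoarseSettings = field(default_factory=coarse_settings)

    @property
    def protein_chain(self) -> str:
        return "A"

    @property
    def rna_chain(self) -> str:
        return "R"


# ---------------------------------------------------------------------------
# geometry


def _pack_sphere(n: int, radius: float, rng: np.random.Generator,
                 min_sep: float = MIN_SEPARATION) -> np.ndarray:
    """Random sequential packing of n points in a sphere."""
    coords = np.empty((n, 3))
    placed = 0
    tries = 0
    max_tries = 20000 * n
    while placed < n:
        if tries > max_tries:
            raise ValueError(
                f"infeasible packing: {n} residues at {min_sep} Å separation "
                f"do not fit in a {radius:.1f} Å sphere"
            )
        tries += 1
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius * radius:
            continue
        if placed and np.min(np.linalg.norm(coords[:placed] - p, axis=1)) < min_sep:
            continue
        coords[placed] = p
        placed += 1
    return coords


def _default_packing_radius(n: int) -> float:
    # sphere sized for a ~25% packing fraction of r=1.9 Å exclusion spheres
    return 0.5 * MIN_SEPARATION * (n / 0.25) ** (1.0 / 3.0)


def _rna_slab(radius: float, z0: float) -> np.ndarray:
    half = radius + 6.0
    ticks = np.arange(-half, half + 1e-9, RNA_SPACING)
    xx, yy = np.meshgrid(ticks, ticks)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z0)])
    keep = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= half * half
    return pts[keep]


def _residue_deltas(protein: np.ndarray, rna: np.ndarray,
                    n_points: int = COARSE_N_POINTS) -> np.ndarray:
    """Exact per-residue SASA loss upon adding the RNA slab."""
    radii_p = np.full(len(protein), PSEUDO_RADIUS)
    radii_all = np.full(len(protein) + len(rna), PSEUDO_RADIUS)
    from .structure import shrake_rupley
    free = shrake_rupley(protein, radii_p, COARSE_PROBE, n_points)
    both = shrake_rupley(np.vstack([protein, rna]), radii_all, COARSE_PROBE, n_points)
    return free - both[: len(protein)]


def generate_complex(spec: SyntheticComplexSpec) -> SyntheticComplex:
    """Build one synthetic complex with planted interface and conservation.

    Deterministic for a fixed spec: rerunning yields byte-identical PDB
    text.  Raises on infeasible packing.
    """
    rngs = spec.rngs()
    rng_geo = rngs["geometry"]
    n = spec.n_protein_residues
    radius = spec.packing_radius or _default_packing_radius(n)
    coords = np.round(_pack_sphere(n, radius, rng_geo), 3)

    # --- place the RNA slab so the contact count hits the target
    target = max(2, round(spec.interface_fraction * n))

    def contact_count(z0: float) -> int:
        rna = _rna_slab(radius, z0)
        d = np.linalg.norm(coords[:, None, :] - rna[None, :, :], axis=2).min(axis=1)
        return int(np.sum(d < CONTACT_CUTOFF))

    lo, hi = 0.0, radius + CONTACT_CUTOFF + 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if contact_count(mid) > target:
            lo = mid
        else:
            hi = mid
    z0 = hi if abs(contact_count(hi) - target) <= abs(contact_count(lo) - target) else lo
    z0 = round(z0, 3)
    rna = np.round(_rna_slab(radius, z0), 3)

    # --- remove residues where geometric contact and SASA loss disagree
    keep = np.ones(n, dtype=bool)
    for _ in range(8):
        sub = coords[keep]
        dist = np.linalg.norm(sub[:, None, :] - rna[None, :, :], axis=2).min(axis=1)
        delta = _residue_deltas(sub, rna)
        contact = dist < CONTACT_CUTOFF
        bad = (contact & (delta < DELTA_MARGIN)) | (~contact & (delta > 0.0))
        if not bad.any():
            break
        idx = np.flatnonzero(keep)
        keep[idx[bad]] = False
    else:
        raise RuntimeError("interface truth did not stabilise; pathological geometry")
    coords = coords[keep]
    dist = np.linalg.norm(coords[:, None, :] - rna[None, :, :], axis=2).min(axis=1)
    true_iface_idx = set(np.flatnonzero(dist < CONTACT_CUTOFF).tolist())

    # --- sequence and structure objects
    rng_seq = rngs["sequence"]
    aas = list(_AA_BACKGROUND)
    probs = np.array(list(_AA_BACKGROUND.values()))
    probs = probs / probs.sum()
    sequence = "".join(rng_seq.choice(aas, size=len(coords), p=probs))

    residues = []
    for i, (aa1, xyz) in enumerate(zip(sequence, coords), start=1):
        residues.append(Residue(
            chain_id="A", seq_number=i, insertion_code="",
            aa_type=ONE_TO_THREE[aa1],
            atoms=[Atom(name="CA", element="C", coord=xyz, vdw_radius=PSEUDO_RADIUS)],
        ))
    for j, xyz in enumerate(rna, start=1):
        residues.append(Residue(
            chain_id="R", seq_number=j, insertion_code="", aa_type="U",
            atoms=[Atom(name="P", element="P", coord=xyz, vdw_radius=PSEUDO_RADIUS)],
        ))
    structure = ComplexStructure(
        residues=residues,
        protein_chain_ids=frozenset({"A"}),
        rna_chain_ids=frozenset({"R"}),
    )
    true_interface = {("A", i + 1, "") for i in true_iface_idx}

    settings = coarse_settings()
    region_table = classify_coarse(structure, settings)

    # --- plant conservation
    rng_cons = rngs["conservation"]
    conserved = _plant_conservation(spec, structure, region_table,
                                    true_interface, rng_cons)
    conserved_positions = {rid[1] - 1 for rid in conserved}

    pdb_text = render_pdb(structure)
    return SyntheticComplex(
        spec=spec, structure=structure, pdb_text=pdb_text, sequence=sequence,
        true_interface=true_interface, region_table=region_table,
        conserved_residues=conserved, conserved_positions=conserved_positions,
        coarse=settings,
    )


def _plant_conservation(
    spec: SyntheticComplexSpec,
    structure: ComplexStructure,
    region_table: RegionTable,
    true_interface: set[ResId],
    rng: np.random.Generator,
) -> set[ResId]:
    interface = sorted(true_interface)
    surface = sorted(set(region_table.surface_ids) - true_interface)
    interior = sorted(set(region_table.interior_ids) - true_interface)
    conserved: set[ResId] = set()

    # interior: mostly conserved (fold maintenance)
    for rid in interior:
        if rng.random() < spec.interior_conserved_fraction:
            conserved.add(rid)

    if spec.conservation_mode == "UNIFORM":
        # one rate over the whole exposed surface, interface included
        for rid in interface + surface:
            if rng.random() < spec.conserved_fraction:
                conserved.add(rid)
        return conserved

    for rid in surface:
        if rng.random() < spec.surface_conserved_fraction:
            conserved.add(rid)

    coords = {r.id: r.ca_coord for r in structure.protein_residues}
    if spec.conservation_mode == "CLUSTERED":
        seed_rid = interface[int(rng.integers(len(interface)))]
        seed_xyz = coords[seed_rid]
        members = [rid for rid in interface
                   if np.linalg.norm(coords[rid] - seed_xyz) <= spec.cluster_disc_radius]
        if len(members) < 2:  # disc too small for this packing: take 2 nearest
            members = sorted(
                interface, key=lambda rid: float(np.linalg.norm(coords[rid] - seed_xyz))
            )[:2]
        cap = max(2, round(0.8 * len(interface)))
        if len(members) > cap:
            members = sorted(
                members, key=lambda rid: float(np.linalg.norm(coords[rid] - seed_xyz))
            )[:cap]
        conserved.update(members)
    else:  # SCATTERED
        k = int(np.clip(round(spec.conserved_fraction * len(interface)),
                        2, max(2, len(interface) - 1)))
        picked = rng.choice(len(interface), size=k, replace=False)
        conserved.update(interface[int(i)] for i in picked)
    return conserved


# ---------------------------------------------------------------------------
# PDB rendering


def render_pdb(structure: ComplexStructure) -> str:
    """Minimal deterministic PDB text (ATOM records and TER lines)."""
    lines = []
    serial = 0
    prev_chain = None
    for res in structure.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for a in res.atoms:
            serial += 1
            name = f" {a.name:<3s}"[:4]
            resname = f"{res.aa_type:>3s}"
            x, y, z = a.coord
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {res.chain_id:1s}"
                f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# alignments


def generate_msa(
    sequence: str,
    conserved_positions: set[int],
    n_rows: int,
    seed: int | np.random.Generator,
    query_id: str = "query",
    min_identity: float = 0.45,
) -> str:
    """Aligned FASTA with planted per-column conservation.

    Conserved columns carry the query residue in every row (7-class
    entropy exactly 0); variable columns draw a class uniformly from
    the seven classes and a residue within it, keeping the query's
    residue when its own class is drawn (the within-class choice does
    not affect class entropy).  Rows are gap-free and resampled, if
    ever needed, until they reach ``min_identity`` to the query, so
    the alignment passes the homolog filters without removals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bad = set(str(i) for i in conserved_positions if not 0 <= int(i) < len(sequence))
    if bad:
        raise ValueError(f"conserved positions outside the sequence: {sorted(bad)}")
    conserved_positions = {int(i) for i in conserved_positions}
    class_members = {c: list(aas) for c, aas in SEVEN_CLASSES.items()}
    classes = sorted(class_members)

    rows = [sequence]
    ids = [query_id]
    for h in range(1, n_rows):
        for _ in range(500):
            chars = []
            for i, q in enumerate(sequence):
                if i in conserved_positions:
                    chars.append(q)
                    continue
                c = classes[int(rng.integers(7))]
                if c == _CLASS_OF[q]:
                    chars.append(q)
                else:
                    mem = class_members[c]
                    chars.append(mem[int(rng.integers(len(mem)))])
            row = "".join(chars)
            ident = sum(a == b for a, b in zip(row, sequence)) / len(sequence)
            if ident >= min_identity:
                break
        else:
            raise RuntimeError(
                "could not sample a homolog at the required identity; "
                "too few conserved positions"
            )
        rows.append(row)
        ids.append(f"hom{h:04d}")

    out = io.StringIO()
    for sid, row in zip(ids, rows):
        out.write(f">{sid}\n")
        for k in range(0, len(row), 60):
            out.write(row[k:k + 60] + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# ddG tables


def generate_ddg(
    interface_residues: list[tuple[ResId, str]],
    cluster_members: set[ResId],
    enrichment_ratio: float,
    seed: int | np.random.Generator,
    base_rate: float = 0.12,
    pdb_id: str = "SYN1",
) -> str:
    """Alanine-scan ddG TSV with planted in-cluster hot-spot enrichment.

    ``interface_residues`` are (residue id, one-letter type) pairs.
    P(ddG >= 2 | in cluster) = ratio * P(ddG >= 2 | outside); hot
    residues draw ddG from 2 + Exp(1) kcal/mol, others from
    U(-0.5, 2).
    """
    if enrichment_ratio < 1.0:
        raise ValueError("enrichment ratio must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_out = base_rate
    p_in = min(enrichment_ratio * base_rate, 0.9)
    lines = ["pdb_id\tchain\tresnum\ticode\twt_aa\tddg_kcal_mol"]
    for rid, aa in interface_residues:
        p = p_in if rid in cluster_members else p_out
        if rng.random() < p:
            ddg = 2.0 + rng.exponential(1.0)
        else:
            ddg = rng.uniform(-0.5, 2.0)
        chain, resnum, icode = rid
        lines.append(f"{pdb_id}\t{chain}\t{resnum}\t{icode}\t{aa}\t{ddg:.3f}")
    return "\n".join(lines) + "\n"
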