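"""Structure handling, solvent accessible surface area and region labels.

A protein-RNA complex is held as a flat, ordered list of residues with
explicit protein / RNA chain assignments.  Solvent accessible surface
area (SASA) is computed with a deterministic Shrake-Rupley quadrature
(golden-spiral point set, probe radius 1.4 Å by default), and every
protein residue is classified into exactly one of three regions:

INTERFACE
    loses more than ``interface_delta_threshold`` (default 0.1 Å²) of
    SASA when the RNA partner is present;
SURFACE
    not interface, and relative SASA in the complex exceeds
    ``surface_rel_threshold`` (default 5%) of the residue's reference
    SASA in an extended Ala-X-Ala tripeptide;
INTERIOR
    everything else.

Interface takes precedence over the surface test so the three labels
partition the protein residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: default probe radius in Å (water)
DEFAULT_PROBE = 1.4
#: default number of quadrature points per atom
DEFAULT_N_POINTS = 960

#: residue id: (chain_id, seq_number, insertion_code)
ResId = tuple[str, int, str]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: common non-standard residues mapped onto their parent type
RESIDUE_ALIASES = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "MLY": "LYS",
    "CSO": "CYS", "KCX": "LYS",
}

RNA_RESIDUES = {"A", "U", "G", "C", "I", "N"}


class RegionLabel(str, Enum):
    INTERFACE = "INTERFACE"
    SURFACE = "SURFACE"
    INTERIOR = "INTERIOR"


# ---------------------------------------------------------------------------
# radius and reference tables


class RadiusTable:
    """Van der Waals radii looked up by atom name, then by element."""

    def __init__(self, by_element: dict[str, float], by_name: dict[str, float] | None = None):
        self.by_element = {k.upper(): float(v) for k, v in by_element.items()}
        self.by_name = {k.upper(): float(v) for k, v in (by_name or {}).items()}

    def radius(self, atom_name: str, element: str) -> float | None:
        r = self.by_name.get(atom_name.upper())
        if r is None:
            r = self.by_element.get(element.upper())
        return r

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RadiusTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        by_element = dict(df[df["kind"] == "element"][["key", "radius"]].values)
        by_name = dict(df[df["kind"] == "name"][["key", "radius"]].values)
        return cls(by_element, by_name)


def default_radius_table() -> RadiusTable:
    with resources.as_file(resources.files("conscluster.data") / "atom_radii.tsv") as p:
        return RadiusTable.from_tsv(p)


def default_reference_table() -> dict[str, float]:
    """Ala-X-Ala extended tripeptide reference SASA per residue type (Å²)."""
    with resources.as_file(resources.files("conscluster.data") / "tripeptide_sasa.tsv") as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["aa"], df["sasa"].astype(float)))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    vdw_radius: float
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.vdw_radius > 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa_type: str  # 3-letter amino acid or nucleotide type
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> ResId:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def ca_coord(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.coord
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(RESIDUE_ALIASES.get(self.aa_type, self.aa_type), "X")


@dataclass
class ComplexStructure:
    residues: list[Residue]
    protein_chain_ids: frozenset[str]
    rna_chain_ids: frozenset[str]

    def __post_init__(self):
        self.protein_chain_ids = frozenset(self.protein_chain_ids)
        self.rna_chain_ids = frozenset(self.rna_chain_ids)
        if self.protein_chain_ids & self.rna_chain_ids:
            raise ValueError("protein and RNA chain id sets overlap")
        seen: set[ResId] = set()
        for r in self.residues:
            if r.id in seen:
                raise ValueError(f"duplicate residue identifier {r.id}")
            seen.add(r.id)

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.chain_id in self.protein_chain_ids]

    @property
    def rna_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.chain_id in self.rna_chain_ids]

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain_residues(chain_id))

    def residue(self, rid: ResId) -> Residue:
        for r in self.residues:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def without_chains(self, chain_ids: frozenset[str] | set[str]) -> "ComplexStructure":
        chain_ids = frozenset(chain_ids)
        return ComplexStructure(
            residues=[r for r in self.residues if r.chain_id not in chain_ids],
            protein_chain_ids=self.protein_chain_ids - chain_ids,
            rna_chain_ids=self.rna_chain_ids - chain_ids,
        )

    def validate_chain_lengths(self, min_protein: int = 30, min_rna: int = 5) -> None:
        """Dataset-style length rule: reject short protein/RNA chains."""
        for c in sorted(self.protein_chain_ids):
            n = len(self.chain_residues(c))
            if n < min_protein:
                raise ValueError(f"protein chain {c} has {n} residues (< {min_protein})")
        for c in sorted(self.rna_chain_ids):
            n = len(self.chain_residues(c))
            if n < min_rna:
                raise ValueError(f"RNA chain {c} has {n} nucleotides (< {min_rna})")


@dataclass
class SasaRecord:
    resid: ResId
    aa_type: str
    sasa_complex: float
    sasa_protein_only: float
    rel_sasa_complex: float
    delta_sasa: float

    def __post_init__(self):
        eps = 0.01
        if self.sasa_complex < 0 or self.sasa_protein_only < 0:
            raise ValueError(f"negative SASA for residue {self.resid}")
        if self.delta_sasa < -eps:
            raise ValueError(
                f"delta SASA {self.delta_sasa:.4f} < -{eps} for residue {self.resid}"
            )


@dataclass
class RegionTable:
    """Per-residue SASA records and region labels for the protein residues."""

    records: dict[ResId, SasaRecord]
    labels: dict[ResId, RegionLabel]

    def ids_with_label(self, label: RegionLabel) -> list[ResId]:
        return [rid for rid, lab in self.labels.items() if lab is label]

    @property
    def interface_ids(self) -> list[ResId]:
        return self.ids_with_label(RegionLabel.INTERFACE)

    @property
    def surface_ids(self) -> list[ResId]:
        return self.ids_with_label(RegionLabel.SURFACE)

    @property
    def interior_ids(self) -> list[ResId]:
        return self.ids_with_label(RegionLabel.INTERIOR)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rid, rec in self.records.items():
            chain, resnum, icode = rid
            rows.append({
                "chain": chain, "resnum": resnum, "icode": icode,
                "aa": rec.aa_type,
                "sasa_complex": rec.sasa_complex,
                "sasa_free": rec.sasa_protein_only,
                "rel_sasa": rec.rel_sasa_complex,
                "delta_sasa": rec.delta_sasa,
                "region": self.labels[rid].value,
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# PDB input


def read_pdb(
    path: str | Path,
    protein_chains: set[str],
    rna_chains: set[str],
    radius_table: RadiusTable | None = None,
    include_het: bool = False,
) -> ComplexStructure:
    """Read a protein-RNA complex from a PDB file.

    Only the named chains are kept.  Waters and hydrogens are always
    dropped; other heteroatom residues are dropped unless
    ``include_het`` or a known alias (e.g. MSE) maps them to a parent
    residue type.  Alternate locations are resolved to the
    highest-occupancy conformer (ties broken by altloc identifier).

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    ValueError
        if a requested chain is absent, or an atom has no radius in the
        table, or the file cannot be parsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    radius_table = radius_table or default_radius_table()
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc

    wanted = set(protein_chains) | set(rna_chains)
    model = st[0]
    present = {ch.name for ch in model}
    missing = sorted(wanted - present)
    if missing:
        raise ValueError(f"chain(s) {', '.join(missing)} not present in {path.name}")

    residues: list[Residue] = []
    for chain in model:
        if chain.name not in wanted:
            continue
        is_protein = chain.name in protein_chains
        for res in chain:
            name = res.name.strip().upper()
            if name == "HOH" or res.is_water():
                continue
            if is_protein:
                parent = RESIDUE_ALIASES.get(name, name)
                if parent not in THREE_TO_ONE and not include_het:
                    continue
                aa_type = parent
            else:
                if name not in RNA_RESIDUES and not include_het:
                    continue
                aa_type = name
            # altloc resolution: per atom name keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.name.upper() in ("H", "D"):
                    continue
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                else:
                    occ_new = atom.occ if atom.occ is not None else 1.0
                    occ_old = prev.occ if prev.occ is not None else 1.0
                    if occ_new > occ_old or (
                        occ_new == occ_old and (atom.altloc or "~") < (prev.altloc or "~")
                    ):
                        best[atom.name] = atom
            atoms = []
            for atom in best.values():
                elem = atom.element.name.upper()
                r = radius_table.radius(atom.name, elem)
                if r is None:
                    raise ValueError(
                        f"no vdW radius for atom {atom.name} (element {elem}) "
                        f"in residue {name} {chain.name}{res.seqid.num}"
                    )
                atoms.append(Atom(
                    name=atom.name,
                    element=elem,
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    vdw_radius=r,
                    occupancy=atom.occ if atom.occ is not None else 1.0,
                    altloc=(atom.altloc or "").strip(),
                ))
            if not atoms:
                continue
            icode = (res.seqid.icode or " ").strip()
            residues.append(Residue(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=icode,
                aa_type=aa_type,
                atoms=atoms,
            ))
    return ComplexStructure(
        residues=residues,
        protein_chain_ids=frozenset(protein_chains),
        rna_chain_ids=frozenset(rna_chains),
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (Å²) by point-counting on expanded spheres.

    Deterministic for a fixed ``n_points``: the quadrature point set is
    the golden-spiral lattice, no random rotation is applied.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    ext = radii + probe_radius
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(n)
    for i in range(n):
        nbrs = tree.query_ball_point(coords[i], ext[i] + max_ext)
        nbrs = [j for j in nbrs if j != i
                and np.dot(coords[j] - coords[i], coords[j] - coords[i])
                < (ext[i] + ext[j]) ** 2]
        sp = coords[i] + ext[i] * pts
        if nbrs:
            nb_coords = coords[nbrs]
            nb_ext2 = ext[nbrs] ** 2
            d2 = ((sp[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= nb_ext2[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * frac
    return areas


def compute_sasa(
    structure: ComplexStructure,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[ResId, float]:
    """Residue SASA (Å²): sum of per-atom Shrake-Rupley areas."""
    coords, radii, owners = [], [], []
    for res in structure.residues:
        for a in res.atoms:
            coords.append(a.coord)
            radii.append(a.vdw_radius)
            owners.append(res.id)
    areas = shrake_rupley(np.array(coords), np.array(radii), probe_radius, n_points)
    out: dict[ResId, float] = {r.id: 0.0 for r in structure.residues}
    for rid, area in zip(owners, areas):
        out[rid] += area
    return out


# ---------------------------------------------------------------------------
# region classification


def classify_regions(
    structure: ComplexStructure,
    reference_table: dict[str, float] | None = None,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    interface_delta_threshold: float = 0.1,
    surface_rel_threshold: float = 5.0,
) -> RegionTable:
    """Label every protein residue interface / surface / interior.

    SASA is computed twice: once on the full complex and once with the
    RNA chains removed.  A residue is INTERFACE when it loses more than
    ``interface_delta_threshold`` Å² upon complexation, else SURFACE
    when its relative SASA in the complex exceeds
    ``surface_rel_threshold`` percent, else INTERIOR.
    """
    if not structure.rna_chain_ids:
        raise ValueError("structure has no RNA chains; interface analysis undefined")
    reference_table = reference_table or default_reference_table()
    sasa_cx = compute_sasa(structure, probe_radius, n_points)
    protein_only = structure.without_chains(structure.rna_chain_ids)
    sasa_free = compute_sasa(protein_only, probe_radius, n_points)

    records: dict[ResId, SasaRecord] = {}
    labels: dict[ResId, RegionLabel] = {}
    for res in structure.protein_residues:
        aa = res.aa_type
        if aa not in reference_table:
            raise KeyError(f"residue type {aa} absent from the reference SASA table")
        s_cx = sasa_cx[res.id]
        s_free = sasa_free[res.id]
        rec = SasaRecord(
            resid=res.id,
            aa_type=aa,
            sasa_complex=s_cx,
            sasa_protein_only=s_free,
            rel_sasa_complex=100.0 * s_cx / reference_table[aa],
            delta_sasa=s_free - s_cx,
        )
        records[res.id] = rec
        if rec.delta_sasa > interface_delta_threshold:
            labels[res.id] = RegionLabel.INTERFACE
        elif rec.rel_sasa_complex > surface_rel_threshold:
            labels[res.id] = RegionLabel.SURFACE
        else:
            labels[res.id] = RegionLabel.INTERIOR
    return RegionTable(records=records, labels=labels)
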