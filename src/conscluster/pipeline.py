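"""Per-complex orchestration and multi-complex aggregation.

``run_complex`` executes the full per-interface analysis — region
classification, conservation mapping, conserved-residue selection,
clustering statistics, optional patch ranking and optional hot-spot /
enrichment analysis — and returns one report row.  ``aggregate``
summarises many such rows the way the per-interface statistics are
tabulated: mean rho (per conserved-residue criterion), the fraction of
interfaces with rho > 1, the fraction with rho in (1.0, 1.2], the
decile histogram of interface ranks and a one-sided Wilcoxon signed
rank p-value for rho > 1.  Interfaces whose conserved subset is a
single isolated residue are excluded from the rho statistics and
counted separately, which is why totals shrink under more stringent
conservation criteria.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import clustering, conservation, enrichment, patches, structure
from .structure import RegionLabel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds of one per-complex run.

    Threshold defaults are the analysis constants: 0.1 Å² SASA loss and
    5% relative SASA for the region labels; 45% identity, 5 missing
    residues and >5 homologs for the alignment filter; 20 Å for
    sub-clusters and method-1 patches; 110° solvent-vector cutoff; 1000
    patches; ddG cutoffs 1.0/1.5/2.0 kcal/mol.
    """

    pdb_path: str = ""
    msa_path: str = ""
    ddg_path: str = ""
    protein_chains: tuple[str, ...] = ()
    rna_chains: tuple[str, ...] = ()
    chain: str = ""                       # chain whose interface is analysed
    complex_id: str = ""

    probe_radius: float = 1.4
    n_points: int = 960
    interface_delta_threshold: float = 0.1
    surface_rel_threshold: float = 5.0
    coarse_mode: bool = False             # Cα-only pseudo-atom inputs

    min_identity: float = 0.45
    max_missing: int = 5
    min_homologs: int = 5

    criterion: str = "C1"                 # C1 | C2 | C3
    subcluster_threshold: float = 20.0

    run_patches: bool = True
    patch_method: int = 1
    n_patches: int = 1000
    patch_radius: float = 20.0
    angle_cutoff_deg: float = 110.0

    ddg_thresholds: tuple[float, ...] = (1.0, 1.5, 2.0)
    seed: int = 0
    out_dir: str = ""

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            t = f.type
            if t in ("float",):
                kwargs[f.name] = float(v)
            elif t in ("int",):
                kwargs[f.name] = int(v)
            elif t in ("bool",):
                kwargs[f.name] = v.lower() in ("1", "true", "yes")
            elif t.startswith("tuple[str"):
                kwargs[f.name] = tuple(x for x in v.split(",") if x)
            elif t.startswith("tuple[float"):
                kwargs[f.name] = tuple(float(x) for x in v.split(",") if x)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


@dataclass
class ComplexReport:
    """One interface's summary statistics."""

    complex_id: str = ""
    chain: str = ""
    n_protein_residues: int = 0
    region_fractions: dict[str, float] = field(default_factory=dict)
    mean_s: float = math.nan
    mean_s_by_region: dict[str, float] = field(default_factory=dict)
    n_interface: int = 0
    mean_s_int: float = math.nan
    n_conserved: int = 0
    ms_int: float = math.nan
    ms_cons: float = math.nan
    rho: float = math.nan
    excluded: bool = False
    n_subclusters: int = 0
    subcluster_sizes: list[int] = field(default_factory=list)
    rank: int | None = None
    decile: int | None = None
    z: float = math.nan
    significant_percentile: bool | None = None
    significant_z: bool | None = None
    hotspot_overlap: dict[float, tuple[int, int, float]] = field(default_factory=dict)

    @classmethod
    def from_rho(cls, rho: float, **kw) -> "ComplexReport":
        return cls(rho=rho, excluded=not math.isfinite(rho), **kw)


def analyze_complex(
    cx: structure.ComplexStructure,
    msa: conservation.Msa,
    config: RunConfig,
    ddg_table: pd.DataFrame | None = None,
    reference_table: dict[str, float] | None = None,
) -> tuple[ComplexReport, dict]:
    """Run regions → conservation → clustering → patches → hot spots.

    Returns the report plus a dict of intermediate artifacts (region
    table, profile, selection, cluster report, ranking, enrichment)
    for persistence.  Any stage failure propagates with the stage
    named.
    """
    if not cx.rna_chain_ids:
        raise ValueError("no RNA chain assigned; cannot define an interface")
    chain_id = config.chain or sorted(cx.protein_chain_ids)[0]
    arts: dict = {}
    if config.coarse_mode:
        from .synthetic import coarse_settings
        settings = coarse_settings()
        reference_table = settings.reference_table
        probe, n_points = settings.probe_radius, settings.n_points
    else:
        reference_table = reference_table or structure.default_reference_table()
        probe, n_points = config.probe_radius, config.n_points

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    region_table = stage("regions", structure.classify_regions, cx,
                         reference_table=reference_table,
                         probe_radius=probe, n_points=n_points,
                         interface_delta_threshold=config.interface_delta_threshold,
                         surface_rel_threshold=config.surface_rel_threshold)
    arts["region_table"] = region_table

    filt = stage("msa_filter", conservation.filter_msa, msa,
                 min_identity=config.min_identity,
                 max_missing=config.max_missing,
                 min_homologs=config.min_homologs)
    if not filt.usable:
        raise RuntimeError(
            f"stage 'msa_filter' failed: only {len(filt.msa.ids) - 1} homologs retained "
            f"(> {config.min_homologs} required)")
    arts["msa_filter"] = filt
    profile = stage("conservation", conservation.build_profile, filt.msa, cx, chain_id)
    arts["profile"] = profile
    selection = stage("conservation", conservation.select_conserved, profile, region_table)
    arts["selection"] = selection
    conserved_ids = selection.conserved(config.criterion)

    chain_iface = [rid for rid in selection.interface_ids if rid[0] == chain_id]
    coords = {r.id: r.ca_coord for r in cx.protein_residues if r.ca_coord is not None}
    iface_with_ca = [rid for rid in chain_iface if rid in coords]
    if len(iface_with_ca) < len(chain_iface):
        logger.warning("analyze_complex: %d interface residues without Cα excluded "
                       "from clustering", len(chain_iface) - len(iface_with_ca))
    iface_set = clustering.ResidueSet(
        ids=iface_with_ca, coords=np.array([coords[r] for r in iface_with_ca]))
    conserved_ids = [rid for rid in conserved_ids if rid in coords and rid[0] == chain_id]
    cluster_report = stage("clustering", clustering.clustering_ratio,
                           iface_set, conserved_ids,
                           subcluster_threshold=config.subcluster_threshold)
    arts["cluster_report"] = cluster_report

    ranking = None
    if config.run_patches:
        surface = stage("patches", patches.surface_residue_set, cx,
                        reference_table=reference_table,
                        probe_radius=probe, n_points=n_points,
                        surface_rel_threshold=config.surface_rel_threshold)
        radius = config.patch_radius
        if config.patch_method in (2, 3):
            radius = patches.method2_radius(iface_set.coords)
        patch_list = stage("patches", patches.sample_patches, surface,
                           config.patch_method, n=config.n_patches,
                           rng=config.seed, radius=radius,
                           angle_cutoff_deg=config.angle_cutoff_deg)
        rhos = [patches.patch_rho(p, surface, profile.by_residue) for p in patch_list]
        if math.isfinite(cluster_report.rho):
            ranking = patches.rank_interface(cluster_report.rho, rhos)
            arts["ranking"] = ranking

    hs_overlap: dict[float, tuple[int, int, float]] = {}
    if ddg_table is not None:
        hs = stage("hotspots", enrichment.hotspots_from_table, ddg_table,
                   structure_ids={r.id for r in cx.protein_residues})
        arts["hotspots"] = hs
        for thr in config.ddg_thresholds:
            hs_overlap[thr] = enrichment.hotspot_overlap(
                hs, cluster_report.subclusters, thr)
        arts["seven_class_table"] = enrichment.seven_class_table(hs)

    if conserved_ids:
        aa_of = {r.id: r.one_letter for r in cx.protein_residues}
        arts["enrichment"] = enrichment.relative_enrichment(
            enrichment.composition([aa_of[r] for r in conserved_ids]),
            enrichment.composition([aa_of[r] for r in iface_with_ca]),
        )

    labels = region_table.labels
    n_prot = len(labels)
    fractions = {lab.value: sum(1 for v in labels.values() if v is lab) / n_prot
                 for lab in RegionLabel}
    by_region: dict[str, float] = {}
    for lab in RegionLabel:
        vals = [profile.by_residue[rid] for rid in region_table.ids_with_label(lab)
                if rid in profile.by_residue and math.isfinite(profile.by_residue[rid])]
        by_region[lab.value] = float(np.mean(vals)) if vals else math.nan

    report = ComplexReport(
        complex_id=config.complex_id, chain=chain_id,
        n_protein_residues=n_prot,
        region_fractions=fractions,
        mean_s=conservation.chain_mean_entropy(profile),
        mean_s_by_region=by_region,
        n_interface=len(iface_with_ca),
        mean_s_int=selection.mean_entropy_int,
        n_conserved=len(conserved_ids),
        ms_int=cluster_report.ms_int,
        ms_cons=cluster_report.ms_cons,
        rho=cluster_report.rho,
        excluded=cluster_report.excluded,
        n_subclusters=len(cluster_report.subclusters),
        subcluster_sizes=cluster_report.subcluster_sizes,
        rank=ranking.rank if ranking else None,
        decile=ranking.decile if ranking else None,
        z=ranking.z if ranking else math.nan,
        significant_percentile=ranking.significant_percentile if ranking else None,
        significant_z=ranking.significant_z if ranking else None,
        hotspot_overlap=hs_overlap,
    )
    return report, arts


def run_complex(config: RunConfig) -> ComplexReport:
    """File-level wrapper: read inputs, analyse, persist intermediates."""
    if config.coarse_mode:
        from .synthetic import coarse_settings
        radius_table = coarse_settings().radius_table
    else:
        radius_table = None
    cx = structure.read_pdb(config.pdb_path,
                            protein_chains=set(config.protein_chains),
                            rna_chains=set(config.rna_chains),
                            radius_table=radius_table)
    msa = conservation.read_fasta_msa(config.msa_path)
    ddg = enrichment.read_ddg_tsv(config.ddg_path) if config.ddg_path else None
    report, arts = analyze_complex(cx, msa, config, ddg_table=ddg)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_file(out / "config.resolved.txt")
        arts["region_table"].write_tsv(out / "regions.tsv")
        conservation.conservation_table(
            arts["profile"], arts["region_table"], arts["selection"]
        ).to_csv(out / "conservation.tsv", sep="\t", index=False, float_format="%.4f")
        cr = arts["cluster_report"]
        pd.DataFrame([{
            "ms_int": cr.ms_int, "ms_cons": cr.ms_cons, "rho": cr.rho,
            "excluded": cr.excluded, "n_subclusters": len(cr.subclusters),
            "sizes": ",".join(map(str, cr.subcluster_sizes)),
        }]).to_csv(out / "clustering.tsv", sep="\t", index=False, float_format="%.6f")
        (out / "subclusters.json").write_text(json.dumps(
            [[list(rid) for rid in cl] for cl in cr.subclusters], indent=1))
        if "ranking" in arts:
            rk = arts["ranking"]
            pd.DataFrame([{
                "rho_int": rk.rho_int, "mean_patch_rho": rk.mean_rho,
                "sigma": rk.sigma, "n": rk.n, "rank": rk.rank,
                "decile": rk.decile, "z": rk.z,
                "significant": rk.significant_percentile,
            }]).to_csv(out / "ranking.tsv", sep="\t", index=False, float_format="%.6f")
        if "enrichment" in arts:
            arts["enrichment"].to_csv(out / "enrichment.tsv", sep="\t",
                                      index=False, float_format="%.4f")
        if report.hotspot_overlap:
            (out / "hotspot_overlap.json").write_text(json.dumps(
                {str(t): {"k": k, "m": m,
                          "fraction": None if math.isnan(f) else round(f, 4)}
                 for t, (k, m, f) in report.hotspot_overlap.items()}, indent=1))
    return report


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class AggregateReport:
    n_reports: int
    n_excluded: int
    n_with_rho: int
    mean_rho: float
    sd_rho: float
    mean_ms_int: float
    mean_ms_cons: float
    n_rho_gt1: int
    frac_rho_gt1: float
    frac_rho_1_to_1p2: float
    decile_histogram: dict[int, int]
    wilcoxon_p_rho_gt1: float

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=float)


def aggregate(reports: list[ComplexReport]) -> AggregateReport:
    """Summary statistics over per-interface reports.

    Excluded interfaces (isolated conserved residue, rho undefined) are
    counted separately and do not enter the rho statistics.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    rhos = np.array([r.rho for r in reports if not r.excluded
                     and math.isfinite(r.rho)])
    n_excluded = sum(1 for r in reports if r.excluded or not math.isfinite(r.rho))
    if rhos.size == 0:
        raise ValueError("no interface with a defined rho")
    deciles = Counter(r.decile for r in reports if r.decile is not None)
    diffs = rhos - 1.0
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs[diffs != 0], alternative="greater").pvalue)
    ms_int = np.array([r.ms_int for r in reports if math.isfinite(r.ms_int)])
    ms_cons = np.array([r.ms_cons for r in reports if math.isfinite(r.ms_cons)])
    return AggregateReport(
        n_reports=len(reports),
        n_excluded=n_excluded,
        n_with_rho=int(rhos.size),
        mean_rho=float(rhos.mean()),
        sd_rho=float(rhos.std(ddof=1)) if rhos.size > 1 else math.nan,
        mean_ms_int=float(ms_int.mean()) if ms_int.size else math.nan,
        mean_ms_cons=float(ms_cons.mean()) if ms_cons.size else math.nan,
        n_rho_gt1=int(np.sum(rhos > 1.0)),
        frac_rho_gt1=float(np.mean(rhos > 1.0)),
        frac_rho_1_to_1p2=float(np.mean((rhos > 1.0) & (rhos <= 1.2))),
        decile_histogram={d: deciles.get(d, 0) for d in range(1, 11)} if deciles else {},
        wilcoxon_p_rho_gt1=p,
    )
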