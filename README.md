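# conscluster

Spatial clustering analysis of evolutionarily conserved residues at
protein–RNA interfaces.

RNA-binding proteins feel stronger evolutionary pressure at their
binding sites than on the rest of their surface, and the conserved
interface residues are not scattered: they pack together into one or a
few spatial clusters. `conscluster` implements the full analysis
behind that observation — region classification by solvent
accessibility, per-position conservation from homolog alignments,
clustering statistics, a random-surface-patch null model that turns
the clustering signal into a binding-site predictor, and the overlap
of alanine-scanning hot spots with the conserved clusters — together
with a synthetic-data generator that plants known ground truth so the
whole pipeline is testable end to end.

## The statistics

* Residues are classified from two Shrake–Rupley SASA passes:
  **interface** (loses > 0.1 Å² of SASA when the RNA is present),
  **non-interface surface** (relative SASA > 5% in the complex), or
  **interior** (the rest).
* Conservation of alignment column *i* is the Shannon entropy over
  seven amino-acid classes,
  `s(i) = −Σ_k p_i(k) log₂ p_i(k)` ∈ [0, log₂7 ≈ 2.81 bits];
  conserved interface residues satisfy `s < ⟨s⟩_int` (criterion C1),
  `s < ⟨s⟩_int/2` (C2) or `s = 0` (C3).
* The clustering degree of a residue set is the mean inverse Cα–Cα
  distance `Ms = ⟨1/r⟩`; the ratio `ρ = Ms,cons / Ms,int` exceeds 1
  exactly when the conserved subset is more clustered than its
  interface. Conserved residues are split into sub-clusters by
  average linkage cut at 20 Å.
* The interface's ρ is ranked against ρ of 1000 random surface patches
  (three patch definitions of increasing interface fidelity) and
  summarised as a decile rank plus `Z = (⟨ρ⟩ − ρ_int)/(σ/√n)`.
* Residue-type preference in conserved clusters is the relative
  enrichment `E_X`, and hot spots (alanine-scan ΔΔG ≥ 1.0/1.5/2.0
  kcal/mol) are tested for membership in the conserved sub-clusters.

See `docs/methods.md` for assumptions, parameter defaults and the
synthetic-data design.

## Worked example

Generate a synthetic complex with a clustered conserved patch planted
in its interface, then analyse it:

```
$ conscluster simulate --seed 11 --out-dir demo
wrote synthetic complex with 159 residues, 19 interface residues to demo

$ conscluster run --pdb demo/complex.pdb --msa demo/alignment.fasta \
    --protein-chains A --rna-chains R --ddg demo/ddg.tsv \
    --out-dir demo_out --coarse --method 1 --n-patches 1000 --seed 2
rho = 1.5827  (Ms_int 0.1094, Ms_cons 0.1731, n_int 19, n_cons 3)
interface rank 1 / decile 1, z = -170.45
```

Reading: the 19 interface residues have clustering degree
Ms = 0.109 Å⁻¹; the 3 conserved ones among them (entropy below the
interface mean) are much more compact (0.173 Å⁻¹), so ρ = 1.58 — the
conserved residues cluster. Ranked by ρ against 1000 random surface
patches of the RNA-stripped protein, the real interface comes first
(decile 1), with a strongly negative Z: the clustering of conserved
residues identifies the binding site. `demo_out/` holds the per-residue
region and conservation tables, sub-cluster membership, the patch
ranking and the hot-spot overlap per ΔΔG cutoff.

The same pipeline is scriptable: `analysis/01_simulate_dataset.py`
builds panels of 30 complexes with CLUSTERED / SCATTERED / UNIFORM
conservation planting, and `analysis/02…05` reproduce the study's
analyses on them (region conservation contrast, ρ summaries per
criterion, decile histograms per patch method, enrichment and hot-spot
overlap), writing tables under `results/`. On the clustered panel the
pipeline reports mean ρ ≈ 1.5 with ρ > 1 in 100% of interfaces, while
the scattered and uniform panels stay near ρ = 1, and the region
entropies order interior < interface < surface as planted.

## Layout

```
src/conscluster/      structure, conservation, clustering, patches,
                      enrichment, synthetic, pipeline, cli
analysis/             numbered study drivers (simulate → tables)
tests/                pytest suite incl. independent numeric oracles
scripts/acceptance.py headline-number reproduction
docs/methods.md       model, parameters, design decisions, limits
```
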