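# Methods

`conscluster` quantifies how evolutionarily conserved residues are
organised within protein–RNA interfaces, and whether their spatial
clustering identifies the binding site. This note documents the model,
the tunable parameters, the synthetic-data design, numerical choices,
and the limits of what the tests demonstrate.

## Region classification

Every protein residue of a complex is assigned exactly one of three
regions from two solvent-accessible-surface-area (SASA) passes — one on
the full complex, one with the RNA chains removed:

* **interface**: SASA loss upon complexation Δ > 0.1 Å²;
* **non-interface surface**: not interface, and relative SASA in the
  complex > 5% of the residue's reference SASA in an extended
  Ala-X-Ala tripeptide;
* **interior**: everything else.

Interface is tested first; this precedence makes the three labels a
partition even for residues that would satisfy both definitions.
Relative SASA uses the *complex* SASA in the numerator (the definition
speaks of exposure "in the complex structure"); the free-protein SASA
enters only through Δ.

SASA is an internal Shrake–Rupley implementation: each atom's sphere is
expanded by the probe radius (water, 1.4 Å) and sampled with a
deterministic golden-spiral lattice (default 960 points/atom; no random
rotation, so results are bit-reproducible without a seed). Atom radii
come from a Chothia-style element table (C 1.87, N 1.65, O 1.40,
S 1.85, P 1.90 Å) with atom-name overrides; the Ala-X-Ala reference
areas follow the theoretical maximum-ASA convention (Tien et al. 2013).
Both tables ship as TSV data files and are overridable. Against an
independent dense-quadrature oracle (10,000-point equal-area lat–long
lattice), the 960-point lattice agrees to within 2% on molecule-like
test fixtures; heavily interpenetrating atom sets with slivers of a few
Å² converge more slowly, which is why the default is 960 and not less.
RNA atoms take radii from the same table — required for the complex
pass. Residues lacking a Cα are classified but excluded from all
Cα-distance statistics with a warning. Non-standard residues (MSE,
SEP, …) map to parent types via a small alias table.

## Sequence conservation

Conservation of an alignment column is the Shannon entropy of seven
amino-acid classes (Thr/Gly/Ser; Val/Ala/Ile/Cys/Met/Leu; Gln/Asn;
Glu/Asp; Trp/Tyr/Phe/Pro; His; Lys/Arg):

    s(i) = − Σ_k p_i(k) log2 p_i(k),   0 ≤ s ≤ log2 7 ≈ 2.81 bits.

Gaps and unknown symbols are excluded from the counts rather than
pooled as an eighth class, since the sum runs over residue classes
only; a column with no countable symbols is *undefined* (NaN), not 0.

Homolog filtering before entropy: drop rows with identity to the query
below 45% or with more than five missing residues; a chain is usable
only when more than five homologs survive. Two definitions the filter
needs but the convention leaves open were fixed as: identity =
exact matches at columns where both rows are non-gap, divided by the
query's non-gap length (query-relative, not pairwise-mean); missing
residues = homolog gaps at query-covered columns. Query positions map
onto structure residues by exact (or substring) sequence match, with a
pairwise-alignment fallback for tagged constructs; mismatches are
reported, never silently skipped.

Conserved interface residues are selected at three stringencies against
the interface mean entropy ⟨s⟩_int: C1 s < ⟨s⟩_int, C2 s < ⟨s⟩_int/2,
C3 s = 0. Inequalities are strict, so ties at the threshold are out and
C3 ⊆ C2 ⊆ C1 always holds. On the dichotomous synthetic alignments
(below) the three criteria coincide, because every planted conserved
position has s = 0 exactly.

## Clustering statistics

The clustering degree of a residue set is the mean inverse Cα–Cα
distance over all pairs, Ms = ⟨1/r⟩ (Å⁻¹); being an average of
*inverse* distances it is robust to a few outlying members. The ratio
ρ = Ms,cons / Ms,int compares the conserved subset with its whole
interface; ρ > 1 means clustering. Interfaces whose conserved subset
has fewer than two members are flagged excluded and skipped by the
aggregation (this is why totals shrink under C2/C3). For uniformly
random subsets of a fixed interface E[ρ] = 1 exactly, since every pair
is equally likely to be sampled — the basis of the null-calibration
test.

Sub-clusters of conserved residues come from agglomerative
average-linkage on Cα distances, cut strictly below 20 Å (the
convention derives that value as half the mean of maximum
conserved-pair distances over a reference interface set;
`auto_threshold` recomputes it for any dataset, and the maximum-pair
distance uses Cα atoms for consistency with Ms). The strict cut is
implemented by stepping scipy's `fcluster` threshold down one ulp.
Clusters are reported ordered by lowest member index for determinism.

## Surface patches and interface ranking

Random patches on the RNA-removed protein provide the null model for
binding-site identification. Surface residues are recomputed on the
free protein (relative SASA > 5%). Three patch definitions:

1. all surface residues with Cα strictly within a fixed 20 Å of a
   random surface residue (half the 40 Å mean maximum interface
   atom-pair distance);
2. the same with a per-protein radius. No formula is given for "its
   own cutoff according to its interface size", so the radius is half
   that protein's maximum interface Cα–Cα distance, mirroring the
   40 → 20 Å logic globally; configurable.
3. method-2 members minus residues whose solvent vector makes an angle
   ≥ 110° with the center's (solvent vector: from the centroid of the
   ten nearest surface neighbours to the residue's Cα), which stops
   patches from wrapping onto the opposite face.

Patch centers are drawn uniformly *with replacement*; duplicates are
allowed. Within each patch, conserved residues are selected against the
patch's own mean entropy (the within-patch analogue of C1); a global
fixed cutoff is available as an option. Patches with fewer than two
conserved residues keep ρ = 0 (ranked least clustered) so the rank
denominator stays at n + 1; a drop mode exists.

The interface is ranked among n patches in descending ρ; ties with the
interface count against it (conservative). The decile is
ceil(10·rank/(n+1)), and

    Z = (⟨ρ⟩ − ρ_int) / (σ/√n)

with ⟨ρ⟩, σ over the patch ρ values. A strongly clustered interface
makes Z large and *negative*; significance is therefore declared at
z ≤ −1.645 by default (a literal `z < 1.64` mode is available, since
that printed form circulates), alongside the exact rule ρ_int ≥ 95th
percentile of patch ρ, which is the flag reported as `significant`.

## Enrichment and hot spots

E_X = (n_X,cons/N_cons)/(n_X,int/N_int) per amino-acid type, undefined
when the type is absent from the interface; the interface-weighted
mean of E_X is identically 1, asserted to 1e−12. Alanine-scan ΔΔG
values come from a headered TSV; rows that fail to match the structure
are reported and skipped. A hot spot at cutoff t (1.0/1.5/2.0
kcal/mol) is "within the conserved clusters" when it belongs to the
conserved set after isolated-residue removal (sub-cluster size ≥ 2) —
exact membership, not proximity; an optional mode accepts residues
within d Å (default 6) of a cluster member, since the mapping rule is
otherwise unspecified.

## Synthetic data

The generator supplies complexes, alignments and ΔΔG tables with known
ground truth, so every stage is testable without downloads.

**Geometry.** The protein is Cα-only pseudo-atoms (radius 3.0 Å,
minimum separation 3.8 Å) packed by random sequential addition in a
sphere sized for a ~25% packing fraction (~16.4 Å for the default 160
residues); at this radius neighbouring spheres interpenetrate, giving a
solid blob with a real interior. The RNA is a planar 5 Å grid of P
pseudo-atoms placed against one face, its offset solved by bisection so
that a target fraction (default 0.12, echoing the ~11.6% interface
share of real complexes) of residues is in contact. Ground-truth
interface = Cα within 8.6 Å of an RNA atom (just inside the 8.8 Å
occlusion range of two expanded pseudo-spheres). Residues for which
that geometric rule and the SASA rule would disagree ambiguously — an
RNA-occluded area in (0, 1) Å², or contact without SASA loss — are
deleted, iterating to a fixpoint, and coordinates are quantised to
0.001 Å so the written PDB round-trips exactly. The planted truth is
then recovered *exactly* by the 0.1 Å² classifier, which is asserted,
not assumed. Coarse mode uses a matching radius table, a uniform
tripeptide reference of 4π(4.4)² ≈ 243 Å², and 480 quadrature points.

**Conservation.** Dichotomous columns: conserved positions carry the
query residue in every row (s = 0 exactly); variable positions draw a
class uniformly from the seven (keeping the query residue when its own
class comes up — the within-class choice cannot affect class entropy),
so s ≈ log2 7. Planting modes: CLUSTERED (interface conserved set = a
disc of default radius 8 Å around a random interface seed, capped at
80% of the interface), SCATTERED (uniform random interface subset,
default fraction 0.5) and UNIFORM (one Bernoulli rate over interface
and surface alike — the exchangeable null for decile calibration).
Interiors are conserved at rate 0.85 and non-interface surface at 0.25
in the non-uniform modes, echoing the strong interior/surface
conservation contrast of real chains and keeping row identity above
the 45% filter; rows are resampled in the rare case one falls below
it. Default 50 rows per alignment (well above the >5-homolog floor;
500 rows pin variable-column entropy to within ±0.1 of the maximum).

**ΔΔG.** Interface residues draw hot-spot status with
P(ΔΔG ≥ 2 | in cluster) = ratio × P(ΔΔG ≥ 2 | outside) (default ratio
3, base rate 0.12); hot residues draw 2 + Exp(1) kcal/mol, others
U(−0.5, 2), so threshold flags nest by construction.

All randomness flows from one spec seed through named
`SeedSequence` children (geometry, sequence, conservation, msa, ddg);
rerunning any generator with the same spec is byte-identical.

**What the synthetic data does not emulate.** No chain connectivity,
side chains, secondary structure or realistic RNA geometry; entropies
are dichotomous rather than graded, so the three conservation criteria
coincide and region mean entropies are mixture means, not the graded
values seen on real alignments. Passing tests therefore demonstrate
correctness of the statistics and the recoverability of planted
signal under the stated geometry — not performance on real complexes.

## Calibration and problem sizes

The null-calibration suite runs the full pipeline on synthetic
complexes at the default size (160 residues, ~19 interface residues):
500 UNIFORM-mode interfaces for the mean-ρ check (mean within
1.00 ± 0.05), with patch ranking (1000 patches) on 200 of them for the
decile-uniformity chi-square. Method-2 patches are used there because
their per-protein radius matches patch size to interface size, which
is what makes the interface approximately exchangeable with its null
patches; method 1 is used for the clustered-signal recovery run (100
complexes), as the fixed 20 Å radius is the definition closest to a
blind prediction setting. These sizes keep the whole suite in the
ten-minute range on one core while leaving the binomial and chi-square
tests adequately powered.

## Known limitations

* Method-2's per-protein radius uses the *real* interface extent, so
  method-2/3 patch nulls are not fully blind — inherent to the
  definition, noted for interpretation.
* The Shrake–Rupley lattice at 960 points resolves ~0.5 Å² per point
  for typical atoms; Δ-SASA thresholds well below that (the 0.1 Å²
  rule) act as "any detectable loss" at default resolution.
* `aggregate`'s Wilcoxon test treats interfaces as independent, which
  real datasets with homologous chains only approximate.
* The alignment fallback mapping refuses (rather than guesses) when
  more than 20% of aligned positions mismatch.
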