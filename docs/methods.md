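# Methods

`pscdkit` re-implements, as a tested pipeline, the analysis workflow used
to study delayed-onset post-stroke cognitive decline (PSCD): functional
brain networks from resting-state BOLD, null-normalized graph attributes,
system segregation of canonical networks, amyloid-PET SUVR and white
matter hyperintensity (WMH) quantification, and the nested case–control
statistics connecting them to cognition.  Because no patient data ship
with the package, a synthetic cohort generator produces every input with
the statistical structure the analysis assumes.  This note documents the
models, the parameters that matter, and what the synthetic results do and
do not show.

## Functional connectivity and graph attributes

Region-level BOLD time courses (time × node) are correlated pairwise
(Pearson) to give a functional connectivity (FC) matrix; Fisher's
z = atanh(r) is applied where averaging requires variance stabilization,
with |r| clipped at 1 − 10⁻⁷ so duplicated regions cannot produce
infinities.

Graphs are built by proportional thresholding: the ⌊d·n(n−1)/2⌋ strongest
*positive* correlations become edges at each density
d ∈ {0.05, 0.10, 0.15, 0.20}.  Negative correlations are never edge
candidates — strength ordering across mixed signs is ill-defined and the
segregation literature this follows uses positive weights.  Ties are
broken by lexicographic node-pair order so thresholding is deterministic.
Graphs are binary; weighted variants are out of scope.

Five attributes are computed per graph:

* characteristic path length (CPL): mean shortest-path length over
  *reachable* ordered pairs.  Thresholded FC graphs at density 0.05 are
  routinely disconnected, so unreachable pairs are excluded rather than
  failing; component structure is visible in the layouts.
* global efficiency: mean of 1/d(i,j) with 1/∞ = 0.
* modularity: best Newman–Girvan Q over restarted Louvain runs
  (default 10 restarts, seed-controlled; community detection on these
  graphs is degenerate enough that a single run is not reproducible
  across orderings).
* clustering coefficient (mean nodal) and transitivity
  (3·triangles / connected triples).

Each attribute is normalized by a degree-preserving (Maslov–Sneppen)
rewiring null: 100 null graphs by default, each produced by double-edge
swaps targeting 10 accepted swaps per edge with a bounded attempt budget.
Graphs with no valid swap (stars) return copies with a warning — the null
is degenerate, not wrong.  Normalization is raw/null-mean, except CPL
which is inverted (null-mean/raw) so that *lower = worse* holds for all
five.  The null mean (not median) is used; the null SD is retained for
diagnostics.  Quantities undefined on a graph (CPL of an edgeless graph,
transitivity without a connected triple, 0/0 ratios) are recorded as NaN,
never silently zeroed.

## System segregation

For a canonical network m with Fisher-z matrix Z:

    SysSeg(m) = (Z̄w − Z̄b) / Z̄w

where Z̄w averages z over within-m node pairs and Z̄b over pairs with one
endpoint in m and the other in any other *analysis* network.  Pairs with
z < 0 are excluded from both means (toggleable; the convention follows
the segregation literature).  The analysis set defaults to the seven
cortical networks (VN, SMN, DAN, VAN, LN, FPN, DMN); subcortical,
cerebellar and brainstem pools are excluded from between-network pairs
unless requested.  The "overall" statistic pools pairs across the
analysis set (each unordered cross pair counted once); the
mean-of-per-network alternative is available (`overall_method="mean"`).
SysSeg operates on the full z matrix, never on thresholded graphs.

## Spring-embedded layout

A Fruchterman–Reingold iteration (attraction d²/k along edges, repulsion
k²/d between all pairs, k = 1/√n, temperature cooling linearly from 0.1
to 0) with a fixed budget of 500 iterations and an early stop when the
largest displacement falls below 10⁻⁴ of the layout scale.  Isolated
nodes receive positions and are drawn as dots.  The potential
Σ d³/(3k) − Σ k² ln d decreases to equilibrium; because displacements are
capped, descent is not strictly monotone — transient upticks below about
10⁻³ of the energy scale occur and the tests allow exactly that slack.
SVG output is written with a fixed hash salt and no timestamp, so
identical inputs give byte-identical files.

## PET SUVR and WMH quantification

All volumes are assumed co-registered on one grid (spatial normalization
is out of scope).  Regional SUVR = mean tracer intensity in a labeled
region / mean intensity in the reference region (cerebellar gray matter,
supplied as an explicit label — no tissue segmentation is performed).
The global SUVR averages four composite cortical regions (frontal,
cingulate, lateral parietal, lateral temporal), each composite being the
*unweighted* mean of its member-region SUVRs; the composite → label map
is configuration, not code, since atlas numbering is data.  WMH burden is
100 × lesion∧brain voxels / brain voxels (% of parenchymal volume);
lesion voxels outside the brain mask are warned about and ignored.  The
lesion frequency map is the voxelwise count of lesions across subjects
plus the pooled lesion proportion.

## Clinical statistics

* Decliner rule: with annual rate = 12·ΔMMSE/months, a subject is a
  decliner if rate ≤ −3/yr or ΔMMSE ≤ −5; a non-decliner if rate ≥ −1/yr
  and the absolute drop is < 3; otherwise indeterminate.
* Matching: greedy 1:1 in seeded random decliner order, nearest unused
  control by |Δage| + |ΔNIHSS| within ±3 years and ±2 NIHSS points;
  unmatched decliners are reported, never force-paired.
* Group comparisons: Wilcoxon rank-sum when either group has n < 15,
  Student's t otherwise (the threshold is a config policy); χ² for
  contingency tables with Fisher's exact fallback on 2×2 tables with any
  expected cell < 5.
* Associations: Spearman's ρ by default (Pearson by flag).  Cohen's d
  uses the n−1-weighted pooled SD.
* Differential WMH effect: OLS of cognition on
  {1, WMH, group, WMH×group}; the interaction term is the headline.
* Voxel-wise amyloid model: per in-mask voxel, logistic regression of
  group (decliner = 1) on age, sex, education and voxel SUVR; Wald test
  for the SUVR coefficient; mask at *uncorrected* p < 0.05 (exploratory
  by design; an FDR option exists but is off).  Voxels with separation or
  non-convergence are flagged and excluded from the mask.  At n = 30 the
  Wald test is mildly conservative (observed null rejection ≈ 4%).

## Synthetic cohort generator

The generator defines the study conditions; everything downstream is
exercised against it.

**BOLD.**  Subject time series are draws from a zero-mean multivariate
normal whose target correlation is block-structured over a 265-region
partition into ten pools (seven cortical canonical networks plus
subcortical/cerebellum/brainstem): r_within = 0.45 inside a module,
r_between = 0.30 across modules, T = 150 volumes.  The matrix is made
positive semidefinite by eigenvalue clipping at 10⁻¹⁰, reconstruction and
re-unit diagonal.  A per-subject jitter (SD 0.03) on r_within creates
between-subject variance.

**Decliner pathology.**  Three mechanisms, chosen so the decliner group
reproduces the qualitative pattern the analysis is designed to detect —
all five normalized attributes and measured SysSeg numerically lower:

1. *Loss of distributed within-module integration*: within-module
   correlation drops by `segregation_shift` = 0.20 for node pairs more
   than `band_width` = 2 apart in node order; a local coherence band
   keeps full strength (short-range connectivity spared).
2. *Spatially contiguous disconnection*: each node receives a random 1-D
   spatial coordinate; every pair further apart than
   `spatial_range` = 0.25 is attenuated ×0.30.  The cut runs across
   module boundaries — like lesion territory crossing functional
   networks — which inflates path lengths and lowers efficiency
   relative to the rewiring null *without* creating a partition that
   Louvain rewards.
3. *Intermingled memberships*: 30% of nodes are reassigned to uniformly
   random other modules before the covariance is built.

This combination is deliberate.  Under degree-preserving normalization,
low normalized efficiency ordinarily requires dense fragmentable
communities — exactly what high normalized clustering and modularity
measure — so "everything lower at once" is impossible for a plain block
model; separating the within-module degradation (1) from a cross-cutting
disconnection (2) is what decouples the two axes.  The pattern is robust
at parcellations of ≳130 nodes where the density-0.05 graphs are not in
the extreme sparse regime.

**Clinical records.**  Covariates are drawn per group from the nested
case–control profile (decliners: age 69.2 ± 3.6, 55% female, education
8.9 ± 5.8 y, NIHSS ≈ 2.5, baseline MMSE ≈ 29, follow-up 68 ± 27 months,
WMH median 0.58% lognormal σ = 0.6, SUVR 1.29 ± 0.16; non-decliners
analogously with WMH 0.52%, SUVR 1.18 ± 0.12).  The MMSE change is

    Δ = β₀(group) + 8·(SysSeg_gen − 0.18) + β_WMH(group)·(WMH − 0.55)
        − 8·(SUVR − 1.25) + ε,   ε ~ N(0, 1)

with β_WMH = −8 for decliners and 0 for non-decliners — the WMH–cognition
coupling is decliner-specific by construction, which is what the
interaction regression is meant to detect.  Intercepts (−3.2 / −2.0) are
set so decliners lose about 6 points and non-decliners stay flat.
Because cases in a nested case–control design are ascertained by their
outcome, a subject whose simulated trajectory does not satisfy their
group's classification rule has the clinical profile redrawn (bounded
retries, then fresh noise); the generator guarantees ≥ 90% label
consistency or fails.  One ascertainment side effect: the realized
decliner WMH median sits slightly above the target (≈0.6 vs 0.58).
Effect sizes linking WMH/SUVR/segregation to decline are free parameters
of the generator, not calibrated claims about patients.

**Volumes.**  Brain = ellipsoid on a 32³ grid; labeled regions are equal
slabs; the four composite regions' intensities equal the subject's drawn
SUVR (reference = 1), plus N(0, 0.05) voxel noise, so the imaging
pipeline recovers the record's SUVR.  WMH masks are unions of small
axis-aligned blobs placed until the drawn lesion fraction is met; the
recorded WMH fraction is recomputed from the actual mask.

**Determinism.**  All randomness flows from one integer seed through
keyed `numpy` generator streams (per subject, per purpose); regeneration
is bit-identical.  Covariance streams are keyed by within-group index so
that a null configuration (zero shift, no attenuation, no mixing) yields
pairwise identical generating matrices in both groups.

## What the synthetic results show — and what they do not

The generator emulates the *statistical structure* of the study: block
FC, group-specific pathology mechanisms, outcome coupling, co-registered
volumes.  It does not emulate hemodynamics, scanner noise, anatomy, or
spatial normalization error.  Passing tests therefore demonstrate that
the pipeline measures what it claims on data with known ground truth —
not that study-scale effect sizes would replicate in patients.  Two
known exaggerations: the synthetic SysSeg group gap (≈0.0 vs ≈0.36) is
much larger than the study's (non-significant) group difference, a
by-product of making all five attribute signs reproducible; and the
efficiency group difference is small (≈0.02 on the normalized scale), so
its Cohen's d can fluctuate in sign at n ≈ 20.

## Problem sizes used in tests and the acceptance script

Desk-scale runs use proportionally scaled parcellations with the same ten
pools: 132 nodes (`half_partition`) wherever graph attributes are
compared between groups, and 69 nodes (`compact_partition`) for
record-level simulation studies.  The sign-pattern analysis uses a
15 + 15 cohort, 10 rewiring nulls and 3 Louvain restarts per graph;
interaction power uses 200 record-level replicates at 15 + 15; the
segregation-gap recovery grid uses 10 gaps at T = 2000; the voxel-wise
null calibration uses 1000 voxels at n = 30.  These sizes are the
package's defaults for reproducible desk-scale analysis; the library
itself accepts the full 265-node partition and 100-null profiles.

## Known limitations

* Binary graphs only; no weighted attributes, rich-club or nodal metrics.
* SysSeg's negative-z exclusion and pooled-overall conventions are
  defensible defaults, not the only readings; both are toggleable.
* The matching routine is greedy (optimal assignment is not implemented).
* The voxel-wise model treats voxels independently; no spatial smoothing
  or multiple-testing correction by default.
* The generator's module layout, lesion geometry and PET label scheme are
  schematic; they support pipeline validation, not anatomical inference.
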