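# pscdkit

Analysis pipeline for **delayed-onset post-stroke cognitive decline
(PSCD)**: functional brain-network construction and graph attributes with
rewiring-null normalization, system segregation of canonical resting-state
networks, amyloid-PET SUVR and white-matter-hyperintensity (WMH)
quantification, and the nested case–control statistics that relate them to
cognition.  A synthetic cohort generator produces every input the pipeline
consumes — modular BOLD time series, clinical records, PET and lesion
volumes on a shared grid — so the whole workflow is testable end to end
without patient data.

Intended for neuroimaging/stroke researchers who want a reproducible,
tested implementation of this workflow, and for method developers who need
a ground-truth cohort to validate connectome statistics against.

## The models at the core

**Functional connectivity and graph attributes.**  Region-averaged BOLD
signals are correlated pairwise (Pearson r, Fisher z = atanh r where
averaged).  Graphs keep the strongest positive correlations at densities
d ∈ {0.05, 0.10, 0.15, 0.20}; on each binary graph five attributes are
computed — characteristic path length L (inverted, so lower = worse),
global efficiency E = ⟨1/d(i,j)⟩, modularity Q (restarted Louvain),
clustering coefficient C and transitivity T — and each is normalized
against the mean of 100 degree-preserving rewired null graphs.

**System segregation.**  For a canonical network m,

```
SysSeg(m) = (Z̄w − Z̄b) / Z̄w
```

with Z̄w the mean Fisher-z connectivity within m and Z̄b the mean between
m and the other analysis networks (VN, SMN, DAN, VAN, LN, FPN, DMN);
negative z excluded by default.

**Imaging.**  Regional SUVR = regional mean uptake / cerebellar
gray-matter mean; global SUVR averages four composite cortical regions.
WMH burden = lesion voxels as % of brain parenchymal volume; cohorts are
summarized by a voxelwise lesion frequency map.

**Clinical statistics.**  Decliner = MMSE loss ≥ 3 points/year or ≥ 5
points overall; non-decliner = ≤ 1 point/year and < 3 points overall.
Controls matched on age (±3 y) and NIHSS (±2).  Group comparisons via
t/Wilcoxon and χ²/Fisher; associations via Spearman's ρ (Pearson by
flag); the decliner-specific WMH effect via a group × WMH interaction in
OLS; amyloid topography via per-voxel logistic regression
`group ~ age + sex + education + SUVR(voxel)` at uncorrected p < 0.05.

See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

```python
import pscdkit as pk
from pscdkit.clinical import rank_correlation, records_to_frame

spec = pk.CohortSpec(n_decliners=11, n_nondecliners=10,
                     partition_spec=pk.half_partition(), seed=7)
cohort = pk.generate_cohort(spec, include_volumes=False)
df = records_to_frame(cohort.records())

print(df.groupby("group")[["mmse_change", "wmh_fraction_pct", "global_suvr"]]
        .median().round(2))

dec = df[df.group == "decliner"]
rho = rank_correlation(dec.wmh_fraction_pct, dec.mmse_change)
print(f"WMH vs MMSE change in decliners: rho={rho.estimate:.2f} p={rho.p_value:.3f}")

subject = cohort.subjects[0]
fc = pk.compute_fc(subject.bold)
seg = pk.system_segregation(pk.fisher_z(fc), cohort.partition)
print(f"subject {subject.record.id}: overall SysSeg = {seg.overall['sysseg']:.3f}")

profile = pk.attribute_profile(fc, densities=(0.05, 0.10, 0.15, 0.20),
                               n_null=20, seed=0)
print(profile.to_frame().query("attribute == 'modularity'")
      [["density", "raw", "null_mean", "normalized"]].round(3).to_string(index=False))
```

prints

```
              mmse_change  wmh_fraction_pct  global_suvr
group
decliner             -7.0              0.66         1.21
non_decliner          0.0              0.61         1.12
WMH vs MMSE change in decliners: rho=-0.72 p=0.012
subject D000: overall SysSeg = 0.073
 density   raw  null_mean  normalized
    0.05 0.520      0.342       1.521
    0.10 0.483      0.227       2.128
    0.15 0.465      0.176       2.646
    0.20 0.444      0.145       3.057
```

Reading it: the simulated decliners lose about 7 MMSE points over
follow-up while matched non-decliners are flat, and within decliners the
WMH fraction tracks the decline (ρ = −0.72).  Subject D000 is a decliner:
its measured system segregation is near zero (intermingled networks), and
its modularity stays well above the rewiring-null expectation
(normalized > 1), as any correlation-derived graph's does — group
contrasts, not absolute values, carry the signal.

A command-line interface mirrors the library
(`pscdkit simulate | metrics | sysseg | layout | suvr | wmh-map |
classify | match | associate | voxel-logistic`); run `pscdkit --help`.

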