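"""Synthetic nested case-control cohort generator.

Everything the downstream pipeline consumes is generated here with the
statistical structure the analysis assumes, so the full workflow is
testable without patient data:

* region-level BOLD time series drawn from a zero-mean multivariate
  normal whose correlation is block-structured over canonical networks
  (``r_within`` inside a module, ``r_between`` across modules);
* decliners differ from non-decliners through three mechanisms --
  within-module correlation reduced by ``segregation_shift`` outside a
  local coherence band (distributed intra-network integration lost,
  short-range connectivity spared), a spatially contiguous disconnection
  factor that attenuates every correlation between nodes far apart on a
  random 1-D spatial axis (``long_range_attenuation`` /
  ``spatial_range``, emulating lesion territory cutting across
  networks), and scrambling of a fraction of node-to-module memberships
  (``mixing_fraction``, emulating intermingled canonical modules);
* clinical records whose covariate distributions follow the nested
  case-control design (ages, sex ratios, education, NIHSS, APOE,
  baseline MMSE, evaluation intervals, WMH fractions, global SUVR);
* the final MMSE is baseline plus a linear outcome model in the
  generating system segregation, WMH fraction and global SUVR (with a
  group-specific WMH slope) plus Gaussian noise, resampled a bounded
  number of times so group labels agree with the MMSE classification
  rule;
* co-registered PET/label/lesion/brain volumes on a shared grid whose
  recomputed regional SUVR and WMH fraction reproduce the record values.

One integer seed governs every stream; regeneration is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .clinical import SubjectRecord, classify_decliner
from .connectivity import BoldTimeSeries, ConnectivityMatrix, fisher_z
from .imaging import LabeledVolume, wmh_volume_fraction
from .segregation import CANONICAL_NETWORKS, CanonicalPartition, system_segregation

__all__ = [
    "DEFAULT_PARTITION",
    "compact_partition",
    "half_partition",
    "OutcomeCoefs",
    "CohortSpec",
    "SyntheticSubject",
    "SyntheticCohort",
    "psd_repair",
    "build_generating_matrix",
    "generate_block_bold",
    "generate_labeled_volumes",
    "generate_cohort",
]

#: 265-node parcellation pools: seven cortical canonical networks plus
#: subcortical / cerebellar / brainstem pools (the latter never enter SysSeg)
DEFAULT_PARTITION: tuple[tuple[str, int], ...] = (
    ("VN", 31),
    ("SMN", 37),
    ("DAN", 29),
    ("VAN", 26),
    ("LN", 17),
    ("FPN", 30),
    ("DMN", 47),
    ("subcortical", 20),
    ("cerebellum", 21),
    ("brainstem", 7),
)


def half_partition() -> tuple[tuple[str, int], ...]:
    """A 132-node partition, the ten pools at roughly half scale."""
    return (
        ("VN", 16),
        ("SMN", 18),
        ("DAN", 14),
        ("VAN", 13),
        ("LN", 9),
        ("FPN", 15),
        ("DMN", 23),
        ("subcortical", 10),
        ("cerebellum", 10),
        ("brainstem", 4),
    )


def compact_partition() -> tuple[tuple[str, int], ...]:
    """A 69-node partition with the same ten pools, for desk-scale runs."""
    return (
        ("VN", 8),
        ("SMN", 9),
        ("DAN", 7),
        ("VAN", 7),
        ("LN", 5),
        ("FPN", 8),
        ("DMN", 12),
        ("subcortical", 5),
        ("cerebellum", 5),
        ("brainstem", 3),
    )


@dataclass
class OutcomeCoefs:
    """Linear model for the MMSE change (final - baseline).

    change = intercept(group) + segregation * (SysSeg - seg_ref)
             + wmh(group) * (WMH% - wmh_ref) + suvr * (SUVR - suvr_ref) + noise

    The WMH slope is group-specific because the WMH-cognition coupling is
    a decliner-only phenomenon in the design this emulates.  Defaults are
    calibrated so decliners lose about 6 MMSE points over the follow-up
    and non-decliners stay flat.
    """

    intercept_decliner: float = -3.2
    intercept_nondecliner: float = -2.0
    segregation: float = 8.0
    wmh_decliner: float = -8.0
    wmh_nondecliner: float = 0.0
    suvr: float = -8.0
    seg_ref: float = 0.18
    wmh_ref: float = 0.55
    suvr_ref: float = 1.25

    @classmethod
    def zero(cls) -> "OutcomeCoefs":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def change(self, group: str, seg: float, wmh: float, suvr: float) -> float:
        b0 = self.intercept_decliner if group == "decliner" else self.intercept_nondecliner
        bw = self.wmh_decliner if group == "decliner" else self.wmh_nondecliner
        return (
            b0
            + self.segregation * (seg - self.seg_ref)
            + bw * (wmh - self.wmh_ref)
            + self.suvr * (suvr - self.suvr_ref)
        )


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_decliners: int = 11
    n_nondecliners: int = 10
    partition_spec: tuple[tuple[str, int], ...] = DEFAULT_PARTITION
    timepoints: int = 150
    r_within: float = 0.45
    r_between: float = 0.30
    segregation_shift: float = 0.20
    mixing_fraction: float = 0.3
    long_range_attenuation: float = 0.30
    band_width: int = 2
    spatial_range: float = 0.25
    r_within_sd: float = 0.03
    outcome_coefs: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    noise_sd: float = 1.0
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    pet_noise_sd: float = 0.05
    max_retries: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r_within < 1:
            raise ValueError("r_within must lie in [0, 1)")
        if not 0 <= self.r_between <= self.r_within:
            raise ValueError("require 0 <= r_between <= r_within")
        if not 0 <= self.mixing_fraction <= 1:
            raise ValueError("mixing_fraction must lie in [0, 1]")
        if self.segregation_shift < 0:
            raise ValueError("segregation_shift must be nonnegative")
        if self.r_within - self.segregation_shift < 0:
            raise ValueError("segregation_shift exceeds r_within")
        self.partition_spec = tuple((str(n), int(c)) for n, c in self.partition_spec)

    @property
    def n_nodes(self) -> int:
        return sum(c for _, c in self.partition_spec)

    def canonical_partition(self) -> CanonicalPartition:
        assignment: dict[int, str] = {}
        i = 0
        for name, count in self.partition_spec:
            for _ in range(count):
                assignment[i] = name
                i += 1
        analysis = tuple(m for m in CANONICAL_NETWORKS if any(n == m for n, _ in self.partition_spec))
        return CanonicalPartition(assignment, analysis)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "outcome_coefs" in data and isinstance(data["outcome_coefs"], dict):
            data["outcome_coefs"] = OutcomeCoefs(**data["outcome_coefs"])
        if "partition_spec" in data:
            data["partition_spec"] = tuple((n, c) for n, c in data["partition_spec"])
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["partition_spec"] = [list(x) for x in self.partition_spec]
        data["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# generating covariance


def psd_repair(c: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Nearest-PSD shortcut: clip eigenvalues, reconstruct, re-unit the diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    w_check = np.linalg.eigvalsh((repaired + repaired.T) / 2.0)
    if w_check.min() < -1e-8:
        raise ValueError(
            f"target correlation not PSD after repair (min eigenvalue {w_check.min():.3g})"
        )
    return (repaired + repaired.T) / 2.0


def _scramble_membership(
    module_ids: np.ndarray, fraction: float, n_modules: int, rng: np.random.Generator
) -> np.ndarray:
    out = module_ids.copy()
    k = int(round(fraction * len(module_ids)))
    if k == 0 or n_modules < 2:
        return out
    chosen = rng.choice(len(module_ids), size=k, replace=False)
    for i in chosen:
        others = [m for m in range(n_modules) if m != out[i]]
        out[i] = others[rng.integers(len(others))]
    return out


def build_generating_matrix(
    sizes: Sequence[int],
    r_within: float,
    r_between: float,
    mixing_fraction: float = 0.0,
    long_range_attenuation: float = 1.0,
    rng: np.random.Generator | None = None,
    segregation_shift: float = 0.0,
    band_width: int = 2,
    spatial_range: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Target correlation matrix: modular blocks plus decliner pathology.

    The healthy structure is block-constant: ``r_within`` inside a module,
    ``r_between`` across modules.  Three mechanisms degrade it:

    * ``mixing_fraction`` scrambles that fraction of node memberships
      before the covariance is built (intermingled canonical modules);
    * ``segregation_shift`` lowers within-module correlation for node
      pairs more than ``band_width`` apart in node order, leaving a local
      coherence band at full strength (distributed intra-network
      integration lost, short-range U-fibre connectivity spared);
    * ``long_range_attenuation`` < 1 multiplies the correlation of every
      pair whose random 1-D spatial coordinates differ by more than
      ``spatial_range`` -- a spatially contiguous disconnection that cuts
      across module boundaries, the way white-matter lesion territory
      does.

    Returns the PSD-repaired matrix and the generating module id per node.
    """
    if not 0 <= r_within < 1:
        raise ValueError("r_within must lie in [0, 1)")
    if not 0 <= r_between <= r_within:
        raise ValueError("require 0 <= r_between <= r_within")
    if segregation_shift < 0 or r_within - segregation_shift < 0:
        raise ValueError("segregation_shift must lie in [0, r_within]")
    rng = rng or np.random.default_rng(0)
    module_ids = np.concatenate([[m] * s for m, s in enumerate(sizes)]).astype(int)
    gen_ids = _scramble_membership(module_ids, mixing_fraction, len(sizes), rng)
    n = len(module_ids)
    same = gen_ids[:, None] == gen_ids[None, :]
    idx = np.arange(n)
    near = np.abs(idx[:, None] - idx[None, :]) <= band_width
    within = np.where(near, r_within, r_within - segregation_shift)
    c = np.where(same, within, r_between).astype(float)
    if long_range_attenuation < 1.0:
        u = rng.uniform(0.0, 1.0, n)
        sdist = np.abs(u[:, None] - u[None, :])
        c = c * np.where(sdist > spatial_range, long_range_attenuation, 1.0)
    np.fill_diagonal(c, 1.0)
    return psd_repair(c), gen_ids


def _sample_bold(c: np.ndarray, timepoints: int, rng: np.random.Generator) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    return rng.standard_normal((timepoints, c.shape[0])) @ factor.T


def generate_block_bold(
    partition_spec: Sequence[tuple[str, int]],
    timepoints: int,
    r_within: float,
    r_between: float,
    mixing_fraction: float = 0.0,
    seed: int = 0,
    long_range_attenuation: float = 1.0,
    segregation_shift: float = 0.0,
    band_width: int = 2,
    spatial_range: float = 0.25,
) -> BoldTimeSeries:
    """Draw a time x node BOLD matrix with block-correlation structure."""
    sizes = [int(c) for _, c in partition_spec]
    n = sum(sizes)
    if timepoints < n:
        import warnings

        warnings.warn(
            f"timepoints ({timepoints}) below node count ({n}); "
            "sample correlations will be noisy"
        )
    rng = np.random.default_rng([seed, 1])
    c, _ = build_generating_matrix(
        sizes, r_within, r_between, mixing_fraction, long_range_attenuation, rng,
        segregation_shift=segregation_shift, band_width=band_width,
        spatial_range=spatial_range,
    )
    values = _sample_bold(c, timepoints, np.random.default_rng([seed, 2]))
    labels = [f"{name}_{i:03d}" for name, cnt in partition_spec for i in range(cnt)]
    return BoldTimeSeries(values, labels)


# ---------------------------------------------------------------------------
# volumes


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    centers = [(s - 1) / 2.0 for s in shape]
    radii = [max(s / 2.0 - 1.5, 1.0) for s in shape]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centers, radii))
    return r2 <= 1.0


def generate_labeled_volumes(
    grid_shape: tuple[int, int, int],
    region_means: dict[int, float],
    reference_label: int,
    reference_mean: float,
    lesion_count: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    lesion_edge: int = 3,
) -> tuple[LabeledVolume, LabeledVolume, LabeledVolume, LabeledVolume]:
    """Intensity, label, lesion-mask and brain-mask volumes on one grid.

    The brain is an ellipsoid; labeled regions are equal slabs of brain
    voxels; voxel intensity is the region mean plus optional Gaussian
    noise.  Lesions are ``lesion_count`` axis-aligned cubes of edge
    ``lesion_edge`` fully inside the brain.
    """
    if reference_label in region_means:
        raise ValueError("reference_label must not also appear in region_means")
    if any(l <= 0 for l in region_means) or reference_label <= 0:
        raise ValueError("region labels must be positive integers")
    rng = np.random.default_rng([seed, 7])
    brain = _ellipsoid_mask(grid_shape)
    flat_idx = np.flatnonzero(brain.ravel())
    all_labels = sorted(region_means) + [reference_label]
    labels = np.zeros(grid_shape, dtype=np.int32).ravel()
    for part, lab in zip(np.array_split(flat_idx, len(all_labels)), all_labels):
        labels[part] = lab
    labels = labels.reshape(grid_shape)
    means = dict(region_means)
    means[reference_label] = reference_mean
    pet = np.zeros(grid_shape, dtype=float)
    for lab, mu in means.items():
        pet[labels == lab] = mu
    if noise_sd > 0:
        pet = pet + rng.normal(0.0, noise_sd, size=grid_shape)
    pet[~brain] = 0.0

    lesion = np.zeros(grid_shape, dtype=np.int8)
    half = lesion_edge // 2
    lo = [half] * 3
    hi = [s - (lesion_edge - half) for s in grid_shape]
    if any(h <= l for l, h in zip(lo, hi)) and lesion_count > 0:
        raise ValueError("grid too small to place the requested lesions")
    placed = 0
    attempts = 0
    while placed < lesion_count:
        attempts += 1
        if attempts > 200 * max(lesion_count, 1):
            raise ValueError("grid too small to place the requested lesions inside the brain")
        center = [int(rng.integers(l, h)) for l, h in zip(lo, hi)]
        sl = tuple(slice(c - half, c - half + lesion_edge) for c in center)
        if not brain[sl].all():
            continue
        lesion[sl] = 1
        placed += 1
    lesion[~brain] = 0
    mk = lambda a: LabeledVolume(a, space_tag="synthetic-grid")
    return mk(pet), mk(labels), mk(lesion), mk(brain.astype(np.int8))


#: labels 1-4 are the four composite cortical regions of the global SUVR
COMPOSITE_MAP: dict[str, list[int]] = {
    "frontal": [1],
    "cingulate": [2],
    "lateral_parietal": [3],
    "lateral_temporal": [4],
}
REFERENCE_LABEL = 9  # cerebellar gray matter stand-in


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    generating_segregation: float
    bold: BoldTimeSeries | None = None
    pet_volume: LabeledVolume | None = None
    label_volume: LabeledVolume | None = None
    lesion_mask: LabeledVolume | None = None
    brain_mask: LabeledVolume | None = None


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    partition: CanonicalPartition
    spec: CohortSpec
    label_consistency: float = 1.0

    def records(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]

    def by_group(self, group: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.record.group == group]

    def write(self, out_dir: str | Path) -> Path:
        """Write BOLD (TSV), volumes (NIfTI), records (CSV) and a manifest."""
        from .clinical import records_to_frame

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, object] = {"subjects": {}}
        records_to_frame(self.records()).to_csv(out / "records.csv", index=False)
        manifest["records"] = "records.csv"
        node_labels = [
            f"{name}_{i:03d}" for name, cnt in self.spec.partition_spec for i in range(cnt)
        ]
        part_rows = [
            {"node": node_labels[i], "network": self.partition.assignment[i]}
            for i in range(len(self.partition.assignment))
        ]
        pd.DataFrame(part_rows).to_csv(out / "partition.tsv", sep="\t", index=False, header=False)
        manifest["partition"] = "partition.tsv"
        for s in self.subjects:
            sid = s.record.id
            entry: dict[str, str] = {}
            if s.bold is not None:
                p = f"{sid}_bold.tsv"
                pd.DataFrame(s.bold.values, columns=s.bold.node_labels).to_csv(
                    out / p, sep="\t", index=False
                )
                entry["bold"] = p
            for name, vol in (
                ("pet", s.pet_volume),
                ("labels", s.label_volume),
                ("lesion", s.lesion_mask),
                ("brain", s.brain_mask),
            ):
                if vol is not None:
                    p = f"{sid}_{name}.nii.gz"
                    vol.to_nifti(out / p)
                    entry[name] = p
            manifest["subjects"][sid] = entry
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out / "manifest.json"


def _generating_segregation(
    c: np.ndarray, partition: CanonicalPartition, node_labels: list[str]
) -> float:
    cm = ConnectivityMatrix(c, node_labels, scale="pearson_r")
    res = system_segregation(fisher_z(cm), partition)
    return float(res.overall["sysseg"])


def _draw_clinical(group: str, rng: np.random.Generator) -> dict:
    dec = group == "decliner"
    return {
        "age_years": float(np.clip(rng.normal(69.2 if dec else 66.7, 3.63 if dec else 9.02), 45, 90)),
        "sex": "F" if rng.random() < (0.545 if dec else 0.10) else "M",
        "education_years": float(np.clip(rng.normal(8.9 if dec else 10.9, 5.8), 0, 22)),
        "nihss_baseline": float(np.clip(np.round(rng.normal(2.5 if dec else 4.0, 2.0)), 0, 20)),
        "apoe_e4": bool(rng.random() < (1 / 11 if dec else 2 / 10)),
        "mmse_baseline": float(np.clip(np.round(rng.normal(28.7 if dec else 26.8, 1.0 if dec else 1.6)), 23, 30)),
        "interval_months": float(np.clip(rng.normal(68.3 if dec else 67.8, 26.8 if dec else 25.2), 14, 130)),
        "wmh_draw_pct": float(np.clip((0.58 if dec else 0.52) * np.exp(rng.normal(0.0, 0.6)), 0.02, 5.0)),
        "global_suvr": float(np.clip(rng.normal(1.29 if dec else 1.18, 0.16 if dec else 0.12), 0.9, 2.0)),
    }


def generate_cohort(
    spec: CohortSpec,
    include_bold: bool = True,
    include_volumes: bool = True,
    enforce_label_consistency: bool = True,
) -> SyntheticCohort:
    """Generate the full synthetic cohort for one CohortSpec.

    ``include_bold`` / ``include_volumes`` switch off the expensive
    artifacts for record-level simulation studies; the clinical record
    streams are identical either way.  With volumes enabled, the recorded
    WMH fraction is recomputed from the actual lesion mask (the mask is
    built to hit the drawn fraction up to blob-placement rounding) so the
    record and the imaging pipeline agree.
    """
    sizes = [c for _, c in spec.partition_spec]
    partition = spec.canonical_partition()
    node_labels = [f"{name}_{i:03d}" for name, cnt in spec.partition_spec for i in range(cnt)]
    seed = int(spec.seed)
    subjects: list[SyntheticSubject] = []
    n_consistent = 0
    groups = [("decliner", spec.n_decliners, 0), ("non_decliner", spec.n_nondecliners, 1)]
    for group, n_sub, gidx in groups:
        dec = group == "decliner"
        for j in range(n_sub):
            # the covariance stream is shared across groups (keyed by the
            # within-group index) so a null configuration yields pairwise
            # identical generating matrices in both groups
            cov_rng = np.random.default_rng([seed, 101, j])
            mix_rng = np.random.default_rng([seed, 202, gidx, j])
            clin_rng = np.random.default_rng([seed, 303, gidx, j])
            noise_rng = np.random.default_rng([seed, 606, gidx, j])

            r_w = spec.r_within + cov_rng.normal(0.0, spec.r_within_sd)
            r_w = float(np.clip(r_w, spec.r_between + 1e-3, 0.97))
            c, _ = build_generating_matrix(
                sizes, r_w, spec.r_between,
                mixing_fraction=spec.mixing_fraction if dec else 0.0,
                long_range_attenuation=spec.long_range_attenuation if dec else 1.0,
                rng=mix_rng,
                segregation_shift=spec.segregation_shift if dec else 0.0,
                band_width=spec.band_width,
                spatial_range=spec.spatial_range,
            )
            gen_seg = _generating_segregation(c, partition, node_labels)

            sid = f"{'D' if dec else 'N'}{j:03d}"

            # nested case-control ascertainment: subjects are selected
            # *because* of their outcome, so a straggler's whole clinical
            # profile is redrawn (bounded), then the MMSE noise resampled
            clin = None
            mmse_final = None
            assigned = None
            for _ in range(spec.max_retries):
                clin = _draw_clinical(group, clin_rng)
                mu = spec.outcome_coefs.change(
                    group, gen_seg, clin["wmh_draw_pct"], clin["global_suvr"]
                )
                for _ in range(20):
                    eps = noise_rng.normal(0.0, spec.noise_sd)
                    mmse_final = float(
                        np.clip(np.round(clin["mmse_baseline"] + mu + eps), 0, 30)
                    )
                    assigned = classify_decliner(
                        clin["mmse_baseline"], mmse_final, clin["interval_months"]
                    )
                    if assigned == group:
                        break
                if assigned == group:
                    break
            if assigned == group:
                n_consistent += 1

            volumes: dict[str, LabeledVolume | None] = dict.fromkeys(
                ("pet", "labels", "lesion", "brain")
            )
            wmh_pct = clin["wmh_draw_pct"]
            if include_volumes:
                suvr = clin["global_suvr"]
                region_means = {1: suvr, 2: suvr, 3: suvr, 4: suvr, 5: 1.05, 6: 1.05, 7: 1.0, 8: 1.0}
                brain_voxels = int(_ellipsoid_mask(spec.grid_shape).sum())
                target_voxels = wmh_pct / 100.0 * brain_voxels
                lesion_count = max(0, int(round(target_voxels / 8.0)))
                pet, labels_vol, lesion, brain = generate_labeled_volumes(
                    spec.grid_shape,
                    region_means,
                    REFERENCE_LABEL,
                    1.0,
                    lesion_count,
                    seed=seed * 131 + gidx * 1009 + j,
                    noise_sd=spec.pet_noise_sd,
                    lesion_edge=2,
                )
                volumes = {"pet": pet, "labels": labels_vol, "lesion": lesion, "brain": brain}
                wmh_pct = wmh_volume_fraction(lesion, brain)

            record = SubjectRecord(
                id=sid,
                group=group,
                age_years=clin["age_years"],
                sex=clin["sex"],
                education_years=clin["education_years"],
                nihss_baseline=clin["nihss_baseline"],
                mmse_baseline=clin["mmse_baseline"],
                mmse_final=mmse_final,
                interval_months=clin["interval_months"],
                wmh_fraction_pct=float(wmh_pct),
                global_suvr=clin["global_suvr"],
                apoe_e4=clin["apoe_e4"],
            )
            bold = None
            if include_bold:
                bold_rng = np.random.default_rng([seed, 404, gidx, j])
                bold = BoldTimeSeries(_sample_bold(c, spec.timepoints, bold_rng), node_labels)
            subjects.append(
                SyntheticSubject(
                    record=record,
                    generating_segregation=gen_seg,
                    bold=bold,
                    pet_volume=volumes["pet"],
                    label_volume=volumes["labels"],
                    lesion_mask=volumes["lesion"],
                    brain_mask=volumes["brain"],
                )
            )
    total = spec.n_decliners + spec.n_nondecliners
    consistency = n_consistent / total if total else 1.0
    if enforce_label_consistency and consistency < 0.9:
        raise RuntimeError(
            f"unsatisfiable cohort spec: only {n_consistent}/{total} subjects "
            "classify into their generating group after bounded resampling; "
            "the outcome model cannot produce the required MMSE trajectories"
        )
    return SyntheticCohort(subjects, partition, spec, consistency)
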