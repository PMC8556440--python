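"""Full study replica: cohort simulation, quantification, statistics, dose.

``run_study`` simulates a cohort on the standard acquisition schedule
(8 scans per patient: four early scans within 0.5 h at 30 s/bp, then
1 h / 2 h / 3.5 h at 120 s/bp and 5.5 h at 180 s/bp; scans from 0.5 h on
are rebinned into shorter durations), measures left/right renal VOI
activities on per-acquisition segmentations, builds the per-patient LRU%
variability table, runs the nonparametric statistical battery, and
attaches the pediatric dose budget.

Randomness policy: a single study-level ``master_seed``; every per-patient
and per-frame random stream is an independent ``numpy`` ``SeedSequence``
derived as ``SeedSequence(master_seed, spawn_key=(patient, time_index,
duration, stream_tag))``, so re-running with the same config and seed
reproduces every output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .acquisition import perturb_mask, rebin_frame, simulate_acquisition
from .cohort_stats import pairwise_to_frame, report_to_json_dict, run_study_tests
from .dosimetry import DoseModel, dose_budget
from .phantom import (
    Biokinetics,
    BloodCurve,
    TissueCurve,
    build_phantom,
    default_phantom_spec,
)
from .quantify import (
    TissueConcInputs,
    lru_percent,
    measure_voi,
    noise_metric,
    peak_time,
    summarize_cohort,
    tissue_concentration,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "expected_series_count",
    "simulate_lru_replicates",
    "simulate_cv_replicates",
    "simulate_null_lru_table",
    "load_table2_fixture",
    "table2_aggregates",
]

log = logging.getLogger(__name__)

TABLE2_SHA256 = "68f3ee57fd5e2e3e9ee0d25b1a1f263b4bc3a3c6763c533352630c90e8d411f5"

# Stream tags for seed splitting (4th spawn-key component).
_TAG_BIOLOGY = 0
_TAG_FRAME = 1
_TAG_MASK = 2


@dataclass(frozen=True)
class StudyConfig:
    """Design of the simulated cohort study."""

    n_patients: int = 12
    #: minutes p.i. of the 8 scans; the four early points (<= 0.5 h) are
    #: declared config, only 0.5/1/2/3.5/5.5 h are protocol facts.
    time_points_pi: tuple[float, ...] = (5, 12, 20, 30, 60, 120, 210, 330)
    native_durations: tuple[float, ...] = (30, 30, 30, 30, 120, 120, 120, 180)
    #: per-time-point rebinned durations; the first three early scans are
    #: not rebinned (too little uptake for useful short frames).
    rebin_durations: tuple[tuple[float, ...], ...] = (
        (),
        (),
        (),
        (10, 20),
        (10, 20, 30, 60, 90),
        (10, 20, 30, 60, 90),
        (10, 20, 30, 60, 90),
        (10, 20, 30, 60, 90, 120),
    )
    injected_activity: float = 4.0  # MBq/kg
    activity_jitter_sd: float = 0.4  # MBq/kg between patients
    activity_range: tuple[float, float] = (3.4, 5.1)
    split_mean: float = 0.483
    split_sd: float = 0.03
    #: patient ids (1-based) with an extreme near-zero left split.
    extreme_split_patient_ids: tuple[int, ...] = (8,)
    extreme_split: float = 0.058
    patient_mass_mean: float = 80.0  # kg
    patient_mass_sd: float = 10.0
    #: segmentation boundary jitter per acquisition, mm; the dominant
    #: LRU% variability source (counting noise alone is ~0.03 pp here).
    segmentation_noise_mm: float = 1.25
    sensitivity: float = 5.0  # counts per (kBq s)
    psf_fwhm: float = 5.0  # mm
    voxel_size: float = 4.0  # mm
    blood_sample_cv: float = 0.02
    uptake_rate_sigma: float = 0.4  # lognormal jitter of tissue uptake rate
    amplitude_sigma: float = 0.15  # lognormal jitter of curve amplitudes
    poisson_noise: bool = True
    master_seed: int = 1234
    #: (patient_id, time_pi) pairs whose list-mode files were lost: the
    #: native reconstruction is kept, the rebinned children are dropped.
    missing_rebins: tuple[tuple[int, float], ...] = ((4, 120), (9, 120))
    schema_version: int = 1

    def __post_init__(self):
        object.__setattr__(self, "time_points_pi", tuple(float(t) for t in self.time_points_pi))
        object.__setattr__(self, "native_durations", tuple(float(d) for d in self.native_durations))
        object.__setattr__(
            self,
            "rebin_durations",
            tuple(tuple(float(d) for d in r) for r in self.rebin_durations),
        )
        object.__setattr__(
            self,
            "missing_rebins",
            tuple((int(p), float(t)) for p, t in self.missing_rebins),
        )
        object.__setattr__(self, "activity_range", tuple(float(a) for a in self.activity_range))
        object.__setattr__(
            self,
            "extreme_split_patient_ids",
            tuple(int(p) for p in self.extreme_split_patient_ids),
        )
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        t = self.time_points_pi
        if len(t) != len(self.native_durations) or len(t) != len(self.rebin_durations):
            raise ValueError("time grid, durations and rebins must have equal length")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time points must be strictly increasing")
        for native, rebins in zip(self.native_durations, self.rebin_durations):
            if native <= 0:
                raise ValueError("native durations must be positive")
            if any(not 0 < d <= native for d in rebins):
                raise ValueError(
                    f"rebin durations {rebins} must be in (0, native {native}]"
                )
        if not 0 < self.split_mean < 1 or not 0 < self.extreme_split < 1:
            raise ValueError("split fractions must be in (0, 1)")
        if self.injected_activity <= 0 or self.sensitivity <= 0:
            raise ValueError("activity and sensitivity must be positive")
        if self.segmentation_noise_mm < 0 or self.voxel_size <= 0:
            raise ValueError("noise and voxel size must be nonnegative/positive")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["rebin_durations"] = [list(r) for r in out["rebin_durations"]]
        out["missing_rebins"] = [list(m) for m in out["missing_rebins"]]
        for key in ("time_points_pi", "native_durations", "activity_range",
                    "extreme_split_patient_ids"):
            out[key] = list(out[key])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        version = data.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported study config schema version {version}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown study config keys: {sorted(unknown)}")
        return cls(schema_version=version, **data)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        return cls.from_dict(_io.load_config(path))

    def mask_group(self, time_index: int) -> int:
        """Early scans (< 0.5 h) reuse the 0.5 h segmentation."""
        t = self.time_points_pi[time_index]
        early = [i for i, tp in enumerate(self.time_points_pi) if tp <= 30.0]
        if t <= 30.0 and early:
            return early[-1]
        return time_index


def expected_series_count(config: StudyConfig) -> int:
    """Combinatorial series count implied by the config grid."""
    per_patient = sum(1 + len(r) for r in config.rebin_durations)
    total = config.n_patients * per_patient
    for pid, t in config.missing_rebins:
        if pid <= config.n_patients and t in config.time_points_pi:
            total -= len(config.rebin_durations[config.time_points_pi.index(t)])
    return total


def _seed(config: StudyConfig, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(config.master_seed, spawn_key=tuple(key))


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    return float(np.clip(mean, lo, hi))


@dataclass
class PatientBiology:
    patient_id: int
    split_fraction_left: float
    dose_mbq_per_kg: float
    mass_kg: float
    kinetics: Biokinetics


def _draw_patient(config: StudyConfig, patient_id: int) -> PatientBiology:
    rng = np.random.default_rng(_seed(config, patient_id, 0, 0, _TAG_BIOLOGY))
    if patient_id in config.extreme_split_patient_ids:
        split = config.extreme_split
    else:
        split = _truncated_normal(rng, config.split_mean, config.split_sd, 0.02, 0.98)
    dose = _truncated_normal(
        rng, config.injected_activity, config.activity_jitter_sd, *config.activity_range
    )
    mass = _truncated_normal(
        rng, config.patient_mass_mean, config.patient_mass_sd, 50.0, 120.0
    )
    base_t, base_b = TissueCurve(), BloodCurve()
    kin = Biokinetics(
        tissue=TissueCurve(
            amplitude=base_t.amplitude * rng.lognormal(0.0, config.amplitude_sigma),
            uptake_rate=base_t.uptake_rate * rng.lognormal(0.0, config.uptake_rate_sigma),
            washout_rate=base_t.washout_rate,
        ),
        blood=BloodCurve(
            amplitude=base_b.amplitude * rng.lognormal(0.0, config.amplitude_sigma),
        ),
    )
    return PatientBiology(patient_id, split, dose, mass, kin)


@dataclass
class StudyResult:
    """Bundle of everything the study replica produces."""

    config: StudyConfig
    lru_table: pd.DataFrame
    summaries: pd.DataFrame
    normalized: pd.DataFrame
    stats_report: dict
    dose_budget: dict
    tissue_conc: pd.DataFrame
    noise_cv: pd.DataFrame
    series_log: pd.DataFrame
    patients: list

    @property
    def n_series(self) -> int:
        return len(self.lru_table)

    def peak_times(self) -> pd.DataFrame:
        rows = []
        for pid, grp in self.tissue_conc.groupby("patient_id"):
            rows.append(
                {
                    "patient_id": pid,
                    "peak_time_pi": peak_time(
                        grp["time_pi"].to_numpy(), grp["c_tissue"].to_numpy()
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.lru_table.to_csv(outdir / "lru_table.csv", index=False)
        self.summaries.to_csv(outdir / "patient_summaries.csv", index=False)
        self.normalized.to_csv(outdir / "normalized_lru.csv", index=False)
        self.tissue_conc.to_csv(outdir / "tissue_concentration.csv", index=False)
        self.noise_cv.to_csv(outdir / "noise_cv.csv", index=False)
        self.series_log.to_csv(outdir / "series_log.csv", index=False)
        self.peak_times().to_csv(outdir / "peak_times.csv", index=False)
        pairwise_to_frame(self.stats_report["dunn"]["time_pi"]).to_csv(
            outdir / "dunn_time_points.csv", index=False
        )
        (outdir / "stats_report.json").write_text(
            json.dumps(report_to_json_dict(self.stats_report), indent=2)
        )
        (outdir / "dose_budget.json").write_text(json.dumps(self.dose_budget, indent=2))
        _io.dump_config(self.config.to_dict(), outdir / "study_config.yaml")


def run_study(
    config: StudyConfig | None = None,
    outdir=None,
    save_volumes: bool = False,
    dose_model: DoseModel | None = None,
) -> StudyResult:
    """Run the full study replica; deterministic for a fixed master seed."""
    if config is None:
        config = StudyConfig()
    config.validate()
    lru_rows, tissue_rows, cv_rows, log_rows = [], [], [], []
    patients = [_draw_patient(config, pid) for pid in range(1, config.n_patients + 1)]

    for bio in patients:
        pid = bio.patient_id
        spec = default_phantom_spec(
            split_fraction_left=bio.split_fraction_left,
            voxel_size=config.voxel_size,
            patient_mass=bio.mass_kg,
        )
        phantom = build_phantom(spec, bio.kinetics, bio.dose_mbq_per_kg)
        gt_masks = {s: phantom.kidney_mask(s) for s in ("left", "right")}
        blood_rng = np.random.default_rng(_seed(config, pid, 0, 1, _TAG_BIOLOGY))

        masks = {}  # mask-group index -> {side: mask}
        for t_idx in range(len(config.time_points_pi)):
            g = config.mask_group(t_idx)
            if g in masks:
                continue
            if config.segmentation_noise_mm > 0:
                masks[g] = {
                    side: perturb_mask(
                        gt_masks[side],
                        config.segmentation_noise_mm,
                        config.voxel_size,
                        seed=_seed(config, pid, g, i, _TAG_MASK),
                    )
                    for i, side in enumerate(("left", "right"))
                }
            else:
                masks[g] = gt_masks

        for t_idx, t in enumerate(config.time_points_pi):
            native_d = config.native_durations[t_idx]
            truth = phantom.truth(t)
            pair = masks[config.mask_group(t_idx)]
            frame = simulate_acquisition(
                truth,
                time_pi=t,
                duration=native_d,
                sensitivity=config.sensitivity,
                psf_fwhm=config.psf_fwhm,
                voxel_size=config.voxel_size,
                seed=_seed(config, pid, t_idx, int(native_d), _TAG_FRAME),
                poisson=config.poisson_noise,
                frame_id=f"p{pid}_t{int(t)}_d{int(native_d)}",
            )
            lost = (pid, t) in config.missing_rebins
            rebins = () if lost else config.rebin_durations[t_idx]

            def record(fr):
                left = measure_voi(fr, pair["left"], side="left")
                right = measure_voi(fr, pair["right"], side="right")
                lru = lru_percent(left.activity_mbq, right.activity_mbq)
                lru_rows.append(
                    {
                        "patient_id": pid,
                        "time_pi": fr.time_pi,
                        "duration": fr.duration,
                        "lru_percent": lru,
                        "left_mbq": left.activity_mbq,
                        "right_mbq": right.activity_mbq,
                    }
                )
                cv_rows.append(
                    {
                        "patient_id": pid,
                        "time_pi": fr.time_pi,
                        "duration": fr.duration,
                        "cv": noise_metric(fr, pair["left"]),
                    }
                )
                log_rows.append(
                    {
                        "patient_id": pid,
                        "time_pi": fr.time_pi,
                        "duration": fr.duration,
                        "frame_id": fr.frame_id,
                        "parent_id": fr.parent_id or "",
                        "total_counts": float(np.asarray(fr.counts).sum()),
                    }
                )
                log.info(
                    "frame patient=%d t=%.0fmin d=%.0fs counts=%.3g",
                    pid, fr.time_pi, fr.duration, float(np.asarray(fr.counts).sum()),
                )
                return left, right

            left, right = record(frame)
            if save_volumes and outdir is not None:
                vol_dir = Path(outdir) / "volumes"
                vol_dir.mkdir(parents=True, exist_ok=True)
                _io.save_nifti(frame.values, config.voxel_size, vol_dir / f"{frame.frame_id}.nii.gz")

            # Blood-corrected tissue concentration from the native series.
            vol = left.volume_ml + right.volume_ml
            c_kidney = (left.activity_mbq + right.activity_mbq) * 1000.0 / vol
            c_blood = float(
                bio.kinetics.blood_conc(t, bio.dose_mbq_per_kg)
            ) * blood_rng.lognormal(0.0, config.blood_sample_cv)
            # negative-tissue warnings are expected for very early frames
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                c_tissue = tissue_concentration(
                    TissueConcInputs(c_kidney, c_blood, spec.blood_fraction)
                )
            tissue_rows.append(
                {
                    "patient_id": pid,
                    "time_pi": t,
                    "c_kidney": c_kidney,
                    "c_blood": c_blood,
                    "c_tissue": c_tissue,
                }
            )

            parent = frame
            for d in sorted(rebins, reverse=True):
                parent = rebin_frame(
                    parent,
                    d,
                    seed=_seed(config, pid, t_idx, int(d), _TAG_FRAME),
                    poisson=config.poisson_noise,
                    frame_id=f"p{pid}_t{int(t)}_d{int(d)}",
                )
                record(parent)

    lru_table = pd.DataFrame(lru_rows)
    stats_report = run_study_tests(lru_table)
    from .cohort_stats import normalize_to_patient_median

    result = StudyResult(
        config=config,
        lru_table=lru_table,
        summaries=summarize_cohort(lru_table),
        normalized=normalize_to_patient_median(lru_table),
        stats_report=stats_report,
        dose_budget=dose_budget(dose_model or DoseModel()),
        tissue_conc=pd.DataFrame(tissue_rows),
        noise_cv=pd.DataFrame(cv_rows),
        series_log=pd.DataFrame(log_rows),
        patients=patients,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def simulate_lru_replicates(
    split_fraction_left: float = 0.483,
    time_pi: float = 60.0,
    duration: float = 60.0,
    n_replicates: int = 200,
    voxel_size: float = 6.0,
    sensitivity: float = 5.0,
    psf_fwhm: float = 5.0,
    dose_mbq_per_kg: float = 4.0,
    seed=0,
) -> np.ndarray:
    """Replicate LRU% measurements of one acquisition with ground-truth masks.

    Used for split-fraction recovery and counting-noise studies; the truth
    volume is computed once and only the Poisson realization varies.
    """
    spec = default_phantom_spec(split_fraction_left, voxel_size=voxel_size)
    phantom = build_phantom(spec, Biokinetics(), dose_mbq_per_kg)
    truth = phantom.truth(time_pi)
    masks = {s: phantom.kidney_mask(s) for s in ("left", "right")}
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        frame = simulate_acquisition(
            truth, time_pi, duration, sensitivity, psf_fwhm, voxel_size, seed=rng
        )
        left = measure_voi(frame, masks["left"])
        right = measure_voi(frame, masks["right"])
        out[i] = lru_percent(left.activity_mbq, right.activity_mbq)
    return out


def simulate_cv_replicates(
    duration: float,
    dose_mbq_per_kg: float = 4.0,
    time_pi: float = 60.0,
    n_replicates: int = 100,
    voxel_size: float = 6.0,
    sensitivity: float = 5.0,
    psf_fwhm: float = 5.0,
    seed=0,
) -> np.ndarray:
    """Replicate VOI coefficient-of-variation measurements at one setting."""
    spec = default_phantom_spec(voxel_size=voxel_size)
    phantom = build_phantom(spec, Biokinetics(), dose_mbq_per_kg)
    truth = phantom.truth(time_pi)
    mask = phantom.kidney_mask("left")
    rng = np.random.default_rng(seed)
    return np.array(
        [
            noise_metric(
                simulate_acquisition(
                    truth, time_pi, duration, sensitivity, psf_fwhm, voxel_size, seed=rng
                ),
                mask,
            )
            for _ in range(n_replicates)
        ]
    )


def simulate_null_lru_table(
    n_patients: int = 12,
    n_time_points: int = 8,
    n_durations: int = 5,
    mean_total_counts: float = 2.0e5,
    split_mean: float = 0.483,
    split_sd: float = 0.03,
    time_shift_pp: dict | None = None,
    rng=None,
) -> pd.DataFrame:
    """VOI-count-level cohort simulation on a balanced homogeneous grid.

    Every (patient, time, duration) cell draws left/right VOI counts as
    ``Poisson(f C)`` / ``Poisson((1 - f) C)`` with the same total ``C``, so
    with no injected effect the values are identically distributed across
    time points and durations (the exact Kruskal-Wallis null).  Meant for
    statistical calibration studies, not for imaging realism.
    ``time_shift_pp`` maps a time index to an LRU% shift in percentage
    points, to inject a time effect for power studies.
    """
    rng = np.random.default_rng(rng)
    shifts = time_shift_pp or {}
    rows = []
    for pid in range(1, n_patients + 1):
        f = float(np.clip(rng.normal(split_mean, split_sd), 0.02, 0.98))
        for t_idx in range(n_time_points):
            for d_idx in range(n_durations):
                left = rng.poisson(f * mean_total_counts)
                right = rng.poisson((1.0 - f) * mean_total_counts)
                lru = lru_percent(left, right) + shifts.get(t_idx, 0.0)
                rows.append(
                    {
                        "patient_id": pid,
                        "time_pi": float(t_idx),
                        "duration": float(d_idx),
                        "lru_percent": lru,
                    }
                )
    return pd.DataFrame(rows)


def load_table2_fixture() -> pd.DataFrame:
    """Packaged per-patient LRU% summary table (printed values, verbatim).

    Columns: patient_id, median_lru, sd_lru, range_min, range_max,
    delta_max.  The printed delta max was computed from unrounded data and
    may differ from ``range_max - range_min`` by up to 0.1 due to rounding;
    the loader checks this consistency and a file checksum.
    """
    path = resources.files("renalpet.data") / "table2_lru.csv"
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE2_SHA256:
        raise ValueError(
            f"fixture checksum mismatch: {digest} != expected {TABLE2_SHA256}"
        )
    df = pd.read_csv(path.open("r"))
    mismatch = (df["delta_max"] - (df["range_max"] - df["range_min"])).abs()
    if (mismatch > 0.15).any():
        raise ValueError("fixture delta_max inconsistent with its range column")
    return df


def table2_aggregates(df: pd.DataFrame | None = None) -> dict:
    """Cohort-level aggregates of the per-patient summary table."""
    if df is None:
        df = load_table2_fixture()
    return {
        "delta_max_min": float(df["delta_max"].min()),
        "delta_max_max": float(df["delta_max"].max()),
        "lru_min": float(df["range_min"].min()),
        "lru_max": float(df["range_max"].max()),
        "sd_max": float(df["sd_lru"].max()),
        "n_patients_delta_max_gt5": int((df["delta_max"] > 5.0).sum()),
        "median_of_medians": float(df["median_lru"].median()),
    }
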