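"""VOI measurement and the study's quantitative endpoints.

The central quantity is the left renal uptake percentage,
``LRU% = 100 * A_left / (A_left + A_right)``, the fraction of total renal
VOI activity found in the left kidney.  Per-patient variability of LRU%
across repeated acquisitions is summarized by the median, sample SD,
range, and "delta max" (highest minus lowest measurement).

The renal VOI is modeled as a 25% blood / 75% tissue mixture, so the
parenchymal tissue concentration is recovered from the VOI concentration
and a whole-blood sample as

    C_tissue = C_kidney / (1 - v) - C_blood * v / (1 - v),   v = V_blood / V_kidney.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import ActivityFrame

__all__ = [
    "VoiMeasurement",
    "PatientSummary",
    "TissueConcInputs",
    "measure_voi",
    "lru_percent",
    "summarize_patient",
    "summarize_cohort",
    "tissue_concentration",
    "peak_time",
    "noise_metric",
    "LRU_COLUMNS",
]

#: Long-format LRU table column names (one row per measured series).
LRU_COLUMNS = ("patient_id", "time_pi", "duration", "lru_percent")


@dataclass(frozen=True)
class VoiMeasurement:
    """Activity, volume and concentration inside one segmented kidney VOI."""

    activity_mbq: float
    volume_ml: float
    concentration_kbq_per_ml: float
    side: str = ""
    time_pi: float = float("nan")
    duration: float = float("nan")


@dataclass(frozen=True)
class PatientSummary:
    """Per-patient LRU% variability summary (one table row per patient)."""

    patient_id: object
    median_lru: float
    sd_lru: float
    range_lru: tuple[float, float]
    delta_max: float
    n_series: int


@dataclass(frozen=True)
class TissueConcInputs:
    """Inputs of the blood-corrected tissue-concentration equation."""

    c_kidney: float  # kBq/mL, whole renal VOI
    c_blood: float  # kBq/mL, whole-blood sample
    blood_fraction: float = 0.25  # V_blood / V_kidney

    def __post_init__(self):
        if not 0.0 <= self.blood_fraction < 1.0:
            raise ValueError("blood_fraction must be in [0, 1)")

    @property
    def tissue_fraction(self) -> float:
        return 1.0 - self.blood_fraction


def measure_voi(
    frame: ActivityFrame,
    mask: np.ndarray,
    side: str = "",
) -> VoiMeasurement:
    """Sum the reconstructed activity inside a segmentation mask.

    activity = sum(voxel concentration) * voxel volume;
    volume = voxel count * voxel volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame.values.shape}"
        )
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty VOI mask")
    vol_ml = n * frame.voxel_volume_ml
    activity_kbq = float(frame.values[mask].sum()) * frame.voxel_volume_ml
    return VoiMeasurement(
        activity_mbq=activity_kbq / 1000.0,
        volume_ml=vol_ml,
        concentration_kbq_per_ml=activity_kbq / vol_ml,
        side=side,
        time_pi=frame.time_pi,
        duration=frame.duration,
    )


def lru_percent(left_activity: float, right_activity: float) -> float:
    """Left renal uptake percentage, 100 * L / (L + R)."""
    if left_activity < 0 or right_activity < 0:
        raise ValueError("activities must be nonnegative")
    total = left_activity + right_activity
    if total == 0:
        raise ValueError("total renal activity is zero; LRU% undefined")
    return 100.0 * left_activity / total


def summarize_patient(values, patient_id=None) -> PatientSummary:
    """Median, sample SD (n-1), range and delta max of one patient's LRU%."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least 2 LRU% records per patient")
    lo, hi = float(arr.min()), float(arr.max())
    return PatientSummary(
        patient_id=patient_id,
        median_lru=float(np.median(arr)),
        sd_lru=float(arr.std(ddof=1)),
        range_lru=(lo, hi),
        delta_max=hi - lo,
        n_series=int(arr.size),
    )


def summarize_cohort(lru_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient summaries of a long-format LRU table (Table-2 layout)."""
    rows = []
    for pid, grp in lru_table.groupby("patient_id", sort=True):
        s = summarize_patient(grp["lru_percent"].to_numpy(), patient_id=pid)
        rows.append(
            {
                "patient_id": pid,
                "median_lru": s.median_lru,
                "sd_lru": s.sd_lru,
                "range_min": s.range_lru[0],
                "range_max": s.range_lru[1],
                "delta_max": s.delta_max,
                "n_series": s.n_series,
            }
        )
    return pd.DataFrame(rows)


def tissue_concentration(inputs: TissueConcInputs) -> float:
    """Blood-corrected parenchymal concentration, kBq/mL.

    May be negative for noisy low-uptake VOIs; negative values are
    returned as-is (with a warning) rather than clipped, so that
    peak-time selection is not biased.
    """
    v = inputs.blood_fraction
    out = inputs.c_kidney / (1.0 - v) - inputs.c_blood * v / (1.0 - v)
    if out < 0:
        warnings.warn(
            f"negative tissue concentration ({out:.3g} kBq/mL); "
            "VOI activity may be dominated by blood",
            stacklevel=2,
        )
    return out


def peak_time(times, values) -> float:
    """Sampled time p.i. with the maximal tissue concentration.

    Ties break toward the earlier time point (earlier imaging is
    operationally preferable).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty concentration series")
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    return float(times[int(np.argmax(values))])


def noise_metric(frame_or_values, mask: np.ndarray) -> float:
    """Coefficient of variation of voxel values inside a mask.

    Objective image-noise surrogate used for duration-vs-quality curves.
    """
    values = (
        frame_or_values.values
        if isinstance(frame_or_values, ActivityFrame)
        else np.asarray(frame_or_values, dtype=float)
    )
    mask = np.asarray(mask, dtype=bool)
    if np.count_nonzero(mask) < 10:
        raise ValueError("noise metric needs a mask with >= 10 voxels")
    roi = values[mask]
    mean = roi.mean()
    if mean == 0:
        raise ValueError("mean of VOI is zero; CV undefined")
    return float(roi.std(ddof=1) / mean)
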