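"""Emission acquisition simulation with rebinnable frame durations.

A frame is simulated by drawing Poisson counts per voxel with mean

    concentration [kBq/mL] x voxel volume [mL] x sensitivity [counts/(kBq s)]
        x duration [s] x decay-averaging factor,

converting the counts back to an activity-concentration estimate, and
applying an isotropic Gaussian blur as a surrogate for regularized
iterative reconstruction.  The decay-averaging factor
``(1 - exp(-lambda d)) / (lambda d)`` accounts exactly for physical decay
across the frame relative to the frame-start activity.

Rebinning emulates retrospective list-mode rebinning: a shorter frame is
the prefix of its parent's event stream, obtained by binomially thinning
the parent's (pre-blur) counts with the decay-exact prefix probability
``(1 - exp(-lambda d)) / (1 - exp(-lambda D))`` (which reduces to d/D for
negligible decay).  Thinned sub-frames therefore share events with their
parent, so quantities measured across durations within one acquisition
are correlated exactly as in rebinned list-mode data, and the marginal
distribution of a sub-frame equals a direct simulation at the shorter
duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import F18_DECAY_PER_MIN

__all__ = [
    "AcquisitionParameterError",
    "ActivityFrame",
    "decay_averaged_factor",
    "expected_counts",
    "simulate_acquisition",
    "rebin_frame",
    "split_frame",
    "perturb_mask",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class AcquisitionParameterError(ValueError):
    """Invalid acquisition parameter (duration, sensitivity, ...)."""


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def decay_averaged_factor(decay_per_min: float, duration_s: float) -> float:
    """Mean decay factor over a frame, relative to frame-start activity."""
    x = decay_per_min * duration_s / 60.0
    if x < 1e-12:
        return 1.0
    return -math.expm1(-x) / x


def _prefix_weight(decay_per_min: float, duration_s: float) -> float:
    """Integral of exp(-lambda u) du over the first ``duration_s`` seconds
    (up to the constant 1/lambda); proportional to expected event count."""
    x = decay_per_min * duration_s / 60.0
    if x < 1e-12:
        return duration_s
    return -math.expm1(-x) / (decay_per_min / 60.0)


@dataclass
class ActivityFrame:
    """One simulated acquisition at a (time p.i., duration) combination.

    ``values`` is the reconstructed activity-concentration estimate
    (kBq/mL, blurred); ``counts`` the raw per-voxel Poisson counts before
    blurring, kept so the frame can be rebinned like list-mode data.
    """

    values: np.ndarray
    counts: np.ndarray
    time_pi: float  # minutes p.i. at frame start
    duration: float  # seconds per bed position
    sensitivity: float  # counts per (kBq s)
    psf_fwhm: float  # mm
    voxel_size: float  # mm
    decay_constant: float = F18_DECAY_PER_MIN  # 1/min
    seed: int | None = None
    frame_id: str = ""
    parent_id: str | None = None

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    @property
    def total_activity_mbq(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_ml / 1000.0


def expected_counts(
    truth: np.ndarray,
    duration_s: float,
    sensitivity: float,
    voxel_size: float,
    decay_constant: float = F18_DECAY_PER_MIN,
) -> np.ndarray:
    """Closed-form per-voxel count expectation for a frame."""
    g = decay_averaged_factor(decay_constant, duration_s)
    voxel_volume_ml = voxel_size**3 / 1000.0
    return np.asarray(truth, dtype=float) * voxel_volume_ml * sensitivity * duration_s * g


def _counts_to_concentration(
    counts: np.ndarray,
    duration_s: float,
    sensitivity: float,
    voxel_size: float,
    decay_constant: float,
) -> np.ndarray:
    g = decay_averaged_factor(decay_constant, duration_s)
    voxel_volume_ml = voxel_size**3 / 1000.0
    return counts.astype(np.float64) / (voxel_volume_ml * sensitivity * duration_s * g)


def _blur(conc: np.ndarray, psf_fwhm: float, voxel_size: float) -> np.ndarray:
    if psf_fwhm <= 0:
        return conc
    sigma = psf_fwhm / _FWHM_TO_SIGMA / voxel_size
    return ndimage.gaussian_filter(conc, sigma=sigma, mode="constant")


def simulate_acquisition(
    truth: np.ndarray,
    time_pi: float,
    duration: float,
    sensitivity: float,
    psf_fwhm: float,
    voxel_size: float,
    decay_constant: float = F18_DECAY_PER_MIN,
    seed=None,
    poisson: bool = True,
    frame_id: str = "",
) -> ActivityFrame:
    """Simulate one frame from a true concentration volume at frame start.

    With ``poisson=False`` the expected counts are used directly (noise-free
    limit), which keeps the full estimation chain including blur.
    """
    if duration <= 0:
        raise AcquisitionParameterError("duration must be positive")
    if sensitivity <= 0:
        raise AcquisitionParameterError("sensitivity must be positive")
    mean = expected_counts(truth, duration, sensitivity, voxel_size, decay_constant)
    if poisson:
        rng = as_rng(seed)
        counts = rng.poisson(mean).astype(np.int64)
    else:
        counts = mean
    conc = _counts_to_concentration(
        counts, duration, sensitivity, voxel_size, decay_constant
    )
    values = _blur(conc, psf_fwhm, voxel_size)
    return ActivityFrame(
        values=values,
        counts=counts,
        time_pi=time_pi,
        duration=duration,
        sensitivity=sensitivity,
        psf_fwhm=psf_fwhm,
        voxel_size=voxel_size,
        decay_constant=decay_constant,
        seed=seed if isinstance(seed, int) else None,
        frame_id=frame_id,
    )


def _child_frame(
    parent: ActivityFrame, counts, duration: float, time_pi: float, frame_id: str
) -> ActivityFrame:
    conc = _counts_to_concentration(
        counts, duration, parent.sensitivity, parent.voxel_size, parent.decay_constant
    )
    values = _blur(conc, parent.psf_fwhm, parent.voxel_size)
    return ActivityFrame(
        values=values,
        counts=counts,
        time_pi=time_pi,
        duration=duration,
        sensitivity=parent.sensitivity,
        psf_fwhm=parent.psf_fwhm,
        voxel_size=parent.voxel_size,
        decay_constant=parent.decay_constant,
        frame_id=frame_id,
        parent_id=parent.frame_id or "parent",
    )


def rebin_frame(
    parent: ActivityFrame,
    sub_duration: float,
    seed=None,
    poisson: bool = True,
    frame_id: str = "",
) -> ActivityFrame:
    """Rebin a parent frame to a shorter duration (prefix thinning)."""
    if not 0 < sub_duration <= parent.duration:
        raise AcquisitionParameterError(
            f"sub-duration {sub_duration} must be in (0, {parent.duration}]"
        )
    p = _prefix_weight(parent.decay_constant, sub_duration) / _prefix_weight(
        parent.decay_constant, parent.duration
    )
    if sub_duration == parent.duration:
        counts = parent.counts.copy()
    elif poisson:
        rng = as_rng(seed)
        counts = rng.binomial(parent.counts, p)
    else:
        counts = parent.counts * p
    return _child_frame(parent, counts, sub_duration, parent.time_pi, frame_id)


def split_frame(
    parent: ActivityFrame, durations, seed=None
) -> list[ActivityFrame]:
    """Partition a parent frame into contiguous sub-frames.

    Counts are distributed multinomially over the segments with
    decay-exact weights, so when the durations exhaust the parent the
    sub-frames sum to the parent's counts voxel-wise, exactly.
    """
    durations = [float(d) for d in durations]
    if any(d <= 0 for d in durations):
        raise AcquisitionParameterError("segment durations must be positive")
    if sum(durations) > parent.duration + 1e-9:
        raise AcquisitionParameterError("segments exceed the parent duration")
    rng = as_rng(seed)
    lam_s = parent.decay_constant / 60.0
    total_w = _prefix_weight(parent.decay_constant, parent.duration)
    remaining = parent.counts.copy()
    remaining_w = total_w
    offset = 0.0
    children = []
    for i, d in enumerate(durations):
        w = math.exp(-lam_s * offset) * _prefix_weight(parent.decay_constant, d)
        exhausts = i == len(durations) - 1 and abs(
            offset + d - parent.duration
        ) < 1e-9
        if exhausts:
            counts = remaining
        else:
            counts = rng.binomial(remaining, min(1.0, w / remaining_w))
            remaining = remaining - counts
            remaining_w -= w
        children.append(
            _child_frame(
                parent,
                counts,
                d,
                parent.time_pi + offset / 60.0,
                frame_id=f"{parent.frame_id}/seg{i}",
            )
        )
        offset += d
    return children


def perturb_mask(
    mask: np.ndarray,
    boundary_noise_mm: float,
    voxel_size: float,
    seed=None,
    correlation_mm: float = 16.0,
    max_tries: int = 5,
) -> np.ndarray:
    """Random boundary jitter of a segmentation mask.

    The mask indicator is warped by a smooth random displacement field
    (per-component RMS ``boundary_noise_mm``, correlation length
    ``correlation_mm``), linearly interpolated and re-thresholded at 0.5.
    This emulates segmentation variability: locally coherent over- and
    under-inclusion at the organ boundary, with genuine sub-voxel
    sensitivity.  The result must overlap the input (Dice > 0.5) and be
    nonempty; failing draws are retried, then an error is raised.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("input mask is empty")
    if boundary_noise_mm < 0:
        raise ValueError("boundary noise must be >= 0")
    if boundary_noise_mm == 0:
        return mask.copy()
    rng = as_rng(seed)
    sigma_vox = correlation_mm / voxel_size
    indicator = mask.astype(np.float32)
    coords = np.meshgrid(*(np.arange(n) for n in mask.shape), indexing="ij")
    for _ in range(max_tries):
        warped = []
        for axis in range(3):
            field = ndimage.gaussian_filter(
                rng.standard_normal(mask.shape), sigma=sigma_vox, mode="wrap"
            )
            field *= boundary_noise_mm / voxel_size / field.std()
            warped.append(coords[axis] + field)
        out = (
            ndimage.map_coordinates(indicator, warped, order=1, mode="constant")
            > 0.5
        )
        inter = np.count_nonzero(out & mask)
        denom = np.count_nonzero(out) + np.count_nonzero(mask)
        dice = 2.0 * inter / denom if denom else 0.0
        if out.any() and dice > 0.5:
            return out
    raise ValueError(
        f"mask perturbation failed after {max_tries} tries "
        f"(noise {boundary_noise_mm} mm too large for this structure)"
    )
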