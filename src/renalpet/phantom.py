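"""Digital two-kidney phantom and tracer kinetics for renal PET simulation.

The phantom is a voxelized abdominal scene: two ellipsoidal kidneys whose
parenchymal activity is divided by a configurable left/right split
fraction, an intrarenal blood compartment (the renal volume is modeled as
25% blood and 75% tissue), an aortic blood pool, liver, spleen, optional
renal-pelvis regions holding excreted activity, optional spherical cold
defects, and a low-uptake background.

Tracer kinetics combine a saturating-uptake / monoexponential-washout
tissue curve, ``b(t) = A (1 - exp(-k_u t)) exp(-k_w t)``, with a
biexponential whole-blood clearance curve; measured concentrations are the
biological curves modulated by the physical decay of fluorine-18
(half-life 109.77 min).  With the default rates the decayed tissue curve
attains its maximum at the 1 h post-injection sample of the standard
acquisition schedule.

Axis order is (x, y, z), coordinates are 0-based voxel indices, world
units are mm, concentrations kBq/mL, time post-injection minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "F18_HALF_LIFE_MIN",
    "F18_DECAY_PER_MIN",
    "PhantomConfigError",
    "Ellipsoid",
    "Compartment",
    "ColdDefect",
    "TissueCurve",
    "BloodCurve",
    "Biokinetics",
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "default_phantom_spec",
    "LABEL_BACKGROUND",
    "LABEL_LEFT_KIDNEY",
    "LABEL_RIGHT_KIDNEY",
    "LABEL_LIVER",
    "LABEL_SPLEEN",
    "LABEL_BLOOD_POOL",
    "LABEL_PELVIS",
]

F18_HALF_LIFE_MIN = 109.77
F18_DECAY_PER_MIN = math.log(2.0) / F18_HALF_LIFE_MIN

LABEL_BACKGROUND = 0
LABEL_LEFT_KIDNEY = 1
LABEL_RIGHT_KIDNEY = 2
LABEL_LIVER = 3
LABEL_SPLEEN = 4
LABEL_BLOOD_POOL = 5
LABEL_PELVIS = 6

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_LEFT_KIDNEY: "left_kidney",
    LABEL_RIGHT_KIDNEY: "right_kidney",
    LABEL_LIVER: "liver",
    LABEL_SPLEEN: "spleen",
    LABEL_BLOOD_POOL: "blood_pool",
    LABEL_PELVIS: "pelvis",
}


class PhantomConfigError(ValueError):
    """Invalid phantom geometry or parameters."""


def _as_vec3(value, name: str) -> tuple[float, float, float]:
    vec = tuple(float(v) for v in value)
    if len(vec) != 3:
        raise PhantomConfigError(f"{name} must have 3 components, got {value!r}")
    return vec


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, center and semi-axes in mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))
        object.__setattr__(self, "semi_axes", _as_vec3(self.semi_axes, "semi_axes"))
        if any(a <= 0 for a in self.semi_axes):
            raise PhantomConfigError("ellipsoid semi-axes must be positive")

    def mask(self, grid_shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
        x, y, z = voxel_center_grids(grid_shape, voxel_size)
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return (
            ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        ) <= 1.0

    def bounding_box(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (c - a, c + a) for c, a in zip(self.center, self.semi_axes)
        )


@dataclass(frozen=True)
class Compartment:
    """An organ region with uptake relative to the population tissue curve."""

    shape: Ellipsoid
    uptake: float

    def __post_init__(self):
        if self.uptake < 0:
            raise PhantomConfigError("compartment uptake must be >= 0")


@dataclass(frozen=True)
class ColdDefect:
    """Spherical region of reduced parenchymal uptake (e.g. a cortical scar)."""

    center: tuple[float, float, float]
    radius_mm: float
    uptake_multiplier: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center, "defect center"))
        if self.radius_mm <= 0:
            raise PhantomConfigError("defect radius must be positive")
        if not 0.0 <= self.uptake_multiplier <= 1.0:
            raise PhantomConfigError("defect uptake multiplier must be in [0, 1]")

    def mask(self, grid_shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
        x, y, z = voxel_center_grids(grid_shape, voxel_size)
        cx, cy, cz = self.center
        return ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= self.radius_mm**2


def voxel_center_grids(grid_shape, voxel_size: float):
    """Open mm-coordinate grids at voxel centers, axis order (x, y, z)."""
    axes = [(np.arange(n) + 0.5) * voxel_size for n in grid_shape]
    return (
        axes[0][:, None, None],
        axes[1][None, :, None],
        axes[2][None, None, :],
    )


@dataclass(frozen=True)
class TissueCurve:
    """Renal parenchymal (biological) concentration curve.

    ``b(t) = amplitude * (1 - exp(-uptake_rate * t)) * exp(-washout_rate * t)``
    with t in minutes p.i.; amplitude is the concentration scale in kBq/mL
    per MBq/kg injected for a symmetric (50/50) split.
    """

    amplitude: float = 22.0
    uptake_rate: float = 0.03
    washout_rate: float = 5.0e-4

    def __post_init__(self):
        if self.amplitude < 0:
            raise PhantomConfigError("tissue amplitude must be >= 0")
        if self.uptake_rate <= 0 or self.washout_rate < 0:
            raise PhantomConfigError("tissue rates must be positive (washout >= 0)")

    def biological(self, t_min):
        t = np.asarray(t_min, dtype=float)
        return (
            self.amplitude
            * -np.expm1(-self.uptake_rate * t)
            * np.exp(-self.washout_rate * t)
        )


@dataclass(frozen=True)
class BloodCurve:
    """Biexponential whole-blood clearance, kBq/mL per MBq/kg injected."""

    amplitude: float = 16.0
    fast_fraction: float = 0.75
    fast_rate: float = 0.15
    slow_rate: float = 0.004

    def __post_init__(self):
        if self.amplitude < 0:
            raise PhantomConfigError("blood amplitude must be >= 0")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise PhantomConfigError("fast_fraction must be in [0, 1]")
        if self.fast_rate <= 0 or self.slow_rate <= 0:
            raise PhantomConfigError("blood clearance rates must be positive")

    def biological(self, t_min):
        t = np.asarray(t_min, dtype=float)
        return self.amplitude * (
            self.fast_fraction * np.exp(-self.fast_rate * t)
            + (1.0 - self.fast_fraction) * np.exp(-self.slow_rate * t)
        )


@dataclass(frozen=True)
class Biokinetics:
    """Tissue + blood kinetics with fluorine-18 physical decay."""

    tissue: TissueCurve = field(default_factory=TissueCurve)
    blood: BloodCurve = field(default_factory=BloodCurve)
    decay_constant: float = F18_DECAY_PER_MIN  # 1/min

    def __post_init__(self):
        if self.decay_constant <= 0:
            raise PhantomConfigError("decay constant must be positive")

    def tissue_conc(self, t_min, dose_mbq_per_kg: float = 1.0):
        """Measured (decayed) parenchymal concentration, kBq/mL."""
        t = np.asarray(t_min, dtype=float)
        return dose_mbq_per_kg * self.tissue.biological(t) * np.exp(
            -self.decay_constant * t
        )

    def blood_conc(self, t_min, dose_mbq_per_kg: float = 1.0):
        """Measured (decayed) whole-blood concentration, kBq/mL."""
        t = np.asarray(t_min, dtype=float)
        return dose_mbq_per_kg * self.blood.biological(t) * np.exp(
            -self.decay_constant * t
        )


# Field of view of the default abdominal scene, mm.
_DEFAULT_FOV_MM = (288.0, 288.0, 192.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and uptake parameters of the digital two-kidney phantom."""

    grid_shape: tuple[int, int, int]
    voxel_size: float  # mm, isotropic
    left_kidney: Ellipsoid
    right_kidney: Ellipsoid
    liver: Compartment | None = None
    spleen: Compartment | None = None
    blood_pool: Ellipsoid | None = None
    pelvis_left: Compartment | None = None
    pelvis_right: Compartment | None = None
    background_uptake: float = 0.02
    split_fraction_left: float = 0.5
    blood_fraction: float = 0.25
    defects: tuple[ColdDefect, ...] = ()
    patient_mass: float = 80.0  # kg

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "defects", tuple(self.defects))
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise PhantomConfigError("grid_shape must be 3 positive integers")
        if self.voxel_size <= 0:
            raise PhantomConfigError("voxel_size must be positive")
        if not 0.0 < self.split_fraction_left < 1.0:
            raise PhantomConfigError("split_fraction_left must be in (0, 1)")
        if not 0.0 <= self.blood_fraction < 1.0:
            raise PhantomConfigError("blood_fraction must be in [0, 1)")
        if self.background_uptake < 0:
            raise PhantomConfigError("background uptake must be >= 0")
        if self.patient_mass <= 0:
            raise PhantomConfigError("patient mass must be positive")
        fov = tuple(n * self.voxel_size for n in self.grid_shape)
        for name, kidney in (("left", self.left_kidney), ("right", self.right_kidney)):
            for (lo, hi), extent in zip(kidney.bounding_box(), fov):
                if lo < 0 or hi > extent:
                    raise PhantomConfigError(
                        f"{name} kidney extends outside the grid "
                        f"(bbox [{lo:.1f}, {hi:.1f}] mm vs FOV {extent:.1f} mm)"
                    )

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0


def default_phantom_spec(
    split_fraction_left: float = 0.483,
    voxel_size: float = 4.0,
    blood_fraction: float = 0.25,
    defects: tuple[ColdDefect, ...] = (),
    include_pelvis: bool = True,
    patient_mass: float = 80.0,
) -> PhantomSpec:
    """Standard adult abdominal scene on a 288 x 288 x 192 mm field of view.

    The mm geometry is fixed; ``voxel_size`` only controls discretization,
    so VOI totals are (approximately) voxel-size independent.
    """
    grid_shape = tuple(int(round(f / voxel_size)) for f in _DEFAULT_FOV_MM)
    kidney_axes = (22.0, 26.0, 48.0)
    left = Ellipsoid((200.0, 150.0, 96.0), kidney_axes)
    right = Ellipsoid((88.0, 150.0, 96.0), kidney_axes)
    liver = Compartment(Ellipsoid((75.0, 140.0, 182.0), (50.0, 45.0, 25.0)), 0.7)
    spleen = Compartment(Ellipsoid((213.0, 140.0, 182.0), (50.0, 45.0, 25.0)), 0.5)
    aorta = Ellipsoid((144.0, 175.0, 96.0), (9.0, 9.0, 70.0))
    pelvis_l = pelvis_r = None
    if include_pelvis:
        pelvis_l = Compartment(Ellipsoid((185.0, 150.0, 96.0), (7.0, 9.0, 15.0)), 3.0)
        pelvis_r = Compartment(Ellipsoid((103.0, 150.0, 96.0), (7.0, 9.0, 15.0)), 3.0)
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        left_kidney=left,
        right_kidney=right,
        liver=liver,
        spleen=spleen,
        blood_pool=aorta,
        pelvis_left=pelvis_l,
        pelvis_right=pelvis_r,
        split_fraction_left=split_fraction_left,
        blood_fraction=blood_fraction,
        defects=defects,
        patient_mass=patient_mass,
    )


@dataclass
class Phantom:
    """Built phantom: label volume plus a true-concentration factory.

    ``truth(t)`` returns the noiseless activity-concentration volume
    (kBq/mL) at t minutes p.i., combining the tissue and blood kinetic
    curves with physical decay.  The spatial weights are time independent:
    ``truth(t) = tissue_conc(t) * tissue_weights + blood_conc(t) * blood_weights``.
    """

    spec: PhantomSpec
    kinetics: Biokinetics
    dose_mbq_per_kg: float
    labels: np.ndarray
    tissue_weights: np.ndarray
    blood_weights: np.ndarray

    @property
    def voxel_size(self) -> float:
        return self.spec.voxel_size

    @property
    def voxel_volume_ml(self) -> float:
        return self.spec.voxel_volume_ml

    def truth(self, t_min: float) -> np.ndarray:
        return (
            float(self.kinetics.tissue_conc(t_min, self.dose_mbq_per_kg))
            * self.tissue_weights
            + float(self.kinetics.blood_conc(t_min, self.dose_mbq_per_kg))
            * self.blood_weights
        )

    def kidney_mask(self, side: str, include_pelvis: bool = False) -> np.ndarray:
        """Ground-truth segmentation of one kidney.

        Excreted activity in the renal pelvis is excluded by default,
        matching how a reader excludes pelvic activity from a cortical VOI.
        """
        label = {"left": LABEL_LEFT_KIDNEY, "right": LABEL_RIGHT_KIDNEY}[side]
        mask = self.labels == label
        if include_pelvis:
            shape = {
                "left": self.spec.pelvis_left,
                "right": self.spec.pelvis_right,
            }[side]
            if shape is not None:
                mask = mask | (
                    shape.shape.mask(self.spec.grid_shape, self.spec.voxel_size)
                    & (self.labels == LABEL_PELVIS)
                )
        return mask


def build_phantom(
    spec: PhantomSpec,
    kinetics: Biokinetics | None = None,
    dose_mbq_per_kg: float = 4.0,
) -> Phantom:
    """Rasterize the phantom and precompute its kinetic weight maps.

    The total renal parenchymal (tissue) activity is split
    ``split_fraction_left : 1 - split_fraction_left`` between the kidneys;
    each kidney voxel is a ``blood_fraction`` / ``1 - blood_fraction``
    mixture of the blood and tissue curves.  Liver, spleen, pelvis and
    background follow the tissue curve scaled by their relative uptake;
    the aortic blood pool follows the blood curve.
    """
    if kinetics is None:
        kinetics = Biokinetics()
    if dose_mbq_per_kg <= 0:
        raise PhantomConfigError("injected activity must be positive")

    shape, vox = spec.grid_shape, spec.voxel_size
    left_mask = spec.left_kidney.mask(shape, vox)
    right_mask = spec.right_kidney.mask(shape, vox)
    if not left_mask.any() or not right_mask.any():
        raise PhantomConfigError("kidney rasterizes to an empty mask")
    if (left_mask & right_mask).any():
        raise PhantomConfigError("kidney ellipsoids overlap")

    labels = np.zeros(shape, dtype=np.int8)
    kidney_mask = left_mask | right_mask
    for label, comp in (
        (LABEL_LIVER, spec.liver),
        (LABEL_SPLEEN, spec.spleen),
    ):
        if comp is not None:
            m = comp.shape.mask(shape, vox)
            if (m & kidney_mask).any():
                raise PhantomConfigError(f"{LABEL_NAMES[label]} overlaps a kidney")
            labels[m] = label
    if spec.blood_pool is not None:
        m = spec.blood_pool.mask(shape, vox)
        if (m & kidney_mask).any():
            raise PhantomConfigError("blood pool overlaps a kidney")
        labels[m] = LABEL_BLOOD_POOL
    labels[left_mask] = LABEL_LEFT_KIDNEY
    labels[right_mask] = LABEL_RIGHT_KIDNEY
    # Renal pelvis regions are carved out of the kidney interiors: excreted
    # activity that a reader would exclude from the cortical VOI.
    for comp in (spec.pelvis_left, spec.pelvis_right):
        if comp is not None:
            m = comp.shape.mask(shape, vox) & kidney_mask
            labels[m] = LABEL_PELVIS

    left_mask = labels == LABEL_LEFT_KIDNEY
    right_mask = labels == LABEL_RIGHT_KIDNEY
    vol_l = left_mask.sum() * spec.voxel_volume_ml
    vol_r = right_mask.sum() * spec.voxel_volume_ml
    f = spec.split_fraction_left
    bf = spec.blood_fraction

    tissue_w = np.full(shape, spec.background_uptake, dtype=np.float64)
    blood_w = np.zeros(shape, dtype=np.float64)
    # Per-voxel tissue weight such that integrated parenchymal activity
    # splits exactly f : (1 - f); for equal-volume kidneys and f = 0.5 the
    # kidney tissue concentration equals (1 - bf) * b(t).
    tissue_w[left_mask] = (1.0 - bf) * f * (vol_l + vol_r) / vol_l
    tissue_w[right_mask] = (1.0 - bf) * (1.0 - f) * (vol_l + vol_r) / vol_r
    blood_w[left_mask | right_mask] = bf
    if spec.liver is not None:
        tissue_w[labels == LABEL_LIVER] = spec.liver.uptake
    if spec.spleen is not None:
        tissue_w[labels == LABEL_SPLEEN] = spec.spleen.uptake
    pelvis_mask = labels == LABEL_PELVIS
    if pelvis_mask.any():
        uptake = (spec.pelvis_left or spec.pelvis_right).uptake
        tissue_w[pelvis_mask] = uptake
        blood_w[pelvis_mask] = 0.0
    if spec.blood_pool is not None:
        m = labels == LABEL_BLOOD_POOL
        tissue_w[m] = 0.0
        blood_w[m] = 1.0

    for defect in spec.defects:
        dm = defect.mask(shape, vox) & (left_mask | right_mask)
        tissue_w[dm] *= defect.uptake_multiplier
        blood_w[dm] *= defect.uptake_multiplier

    return Phantom(
        spec=spec,
        kinetics=kinetics,
        dose_mbq_per_kg=dose_mbq_per_kg,
        labels=labels,
        tissue_weights=tissue_w,
        blood_weights=blood_w,
    )
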