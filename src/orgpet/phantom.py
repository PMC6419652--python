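"""Digital phantom simulation of respiratory-motion PET acquisitions.

The phantom stands in for patient scans: a heterogeneous hot lesion (Gaussian
radial profile, optional necrotic core) on a warm uniform background, sampled
on a voxel grid in SUV units.  Respiratory motion is modelled as rigid
cranio-caudal translation of the lesion foreground driven by a cos^2n
breathing waveform that dwells at end-expiration; an acquisition is a stack of
short frames, each with the lesion displaced by the instantaneous amplitude,
optionally with Poisson count noise.  Ungated and gated images are voxelwise
means over (subsets of) frames, so both live on a common SUV scale.

The reconstruction point-spread function is Gaussian; because the lesion
profile is Gaussian too, the PSF convolution is applied in closed form
(variances add, peak amplitude scales by (sigma_l^2 / (sigma_l^2+sigma_p^2))^(3/2))
and the result is sampled at voxel centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomImage",
    "PhantomSpec",
    "NecroticCore",
    "RespiratoryTrace",
    "FrameStack",
    "make_phantom",
    "lujan_waveform",
    "simulate_acquisition",
    "sum_frames",
    "default_phantom_spec",
]

# FWHM = 2*sqrt(2 ln 2) * sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PhantomImage:
    """A 3-D SUV-scaled intensity grid with physical voxel spacing (mm)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"PhantomImage must be 3-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("PhantomImage contains non-finite values")
        if values.min() < 0:
            raise ValueError("PhantomImage contains negative values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive floats")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class NecroticCore:
    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the motion-free digital phantom.

    ``voxel_spacing_mm`` and ``psf_fwhm_mm`` default to the acquisition
    settings emulated throughout (4.07 mm isotropic voxels, 3.0 mm Gaussian
    post-filter).  ``noise_scale`` is counts per SUV per frame; 0 disables
    Poisson noise.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 48)
    voxel_spacing_mm: tuple[float, float, float] = (4.07, 4.07, 4.07)
    background_suv: float = 1.0
    lesion_centers_mm: tuple[tuple[float, float, float], ...] = ()
    lesion_radii_mm: tuple[float, ...] = ()
    lesion_peak_suv: tuple[float, ...] = ()
    necrotic_core: Optional[NecroticCore] = None
    psf_fwhm_mm: float = 3.0
    noise_scale: float = 0.0
    seed: int = 0
    # intra-lesional heterogeneity: multiplicative correlated random field on
    # the lesion excess (fraction = field SD; 0 disables, giving a smooth blob)
    texture_frac: float = 0.0
    texture_corr_mm: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(
            self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm)
        )
        object.__setattr__(
            self,
            "lesion_centers_mm",
            tuple(tuple(float(c) for c in ctr) for ctr in self.lesion_centers_mm),
        )
        object.__setattr__(
            self, "lesion_radii_mm", tuple(float(r) for r in self.lesion_radii_mm)
        )
        object.__setattr__(
            self, "lesion_peak_suv", tuple(float(p) for p in self.lesion_peak_suv)
        )
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 4 voxels")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.background_suv < 0:
            raise ValueError("background_suv must be non-negative")
        n = len(self.lesion_centers_mm)
        if len(self.lesion_radii_mm) != n or len(self.lesion_peak_suv) != n:
            raise ValueError("lesion centers/radii/peaks must have equal length")
        if any(r <= 0 for r in self.lesion_radii_mm):
            raise ValueError("lesion radii must be positive")
        if any(p <= self.background_suv for p in self.lesion_peak_suv):
            raise ValueError("lesion peak SUV must exceed background")
        if self.psf_fwhm_mm < 0 or self.noise_scale < 0:
            raise ValueError("psf_fwhm_mm and noise_scale must be non-negative")
        if self.texture_frac < 0 or self.texture_corr_mm <= 0:
            raise ValueError("texture_frac must be >= 0 and texture_corr_mm > 0")
        extent = [
            (ni - 1) * si for ni, si in zip(self.grid_shape, self.voxel_spacing_mm)
        ]
        margin = [2.0 * s for s in self.voxel_spacing_mm]
        for ctr, rad in zip(self.lesion_centers_mm, self.lesion_radii_mm):
            for ax in range(3):
                if not (
                    margin[ax] <= ctr[ax] - rad and ctr[ax] + rad <= extent[ax] - margin[ax]
                ):
                    raise ValueError(
                        f"lesion at {ctr} mm with radius {rad} mm is closer than "
                        f"2 voxels to the grid boundary on axis {ax}"
                    )


@dataclass(frozen=True)
class RespiratoryTrace:
    """Uniformly sampled surrogate respiratory signal (mm amplitudes)."""

    times_s: np.ndarray
    amplitudes_mm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=np.float64)
        a = np.asarray(self.amplitudes_mm, dtype=np.float64)
        if t.ndim != 1 or a.ndim != 1 or len(t) != len(a):
            raise ValueError("times and amplitudes must be 1-D and equal length")
        if len(t) < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"times must be strictly increasing (row {bad})")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise ValueError("sampling interval must be uniform")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "amplitudes_mm", a)

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass(frozen=True)
class FrameStack:
    """One short frame per trace sample plus the motion-free truth."""

    frames: tuple[PhantomImage, ...]
    trace: RespiratoryTrace
    truth: PhantomImage

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.trace):
            raise ValueError("frame count must equal trace sample count")
        shape, spacing = self.truth.shape, self.truth.spacing_mm
        for fr in self.frames:
            if fr.shape != shape or fr.spacing_mm != spacing:
                raise ValueError("all frames must share the truth's shape and spacing")

    def __len__(self) -> int:
        return len(self.frames)


def _voxel_coords_mm(shape: Sequence[int], spacing: Sequence[float]):
    """Per-axis voxel-center coordinates (voxel i sits at i * spacing)."""
    return [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]


def _gaussian_blob(coords, center, sigma, amplitude):
    r2 = (
        (coords[0][:, None, None] - center[0]) ** 2
        + (coords[1][None, :, None] - center[1]) ** 2
        + (coords[2][None, None, :] - center[2]) ** 2
    )
    return amplitude * np.exp(-r2 / (2.0 * sigma**2))


def make_phantom(spec: PhantomSpec) -> PhantomImage:
    """Render the motion-free ground-truth image.

    Lesions have Gaussian radial profiles with sigma = radius / 2 (the stated
    radius is the 2-sigma point).  The Gaussian PSF is folded in analytically:
    a Gaussian blob of variance s_l^2 convolved with a Gaussian PSF of
    variance s_p^2 is a Gaussian of variance s_l^2 + s_p^2 whose peak is
    scaled by (s_l^2 / (s_l^2 + s_p^2))^(3/2).  A necrotic core is a negative
    blob whose depth is set so the un-blurred object equals the core SUV at
    the core center.
    """
    coords = _voxel_coords_mm(spec.grid_shape, spec.voxel_spacing_mm)
    sigma_p = spec.psf_fwhm_mm * _FWHM_TO_SIGMA

    def blurred_params(sigma_l: float, amp: float) -> tuple[float, float]:
        var = sigma_l**2 + sigma_p**2
        scale = (sigma_l**2 / var) ** 1.5
        return math.sqrt(var), amp * scale

    excess = np.zeros(spec.grid_shape)
    for ctr, rad, peak in zip(
        spec.lesion_centers_mm, spec.lesion_radii_mm, spec.lesion_peak_suv
    ):
        sig, amp = blurred_params(rad / 2.0, peak - spec.background_suv)
        excess += _gaussian_blob(coords, ctr, sig, amp)

    core = spec.necrotic_core
    if core is not None:
        # depth of the subtraction from the *un-blurred* object at the core center
        val0 = spec.background_suv
        for ctr, rad, peak in zip(
            spec.lesion_centers_mm, spec.lesion_radii_mm, spec.lesion_peak_suv
        ):
            r2 = sum((a - b) ** 2 for a, b in zip(core.center_mm, ctr))
            val0 += (peak - spec.background_suv) * math.exp(
                -r2 / (2.0 * (rad / 2.0) ** 2)
            )
        depth = val0 - core.suv
        if depth < 0:
            raise ValueError("necrotic core SUV exceeds the surrounding lesion value")
        sig, amp = blurred_params(core.radius_mm / 2.0, depth)
        excess -= _gaussian_blob(coords, core.center_mm, sig, amp)

    if spec.texture_frac > 0 and len(spec.lesion_centers_mm) > 0:
        # seeded correlated random field modulating the lesion excess:
        # intra-tumoral heterogeneity that moves rigidly with the lesion
        rng = np.random.default_rng(spec.seed)
        field = rng.standard_normal(spec.grid_shape)
        sig_vox = [
            (spec.texture_corr_mm / 2.0) / s for s in spec.voxel_spacing_mm
        ]
        field = ndimage.gaussian_filter(field, sig_vox)
        field /= field.std()
        excess = excess * (1.0 + spec.texture_frac * field)

    img = np.maximum(spec.background_suv + excess, 0.0)
    if spec.texture_frac == 0 and (spec.background_suv + excess).min() < -1e-12:
        raise ValueError("phantom rendered negative SUVs; core too deep")
    return PhantomImage(img, spec.voxel_spacing_mm)


def lujan_waveform(
    period_s: float,
    amplitude_mm: float,
    exponent_n: int,
    duration_s: float,
    dt_s: float,
    drift_mm_per_min: float = 0.0,
    jitter: float = 0.0,
    seed: Optional[int] = None,
) -> RespiratoryTrace:
    """cos^2n breathing surrogate dwelling at end-expiration.

    z(t) = A * cos(pi t / tau)^{2n}; larger n concentrates the cycle near the
    baseline (end-expiration dwell).  ``jitter`` perturbs the per-cycle
    amplitude by a Gaussian fraction; ``drift_mm_per_min`` subtracts a linear
    baseline drift.
    """
    if period_s <= 0 or dt_s <= 0:
        raise ValueError("period_s and dt_s must be positive")
    if exponent_n < 1 or int(exponent_n) != exponent_n:
        raise ValueError("exponent_n must be an integer >= 1")
    if dt_s >= period_s / 8.0:
        raise ValueError("dt_s must be smaller than period_s / 8")
    n_samples = int(round(duration_s / dt_s))
    if n_samples < 2:
        raise ValueError("duration too short for the sampling interval")
    times = np.arange(n_samples, dtype=np.float64) * dt_s
    base = np.cos(np.pi * times / period_s) ** (2 * int(exponent_n))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        cycle = np.floor(times / period_s).astype(np.intp)
        factors = np.clip(1.0 + jitter * rng.standard_normal(cycle[-1] + 1), 0.0, None)
        base = base * factors[cycle]
    amplitudes = amplitude_mm * base - drift_mm_per_min * times / 60.0
    return RespiratoryTrace(times, amplitudes)


def _shift_axis_integer(arr: np.ndarray, n: int, axis: int) -> np.ndarray:
    """Shift contents by +n voxels along ``axis``, zero-filling."""
    if n == 0:
        return arr
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    size = arr.shape[axis]
    if abs(n) >= size:
        return out
    if n > 0:
        dst[axis] = slice(n, size)
        src[axis] = slice(0, size - n)
    else:
        dst[axis] = slice(0, size + n)
        src[axis] = slice(-n, size)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shift_axis_linear(arr: np.ndarray, shift: float, axis: int) -> np.ndarray:
    """Subvoxel translation along one axis by linear interpolation."""
    n = math.floor(shift)
    w = shift - n
    a = _shift_axis_integer(arr, n, axis)
    if w == 0.0:
        return a
    b = _shift_axis_integer(arr, n + 1, axis)
    return (1.0 - w) * a + w * b


def simulate_acquisition(
    truth: PhantomImage,
    trace: RespiratoryTrace,
    background_suv: float,
    motion_axis: int = 2,
    noise_scale: float = 0.0,
    seed: Optional[int] = None,
    lesion_mask: Optional[np.ndarray] = None,
) -> FrameStack:
    """Build one frame per trace sample by translating the lesion foreground.

    The foreground (truth minus the uniform background, optionally restricted
    to ``lesion_mask``) is rigidly shifted along ``motion_axis`` by the
    frame's amplitude (mm -> voxels via the spacing) with linear subvoxel
    interpolation, then re-added to the background.  Poisson noise on
    counts = noise_scale * SUV is applied per frame when noise_scale > 0.
    """
    if motion_axis not in (0, 1, 2):
        raise ValueError("motion_axis must be 0, 1 or 2")
    fg = truth.values - background_suv
    if lesion_mask is not None:
        fg = np.where(lesion_mask, fg, 0.0)

    spacing = truth.spacing_mm[motion_axis]
    shifts_vox = np.asarray(trace.amplitudes_mm, dtype=np.float64) / spacing

    # bounds: the foreground support must stay inside the grid for every shift
    support = np.abs(fg) > 1e-12 * max(np.abs(fg).max(), 1.0)
    if support.any():
        idx = np.nonzero(support.any(axis=tuple(ax for ax in range(3) if ax != motion_axis)))[0]
        lo, hi = idx[0], idx[-1]
        n_ax = truth.shape[motion_axis]
        smin, smax = shifts_vox.min(), shifts_vox.max()
        if lo + smin < -1e-9 or hi + smax > n_ax - 1 + 1e-9:
            raise ValueError(
                f"motion pushes the lesion outside the grid on axis {motion_axis} "
                f"(support [{lo},{hi}], shifts [{smin:.2f},{smax:.2f}] voxels)"
            )

    rng = np.random.default_rng(seed) if noise_scale > 0 else None
    frames = []
    for sv in shifts_vox:
        if sv == 0.0:
            moved = fg
        else:
            moved = _shift_axis_linear(fg, sv, motion_axis)
        vals = np.maximum(background_suv + moved, 0.0)
        if rng is not None:
            vals = rng.poisson(vals * noise_scale).astype(np.float64) / noise_scale
        frames.append(PhantomImage(vals, truth.spacing_mm))
    return FrameStack(tuple(frames), trace, truth)


def sum_frames(stack: FrameStack, selection: Sequence[int]) -> PhantomImage:
    """Voxelwise mean over the selected frames (mean keeps the SUV scale)."""
    sel = np.asarray(selection, dtype=np.intp)
    if sel.size == 0:
        raise ValueError("selection must be non-empty")
    n = len(stack)
    if sel.min() < 0 or sel.max() >= n:
        raise ValueError("selection contains out-of-range frame indices")
    acc = np.zeros(stack.truth.shape)
    for k in sel:
        acc += stack.frames[k].values
    return PhantomImage(acc / sel.size, stack.truth.spacing_mm)


def default_phantom_spec(
    seed: int = 0,
    noise_scale: float = 0.0,
    lesion_peak_suv: float = 8.0,
    lesion_radius_mm: float = 16.0,
    core_suv: float = 2.5,
    core_radius_mm: float = 6.0,
    texture_frac: float = 0.3,
) -> PhantomSpec:
    """The study-condition phantom: a heterogeneous hot lesion with necrotic core.

    Lesion sized for a pancreatic primary (~14 ml at a 16 mm radius), peak
    8 SUV on a 1 SUV background, at the center of a 40x40x48 grid of 4.07 mm
    voxels, with the necrotic core offset from the lesion center and a
    seeded correlated texture field (30% SD, 10 mm correlation length)
    modelling intra-tumoral heterogeneity.
    """
    shape = (40, 40, 48)
    spacing = (4.07, 4.07, 4.07)
    center = tuple((n - 1) // 2 * s for n, s in zip(shape, spacing))
    core_center = (center[0] + 6.0, center[1], center[2] + 6.0)
    return PhantomSpec(
        grid_shape=shape,
        voxel_spacing_mm=spacing,
        background_suv=1.0,
        lesion_centers_mm=(center,),
        lesion_radii_mm=(lesion_radius_mm,),
        lesion_peak_suv=(lesion_peak_suv,),
        necrotic_core=NecroticCore(core_center, core_radius_mm, core_suv),
        psf_fwhm_mm=3.0,
        noise_scale=noise_scale,
        seed=seed,
        texture_frac=texture_frac,
    )
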