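"""SNR and FWHM image-quality evaluation of gating schemes.

SNR is ``10 log10(mean / SD)`` over a homogeneous volume of interest, in dB;
for a gated scheme it is evaluated on the voxelwise sum of all gates.  The
dependence on gate count is summarised by fitting ``a + b log10(n)``, and a
scheme is acceptable when its summed-image SNR is within 3 dB of the
non-gated image.  Spatial resolution is quantified as the FWHM of a line
profile through a feature (hot spot or myocardial wall), with the relative
difference between dual-gated and non-gated FWHM as the blur-reduction
figure of merit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateFitError, InputError, ProfileError, SnrError
from .phantom_sim import GatedImageSet, VolumeImage

__all__ = [
    "VOI",
    "LineProfile",
    "SnrCurveFit",
    "snr_voi",
    "scheme_snr",
    "fit_snr_curve",
    "snr_criterion",
    "extract_profile",
    "fwhm",
    "relative_fwhm_difference",
]

#: maximum tolerated SNR loss from non-gated to optimally gated images (dB)
SNR_LOSS_LIMIT_DB = 3.0


@dataclass(frozen=True)
class VOI:
    """A box or ellipsoid volume of interest in voxel coordinates.

    ``center`` is a voxel index triple, ``extents`` the full size along each
    axis in voxels.  Conventional sizes: 13x13x13 voxels inside a phantom's
    inner balloon, 10x15x15 in a patient's lung.
    """

    center: tuple[int, int, int]
    extents: tuple[int, int, int] = (13, 13, 13)
    shape: str = "box"

    def __post_init__(self):
        if self.shape not in ("box", "ellipsoid"):
            raise InputError(f"unknown VOI shape {self.shape!r}")
        if any(e < 1 for e in self.extents):
            raise InputError("VOI extents must be >= 1 voxel")

    def mask(self, volume_shape: tuple[int, int, int]) -> np.ndarray:
        # for even extents the centre voxel sits just left of the middle
        lo = [self.center[k] - (self.extents[k] - 1) // 2 for k in range(3)]
        hi = [lo[k] + self.extents[k] for k in range(3)]
        if any(lo[k] < 0 or hi[k] > volume_shape[k] for k in range(3)):
            raise InputError(
                f"VOI {lo}..{hi} does not fit inside volume {volume_shape}"
            )
        mask = np.zeros(volume_shape, dtype=bool)
        if self.shape == "box":
            mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
            return mask
        half = [e / 2.0 for e in self.extents]
        axes = [np.arange(volume_shape[k]) - self.center[k] for k in range(3)]
        rho = (
            (axes[0][:, None, None] / half[0]) ** 2
            + (axes[1][None, :, None] / half[1]) ** 2
            + (axes[2][None, None, :] / half[2]) ** 2
        )
        return rho <= 1.0


@dataclass(frozen=True)
class LineProfile:
    """Intensities sampled at uniform spacing along a straight segment."""

    values: np.ndarray
    spacing_mm: float
    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 3:
            raise InputError("a profile needs at least 3 samples")
        if self.spacing_mm <= 0:
            raise InputError("spacing must be positive")


@dataclass(frozen=True)
class SnrCurveFit:
    """Least-squares fit of SNR_dB = a + b log10(n_gates)."""

    a: float
    b: float
    rmse_db: float

    def predict(self, n: float) -> float:
        return self.a + self.b * np.log10(n)


def snr_voi(volume: VolumeImage, voi: VOI, ddof: int = 0) -> float:
    """SNR (dB) of a homogeneous VOI: 10 log10(mean / SD).

    ``ddof=0`` (population SD over the N VOI voxels) by default; set
    ``ddof=1`` for the sample convention.
    """
    values = volume.voxels[voi.mask(volume.shape)].astype(float)
    if values.size < 2:
        raise InputError("VOI must contain at least 2 voxels")
    sd = values.std(ddof=ddof)
    mean = values.mean()
    if sd == 0:
        raise SnrError("zero standard deviation: SNR is infinite")
    if mean <= 0:
        raise SnrError("non-positive VOI mean: SNR undefined")
    return float(10.0 * np.log10(mean / sd))


def scheme_snr(image_set: GatedImageSet, voi: VOI, ddof: int = 0) -> float:
    """SNR (dB) of the voxelwise sum over all gates of a scheme."""
    return snr_voi(image_set.summed(), voi, ddof=ddof)


def fit_snr_curve(points: Iterable[tuple[float, float]]) -> SnrCurveFit:
    """Fit ``a + b log10(n)`` to (total gate count, SNR dB) points."""
    pts = [(float(n), float(s)) for n, s in points]
    if len({n for n, _ in pts}) < 2:
        raise DegenerateFitError("need at least two distinct gate counts")
    n = np.array([x for x, _ in pts])
    s = np.array([y for _, y in pts])
    if (n < 1).any():
        raise InputError("gate counts must be >= 1")
    X = np.column_stack([np.ones_like(n), np.log10(n)])
    (a, b), *_ = np.linalg.lstsq(X, s, rcond=None)
    resid = s - (a + b * np.log10(n))
    return SnrCurveFit(a=float(a), b=float(b), rmse_db=float(np.sqrt(np.mean(resid**2))))


def snr_criterion(snr_nongated_db: float, snr_optimal_db: float) -> bool:
    """True when gating costs at most 3 dB of summed-image SNR."""
    if not (np.isfinite(snr_nongated_db) and np.isfinite(snr_optimal_db)):
        raise InputError("SNR values must be finite")
    return (snr_nongated_db - snr_optimal_db) <= SNR_LOSS_LIMIT_DB


def extract_profile(
    volume: VolumeImage,
    p0_mm: Sequence[float],
    p1_mm: Sequence[float],
    spacing_mm: float | None = None,
) -> LineProfile:
    """Trilinear line profile between two mm positions.

    Default spacing is half the smallest voxel dimension.
    """
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    for point in (p0, p1):
        vox = volume.mm_to_voxel(point)
        if ((vox < 0) | (vox > np.array(volume.shape) - 1)).any():
            raise ProfileError(f"profile endpoint {point} lies outside the volume")
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ProfileError("zero-length profile segment")
    if spacing_mm is None:
        spacing_mm = min(volume.voxel_size_mm) / 2.0
    n = int(np.floor(length / spacing_mm)) + 1
    ts = np.linspace(0.0, (n - 1) * spacing_mm / length, n)
    points = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    coords = np.stack(
        [
            (points[:, k] - volume.origin_mm[k]) / volume.voxel_size_mm[k]
            for k in range(3)
        ]
    )
    values = ndimage.map_coordinates(
        volume.voxels.astype(float), coords, order=1, mode="nearest"
    )
    return LineProfile(values=values, spacing_mm=spacing_mm,
                       endpoints=(tuple(p0), tuple(p1)))


def fwhm(profile: LineProfile) -> float:
    """Full width at half maximum (mm) of a single-peaked profile.

    The half level sits midway between the profile's maximum and its
    minimum (taken as baseline).  Each crossing is located by linear
    interpolation between the bracketing samples nearest the peak; a side
    that never descends below the half level raises ``ProfileError``.
    """
    v = profile.values
    peak = int(np.argmax(v))
    if peak == 0 or peak == v.size - 1:
        raise ProfileError("profile maximum lies on an endpoint (open profile)")
    base = float(v.min())
    top = float(v[peak])
    if top <= base:
        raise ProfileError("flat profile: no peak above baseline")
    half = (top + base) / 2.0

    def crossing(direction: int) -> float:
        i = peak
        while 0 <= i + direction < v.size:
            j = i + direction
            if v[j] < half:
                # interpolate between samples i (>= half) and j (< half)
                frac = (v[i] - half) / (v[i] - v[j])
                return i + direction * frac
            i = j
        raise ProfileError("profile does not cross half maximum on one side")

    left = crossing(-1)
    right = crossing(+1)
    return float((right - left) * profile.spacing_mm)


def relative_fwhm_difference(fwhm_dg: float, fwhm_ng: float) -> float:
    """Percentage FWHM change of dual-gated relative to non-gated images."""
    if fwhm_ng <= 0:
        raise InputError("reference FWHM must be positive")
    return (fwhm_dg - fwhm_ng) / fwhm_ng * 100.0
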