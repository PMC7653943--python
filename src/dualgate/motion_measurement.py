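"""Measure respiratory and cardiac motion from gated image sets.

Respiratory motion is read from cardiac-averaged images (one per respiratory
gate) as the displacement of a tracked feature between the two extreme
gates; cardiac motion from respiratory-averaged images as the displacement
of the mid-cycle gate from the average of the cycle's end gates.  Features
are located either as hot spots (local maximum, or the intensity-weighted
centroid of voxels above 90% of it) or as the centre of mass of the
extracted myocardium (CMA).  The resulting per-scheme motion table feeds the
capture-law fits of :mod:`dualgate.motion_models`.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ExtractionError, InputError, LocalisationError
from .motion_models import GateScheme, MotionSample
from .phantom_sim import GatedImageSet, VolumeImage

__all__ = [
    "locate_hotspot",
    "locate_hotspot_component",
    "extract_myocardium",
    "cma",
    "average_over_cardiac",
    "average_over_respiratory",
    "measure_extreme_motion",
    "measure_scheme_motion",
    "build_motion_table",
    "build_motion_samples",
    "resp_samples",
    "card_samples",
]

#: default half-maximum-of-max threshold for hot-spot centroiding
HOTSPOT_THRESHOLD = 0.9
#: default neighbourhood radius around the maximum, as a multiple of the
#: scanner FWHM, used to isolate one hot spot from its neighbours
NEIGHBOURHOOD_FWHM = 3.0


def _region_slices(volume: VolumeImage, search_region):
    if search_region is None:
        return tuple(slice(0, s) for s in volume.shape)
    slices = []
    for k, (lo, hi) in enumerate(search_region):
        if not (0 <= lo < hi <= volume.shape[k]):
            raise InputError(
                f"search region {search_region} exceeds volume shape {volume.shape}"
            )
        slices.append(slice(int(lo), int(hi)))
    return tuple(slices)


def locate_hotspot(
    volume: VolumeImage,
    method: str = "weighted90",
    search_region=None,
    resolution_fwhm_mm: float = 5.2,
) -> np.ndarray:
    """Locate the brightest hot spot, returning its mm position.

    ``local_max`` returns the centre of the maximum voxel in the (optional)
    search region.  ``weighted90`` returns the intensity-weighted centroid
    of voxels at or above ``HOTSPOT_THRESHOLD`` of that maximum, restricted
    to within ``NEIGHBOURHOOD_FWHM * resolution_fwhm_mm`` of it so that
    neighbouring spots do not bleed in.
    """
    slices = _region_slices(volume, search_region)
    sub = volume.voxels[slices]
    if sub.size == 0:
        raise InputError("empty search region")
    vmax = float(sub.max())
    if vmax <= float(sub.min()):
        raise LocalisationError("no unique maximum: region is flat")
    peak_local = np.unravel_index(int(np.argmax(sub)), sub.shape)
    peak = tuple(peak_local[k] + slices[k].start for k in range(3))
    if method == "local_max":
        return volume.voxel_to_mm(peak)
    if method != "weighted90":
        raise InputError(f"unknown hot-spot method {method!r}")
    radius_mm = NEIGHBOURHOOD_FWHM * resolution_fwhm_mm
    lo = [max(int(np.floor(peak[k] - radius_mm / volume.voxel_size_mm[k])), 0)
          for k in range(3)]
    hi = [min(int(np.ceil(peak[k] + radius_mm / volume.voxel_size_mm[k])) + 1,
              volume.shape[k]) for k in range(3)]
    nb = tuple(
        slice(max(lo[k], slices[k].start), min(hi[k], slices[k].stop))
        for k in range(3)
    )
    box = volume.voxels[nb].astype(float)
    # evaluate the centroid on a spline-interpolated fine grid (quarter-voxel
    # pitch); on coarse grids the >= 90% region can be a single voxel, which
    # would quantise the position to the voxel lattice
    fine_axes = [
        np.linspace(0.0, box.shape[k] - 1.0, max(4 * (box.shape[k] - 1) + 1, 2))
        for k in range(3)
    ]
    mesh = np.meshgrid(*fine_axes, indexing="ij")
    values = ndimage.map_coordinates(
        box, [m.ravel() for m in mesh], order=3, mode="nearest"
    )
    vmax_fine = values.max()
    mask = values >= HOTSPOT_THRESHOLD * vmax_fine
    if not mask.any():
        raise LocalisationError("no voxels above the hot-spot threshold")
    weights = values[mask]
    centroid_vox = np.array(
        [m.ravel()[mask] @ weights for m in mesh]
    ) / weights.sum() + np.array([nb[k].start for k in range(3)])
    return volume.voxel_to_mm(centroid_vox)


def locate_hotspot_component(
    volume: VolumeImage,
    threshold_fraction: float = 0.5,
    search_region=None,
) -> np.ndarray:
    """Intensity centroid of the connected component containing the maximum.

    A mean-based hot-spot position: all voxels of the peak's 26-connected
    component at or above ``threshold_fraction`` of the peak contribute,
    weighted by intensity.  Unlike the near-maximum centroid this integrates
    the full extent of a motion-smeared spot, so on gate-averaged images
    (where residual motion turns the spot into a broad ridge) it tracks the
    mean displacement instead of the noisy location of the ridge top.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InputError("threshold_fraction must lie strictly between 0 and 1")
    slices = _region_slices(volume, search_region)
    sub = volume.voxels[slices].astype(float)
    if sub.size == 0:
        raise InputError("empty search region")
    if float(sub.max()) <= float(sub.min()):
        raise LocalisationError("no unique maximum: region is flat")
    peak = np.unravel_index(int(np.argmax(sub)), sub.shape)
    # reference level from the mean of the top few voxels: robust to a
    # single noisy spike inflating the threshold
    top = np.sort(sub, axis=None)[-min(5, sub.size):]
    vref = float(top.mean())
    binary = sub >= threshold_fraction * vref
    structure = ndimage.generate_binary_structure(3, 3)
    labels, _ = ndimage.label(binary, structure=structure)
    mask = labels == labels[peak]
    weights = sub[mask]
    idx = np.argwhere(mask).astype(float)
    centroid = (idx * weights[:, None]).sum(axis=0) / weights.sum()
    centroid += np.array([slices[k].start for k in range(3)])
    return volume.voxel_to_mm(centroid)


def extract_myocardium(
    volume: VolumeImage, threshold_fraction: float = 0.5
) -> np.ndarray:
    """Boolean mask: largest connected component above a fractional threshold.

    26-connectivity; the threshold is relative to the volume maximum.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InputError("threshold_fraction must lie strictly between 0 and 1")
    vmax = float(volume.voxels.max())
    if vmax <= 0:
        raise ExtractionError("volume has no positive intensity")
    binary = volume.voxels >= threshold_fraction * vmax
    structure = ndimage.generate_binary_structure(3, 3)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        raise ExtractionError("threshold produced an empty mask")
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def cma(volume: VolumeImage, mask: np.ndarray) -> np.ndarray:
    """Intensity-weighted centre of mass (mm) over the masked voxels."""
    if mask.shape != volume.shape:
        raise InputError("mask shape does not match the volume")
    if not mask.any():
        raise InputError("empty mask")
    weights = volume.voxels[mask]
    total = weights.sum()
    if total <= 0:
        raise InputError("zero total intensity inside the mask")
    idx = np.argwhere(mask).astype(float)
    centroid_vox = (idx * weights[:, None]).sum(axis=0) / total
    return volume.voxel_to_mm(centroid_vox)


def _mean_volume(volumes: Sequence[VolumeImage]) -> VolumeImage:
    ref = volumes[0]
    total = np.zeros(ref.shape)
    for v in volumes:
        total += v.voxels
    return VolumeImage(total / len(volumes), ref.voxel_size_mm, ref.origin_mm)


def average_over_cardiac(image_set: GatedImageSet) -> list[VolumeImage]:
    """One cardiac-averaged image per respiratory gate (ordered by gate)."""
    r, p = image_set.scheme.n_resp, image_set.scheme.n_card
    return [
        _mean_volume([image_set.volumes[(i, j)] for j in range(1, p + 1)])
        for i in range(1, r + 1)
    ]


def average_over_respiratory(image_set: GatedImageSet) -> list[VolumeImage]:
    """One respiratory-averaged image per cardiac gate (ordered by gate)."""
    r, p = image_set.scheme.n_resp, image_set.scheme.n_card
    return [
        _mean_volume([image_set.volumes[(i, j)] for i in range(1, r + 1)])
        for j in range(1, p + 1)
    ]


def _locate(volume: VolumeImage, locator: str, **kwargs) -> np.ndarray:
    if locator == "hotspot_local_max":
        return locate_hotspot(volume, "local_max", **kwargs)
    if locator == "hotspot_weighted90":
        return locate_hotspot(volume, "weighted90", **kwargs)
    if locator == "hotspot_component":
        kwargs.pop("resolution_fwhm_mm", None)
        return locate_hotspot_component(volume, **kwargs)
    if locator == "cma":
        threshold = kwargs.pop("threshold_fraction", 0.5)
        mask = extract_myocardium(volume, threshold)
        return cma(volume, mask)
    raise InputError(f"unknown locator {locator!r}")


def measure_extreme_motion(
    images: Sequence[VolumeImage],
    locator: str = "hotspot_weighted90",
    mode: str = "respiratory",
    **locator_kwargs,
) -> float:
    """Motion (mm) between the extreme motion states of an ordered gate list.

    ``respiratory``: Euclidean distance between the feature positions in the
    first and last image (end-expiration vs peak-inspiration).
    ``cardiac``: distance between the mid-cycle image's position and the
    average position of the two end images (systole/diastole vs mid-cycle);
    for an even count the later of the two middle gates is used.
    """
    if len(images) < 2:
        raise InputError("need at least two images")
    if mode == "respiratory":
        p0 = _locate(images[0], locator, **locator_kwargs)
        p1 = _locate(images[-1], locator, **locator_kwargs)
        return float(np.linalg.norm(p1 - p0))
    if mode == "cardiac":
        p_first = _locate(images[0], locator, **locator_kwargs)
        p_last = _locate(images[-1], locator, **locator_kwargs)
        p_mid = _locate(images[len(images) // 2], locator, **locator_kwargs)
        return float(np.linalg.norm(p_mid - (p_first + p_last) / 2.0))
    raise InputError(f"unknown mode {mode!r}")


def _tracking_box(image_set: GatedImageSet, half_mm=(9.0, 9.0, 18.0)):
    """Search box around the brightest spot of the scheme-summed image.

    Locating once on the summed image (all counts) fixes the tracked spot's
    identity; the per-gate search is then confined to a box wide enough for
    the residual gate-to-gate motion but excluding the neighbouring spots.
    """
    summed = image_set.summed()
    center = locate_hotspot_component(summed)
    center_vox = summed.mm_to_voxel(center)
    region = []
    for k in range(3):
        half_vox = half_mm[k] / summed.voxel_size_mm[k]
        lo = max(int(np.floor(center_vox[k] - half_vox)), 0)
        hi = min(int(np.ceil(center_vox[k] + half_vox)) + 1, summed.shape[k])
        region.append((lo, hi))
    return tuple(region)


def measure_scheme_motion(
    image_set: GatedImageSet,
    locator: str = "hotspot_component",
    track: bool = True,
    **locator_kwargs,
) -> tuple[float, float]:
    """(respiratory, cardiac) motion in mm for one gated set.

    Respiratory motion is measured across the cardiac-averaged images and
    cardiac motion across the respiratory-averaged images; single-gate axes
    capture no motion by construction and measure 0.  With ``track`` the
    hot-spot locators are confined to a box around the spot found in the
    scheme-summed image, so noise cannot switch the tracked spot's identity
    between gates.
    """
    if track and locator != "cma" and "search_region" not in locator_kwargs:
        locator_kwargs = {
            **locator_kwargs,
            "search_region": _tracking_box(image_set),
        }
    resp_imgs = average_over_cardiac(image_set)
    card_imgs = average_over_respiratory(image_set)
    resp_mm = (
        measure_extreme_motion(resp_imgs, locator, "respiratory", **locator_kwargs)
        if len(resp_imgs) >= 2
        else 0.0
    )
    card_mm = (
        measure_extreme_motion(card_imgs, locator, "cardiac", **locator_kwargs)
        if len(card_imgs) >= 2
        else 0.0
    )
    return resp_mm, card_mm


def build_motion_table(
    sets: Iterable[tuple[GateScheme, GatedImageSet]] | Mapping[GateScheme, GatedImageSet],
    locator: str = "hotspot_component",
    **locator_kwargs,
) -> pd.DataFrame:
    """Per-scheme motion table with columns
    ``n_resp, n_card, resp_mm, card_mm, total_mm``."""
    if isinstance(sets, Mapping):
        sets = sets.items()
    rows = []
    for scheme, image_set in sets:
        resp_mm, card_mm = measure_scheme_motion(image_set, locator, **locator_kwargs)
        rows.append(
            {
                "n_resp": scheme.n_resp,
                "n_card": scheme.n_card,
                "resp_mm": resp_mm,
                "card_mm": card_mm,
                "total_mm": resp_mm + card_mm,
            }
        )
    if len(rows) < 2:
        raise InputError("need measurements from at least two schemes")
    return pd.DataFrame(rows)


def build_motion_samples(sets, locator: str = "hotspot_component", **kwargs):
    """Total-motion :class:`MotionSample` list for the dual-model fit."""
    table = build_motion_table(sets, locator, **kwargs)
    return table_to_samples(table)


def table_to_samples(table: pd.DataFrame) -> list[MotionSample]:
    return [
        MotionSample(GateScheme(int(r.n_resp), int(r.n_card)), float(r.total_mm))
        for r in table.itertuples()
    ]


def resp_samples(table: pd.DataFrame) -> list[tuple[int, float]]:
    """(r, respiratory motion) pairs for the single-mode respiratory fit."""
    return [(int(r.n_resp), float(r.resp_mm)) for r in table.itertuples()]


def card_samples(table: pd.DataFrame) -> list[tuple[int, float]]:
    """(p, cardiac motion) pairs for the single-mode cardiac fit."""
    return [(int(r.n_card), float(r.card_mm)) for r in table.itertuples()]
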