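"""Rules-based nonperfusion-area segmentation.

The pipeline has five stages:

1. multiscale Frangi vesselness enhancement of the angiographic image;
2. adaptive binarization of the vesselness response, with the local threshold
   modulated downward where structural reflectance is low (signal
   compensation, so attenuated-but-perfused regions keep their vessels);
3. exact Euclidean distance transform of the binary vessel map (each pixel
   holds the distance to the nearest vessel);
4. thresholding of the distance map, with the threshold calibrated on
   healthy-control scans so that no NPA is detected outside the fovea;
5. morphological opening and removal of small connected components so tiny
   nonpathological intercapillary gaps are not reported as NPA.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .config import RBParams
from .types import EnFaceScan, Method, NPAMask

__all__ = [
    "CalibrationError",
    "vesselness_filter",
    "adaptive_binarize",
    "vessel_distance_map",
    "extrafoveal_region",
    "calibrate_distance_threshold",
    "segment_npa_rb",
]


class CalibrationError(RuntimeError):
    """No candidate threshold removed all extrafoveal NPA on healthy scans."""

    def __init__(self, max_residual_mm2: float):
        self.max_residual_mm2 = max_residual_mm2
        super().__init__(
            "no threshold on the calibration grid yields zero extrafoveal NPA "
            f"(max residual {max_residual_mm2:.4f} mm^2 at the largest threshold)"
        )


def _frangi_single_scale(
    image: np.ndarray, sigma: float, beta: float, c: float
) -> np.ndarray:
    """2D Frangi vesselness at one scale (bright curvilinear structures).

    Scale-normalized Hessian (separable Gaussian derivatives times sigma^2),
    eigenvalues |l1| <= |l2|; response = exp(-Rb^2 / 2 beta^2) *
    (1 - exp(-S^2 / 2 c^2)) where Rb = l1/l2 (blobness) and
    S = sqrt(l1^2 + l2^2) (second-order structure), zero where l2 >= 0.
    Built on separable filters, so it is exactly transpose-equivariant.
    """
    # The discrete 2nd-derivative Gaussian kernel does not sum exactly to
    # zero; subtract the residual (kernel sum times the local mean) so a
    # constant image yields an exactly flat Hessian.
    m = 2 * int(4.0 * sigma + 0.5) + 3
    ones = np.ones((m, m))
    k_res = ndimage.gaussian_filter(ones, sigma, order=(2, 0))[m // 2, m // 2]
    smooth = ndimage.gaussian_filter(image, sigma)
    hrr = (ndimage.gaussian_filter(image, sigma, order=(2, 0)) - k_res * smooth) * sigma**2
    hcc = (ndimage.gaussian_filter(image, sigma, order=(0, 2)) - k_res * smooth) * sigma**2
    hrc = ndimage.gaussian_filter(image, sigma, order=(1, 1)) * sigma**2
    tmp = np.sqrt((hrr - hcc) ** 2 + 4.0 * hrc**2)
    mu1 = (hrr + hcc + tmp) / 2.0
    mu2 = (hrr + hcc - tmp) / 2.0
    # order by absolute value: |l1| <= |l2|
    swap = np.abs(mu1) > np.abs(mu2)
    l1 = np.where(swap, mu2, mu1)
    l2 = np.where(swap, mu1, mu2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
    s2 = l1**2 + l2**2
    response = np.exp(-rb2 / (2.0 * beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c**2)))
    return np.where(l2 < 0, response, 0.0)


def vesselness_filter(angio: np.ndarray, params: RBParams) -> np.ndarray:
    """Multiscale Hessian tubularity response (bright-on-dark), max over scales.

    Returns values in [0, 1]; flat regions score 0.
    """
    angio = np.asarray(angio, float)
    if angio.ndim != 2 or min(angio.shape) < 3:
        raise ValueError("angio must be a 2D grid with at least 3 pixels per axis")
    if not np.all(np.isfinite(angio)):
        raise ValueError("angio must be finite-valued")
    response = np.zeros(angio.shape)
    for sigma in params.vesselness_scales_px:
        np.maximum(
            response,
            _frangi_single_scale(
                angio, float(sigma), params.vesselness_beta, params.vesselness_c
            ),
            out=response,
        )
    return np.clip(response, 0.0, 1.0)


def adaptive_binarize(
    vesselness: np.ndarray, structure: np.ndarray, params: RBParams
) -> np.ndarray:
    """Binarize the vesselness response against a reflectance-aware local mean.

    The per-pixel threshold is the local mean of the vesselness over a
    ``binarize_window_px`` window, scaled down where normalized structural
    reflectance is low (``reflectance_compensation_strength`` in [0, 1] sets
    how strongly shadows lower the bar), minus ``binarize_offset``.  A pixel
    is vessel iff its vesselness strictly exceeds its threshold.
    """
    if vesselness.shape != structure.shape:
        raise ValueError("vesselness and structure must be co-registered")
    if params.binarize_window_px > min(vesselness.shape):
        raise ValueError("binarize_window_px exceeds the image extent")
    local_mean = ndimage.uniform_filter(
        np.asarray(vesselness, float), size=params.binarize_window_px, mode="reflect"
    )
    ref = float(np.percentile(structure, 99))
    s_norm = np.clip(structure / ref, 0.0, 1.0) if ref > 0 else np.ones_like(structure)
    modulation = 1.0 - params.reflectance_compensation_strength * (1.0 - s_norm)
    threshold = local_mean * modulation - params.binarize_offset
    return vesselness > threshold


def extrafoveal_region(fovea_mask: np.ndarray, dilation_px: float) -> np.ndarray:
    """Pixels farther than ``dilation_px`` (Euclidean) from the foveal disk."""
    fovea_mask = np.asarray(fovea_mask, bool)
    if not fovea_mask.any():
        return np.ones_like(fovea_mask)
    return ndimage.distance_transform_edt(~fovea_mask) > dilation_px


def vessel_distance_map(vessel_mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance (px) from each pixel to the nearest vessel."""
    vessel_mask = np.asarray(vessel_mask, bool)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty; distance map is undefined")
    return ndimage.distance_transform_edt(~vessel_mask)


def _disk(radius: int) -> np.ndarray:
    rr, cc = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return rr**2 + cc**2 <= radius**2


def _postprocess(npa: np.ndarray, params: RBParams, pixel_pitch_mm: float) -> np.ndarray:
    """Morphological opening + small-component removal (8-connectivity)."""
    if params.morphology_radius_px >= 1:
        npa = ndimage.binary_opening(npa, structure=_disk(params.morphology_radius_px))
    min_px = int(np.ceil(params.min_region_area_mm2 / pixel_pitch_mm**2))
    if min_px > 1:
        labels, n = ndimage.label(npa, structure=np.ones((3, 3), int))
        if n:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < min_px)
            npa = npa & ~np.isin(labels, small[small > 0])
    return npa


def _distance_map_for_scan(scan: EnFaceScan, params: RBParams) -> np.ndarray:
    vesselness = vesselness_filter(scan.angio, params)
    vessels = adaptive_binarize(vesselness, scan.structure, params)
    return vessel_distance_map(vessels)


def calibrate_distance_threshold(
    healthy_scans: Sequence[EnFaceScan],
    fovea_masks: Sequence[np.ndarray],
    params: RBParams,
) -> float:
    """Smallest grid threshold with zero extrafoveal NPA on every healthy scan.

    ``fovea_masks`` are the ground-truth foveal avascular disks; each is
    dilated by ``params.fovea_dilation_px`` before "extrafoveal" is assessed.
    Calibration is per anatomical slab: pass the healthy scans of one slab.
    Raises :class:`CalibrationError` if even the largest candidate leaves
    extrafoveal NPA.
    """
    if not healthy_scans:
        raise ValueError("need at least one healthy calibration scan")
    for scan in healthy_scans:
        if scan.etdrs != 10:
            raise ValueError("calibration scans must be healthy (ETDRS level 10)")

    dist_maps = [_distance_map_for_scan(s, params) for s in healthy_scans]
    extrafoveal = [
        extrafoveal_region(m, params.fovea_dilation_px) for m in fovea_masks
    ]
    lo, hi, step = params.calibration_grid_px
    grid = np.arange(lo, hi + step / 2.0, step)

    def residual_px(threshold: float) -> int:
        worst = 0
        for scan, dist, extra in zip(healthy_scans, dist_maps, extrafoveal):
            npa = _postprocess(dist > threshold, params, scan.pixel_pitch_mm)
            worst = max(worst, int(np.count_nonzero(npa & extra)))
        return worst

    def ok(threshold: float) -> bool:
        for scan, dist, extra in zip(healthy_scans, dist_maps, extrafoveal):
            npa = _postprocess(dist > threshold, params, scan.pixel_pitch_mm)
            if np.any(npa & extra):
                return False
        return True

    if not ok(grid[-1]):
        pitch = healthy_scans[0].pixel_pitch_mm
        raise CalibrationError(residual_px(grid[-1]) * pitch**2)

    # Zero-extrafoveal-NPA is monotone in the threshold (superlevel sets of
    # the distance map shrink, and opening/area filtering preserve inclusion),
    # so the smallest passing threshold is found by bisection.
    lo_i, hi_i = 0, len(grid) - 1
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        if ok(grid[mid]):
            hi_i = mid
        else:
            lo_i = mid + 1
    return float(grid[hi_i])


def segment_npa_rb(
    scan: EnFaceScan,
    params: RBParams,
    exclusion: np.ndarray | None = None,
) -> NPAMask:
    """Run the full rules-based pipeline on one scan."""
    dist = _distance_map_for_scan(scan, params)
    npa = _postprocess(dist > params.distance_threshold_px, params, scan.pixel_pitch_mm)
    return NPAMask(
        mask=npa,
        pixel_pitch_mm=scan.pixel_pitch_mm,
        method=Method.RB,
        exclusion=exclusion,
    )


def params_with_threshold(params: RBParams, threshold: float) -> RBParams:
    """Copy of ``params`` with the calibrated distance threshold set."""
    return replace(params, distance_threshold_px=float(threshold))
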