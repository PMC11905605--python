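"""Synthetic en face OCTA cohort generator with known nonperfusion ground truth.

The generator emulates the statistical structure the downstream analysis
relies on, not retinal anatomy per se:

* per eye, a branching capillary network per plexus (SVC coarser, ICP/DCP
  finer; the inner-retina slab is the union of the three) with a central
  foveal avascular zone (FAZ);
* severity-dependent capillary-dropout lesions whose expected extrafoveal
  area is nondecreasing across the clinical severity groups;
* paired angiographic + structural channels, where shadow artifacts attenuate
  BOTH channels (the cue that separates artifact from true nonperfusion);
* additive decorrelation background noise whose level decreases with the
  scan-quality index (SSI), and increases with slab depth;
* a clustered design: participants contribute up to two eyes, eyes up to
  three visits, severity constant within an eye.

Vessel networks are grown by iterative stochastic branching: segments sprout
from boundary seed points and from existing vessels toward the locations
currently farthest from any vessel (a perfusion-demand map), until no
perfused point is farther than the slab's target intercapillary spacing.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import CohortConfig, ConfigError
from .types import (
    GRID,
    PIXEL_PITCH_MM,
    PLEXUSES,
    EnFaceScan,
    GroundTruth,
    Slab,
    disk_mask,
    severity_group,
)

__all__ = [
    "render_vessel_network",
    "plant_npa_lesions",
    "rasterize_scan",
    "generate_cohort",
    "healthy_cohort_config",
]

_SLAB_STREAM = {Slab.SVC: 101, Slab.ICP: 102, Slab.DCP: 103}


# ---------------------------------------------------------------------------
# vessel networks
# ---------------------------------------------------------------------------

def _draw_segment(
    canvas: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    rng: np.random.Generator,
) -> None:
    """Stamp a jittered quadratic path from p0 to p1 onto ``canvas``."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length < 1.0:
        canvas[int(round(p1[0])), int(round(p1[1]))] = True
        return
    perp = np.array([-d[1], d[0]]) / length
    mid = (p0 + p1) / 2.0 + perp * rng.normal(0.0, length / 6.0)
    t = np.linspace(0.0, 1.0, max(int(2 * length), 4))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p1
    rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, canvas.shape[0] - 1)
    cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, canvas.shape[1] - 1)
    canvas[rr, cc] = True


def _render_plexus(
    slab: Slab,
    fovea_center: tuple[float, float],
    fovea_radius_px: float,
    seed: int,
    shape: tuple[int, int],
    spacing_px: float,
    caliber_px: float,
    batch: int = 60,
    max_rounds: int = 200,
) -> np.ndarray:
    rng = np.random.default_rng([_SLAB_STREAM[slab], seed])
    canvas = np.zeros(shape, bool)
    h, w = shape

    # Feeding vessels enter from the scan border.
    n_seeds = 16
    for k in range(n_seeds):
        side = k % 4
        pos = rng.uniform(0, h - 1)
        if side == 0:
            canvas[0, int(pos * (w - 1) / (h - 1))] = True
        elif side == 1:
            canvas[h - 1, int(pos * (w - 1) / (h - 1))] = True
        elif side == 2:
            canvas[int(pos), 0] = True
        else:
            canvas[int(pos), w - 1] = True

    fovea = (
        disk_mask(shape, fovea_center, fovea_radius_px)
        if fovea_radius_px > 0
        else np.zeros(shape, bool)
    )
    perfused = ~fovea

    for _ in range(max_rounds):
        dist, (ir, ic) = ndimage.distance_transform_edt(~canvas, return_indices=True)
        demand = (dist > spacing_px) & perfused
        idx = np.flatnonzero(demand)
        if idx.size == 0:
            break
        take = min(batch, idx.size)
        chosen = rng.choice(idx, size=take, replace=False)
        for flat in chosen:
            r, c = divmod(int(flat), w)
            _draw_segment(canvas, (ir[r, c], ic[r, c]), (r, c), rng)

    if caliber_px >= 1.0:
        canvas = ndimage.binary_dilation(
            canvas, structure=_disk_structure(int(round(caliber_px)))
        )
    canvas &= perfused
    return canvas


def _disk_structure(radius: int) -> np.ndarray:
    rr, cc = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return rr**2 + cc**2 <= radius**2


def render_vessel_network(
    slab: Slab | str,
    fovea_radius_px: float,
    seed: int,
    *,
    shape: tuple[int, int] = (GRID, GRID),
    fovea_center: tuple[float, float] | None = None,
    slab_params: dict[str, dict[str, float]] | None = None,
) -> np.ndarray:
    """Grow a branching vessel mask for one slab.

    The same ``seed`` makes the inner-retina mask exactly the elementwise OR
    of the three plexus masks, because each plexus draws from its own seed
    stream keyed by (slab, seed).
    """
    slab = Slab(slab)
    if fovea_radius_px >= min(shape) / 2:
        raise ValueError("fovea_radius_px must be smaller than the grid half-width")
    if fovea_center is None:
        fovea_center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    if slab_params is None:
        from .config import _default_slab_params

        slab_params = _default_slab_params()

    if slab is Slab.INNER:
        out = np.zeros(shape, bool)
        for plexus in PLEXUSES:
            out |= render_vessel_network(
                plexus,
                fovea_radius_px,
                seed,
                shape=shape,
                fovea_center=fovea_center,
                slab_params=slab_params,
            )
        return out

    p = slab_params[slab.value]
    return _render_plexus(
        slab,
        fovea_center,
        fovea_radius_px,
        seed,
        shape,
        spacing_px=float(p["spacing_px"]),
        caliber_px=float(p["caliber_px"]),
    )


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def plant_npa_lesions(
    vessel_mask: np.ndarray,
    lesion_model: dict[str, dict[str, float]],
    etdrs: int,
    seed: int,
    *,
    fovea_center: tuple[float, float],
    fovea_radius_px: float,
    pixel_pitch_mm: float = PIXEL_PITCH_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Carve severity-dependent capillary-dropout lesions out of a vessel mask.

    Returns ``(vessel_mask_without_lesions, npa_mask)`` where the NPA mask is
    the union of the planted lesion blobs and the foveal avascular disk.
    ETDRS level 10 (no retinopathy) plants zero lesions.  Lesion blobs are
    randomly oriented ellipses placed fully outside the fovea and away from
    each other, so the expected extrafoveal NPA equals the configured
    per-severity mean (a Gamma-distributed total split across lesions).
    """
    shape = vessel_mask.shape
    rng = np.random.default_rng([7, seed])
    npa = disk_mask(shape, fovea_center, fovea_radius_px)

    if etdrs != 10:
        group = severity_group(etdrs)
        if group not in lesion_model:
            raise ConfigError(f"lesion_model missing severity group {group!r}")
        entry = lesion_model[group]
        mean_area = float(entry["mean_area_mm2"])
        mean_count = float(entry.get("mean_count", 3.0))
        min_lesion = float(entry.get("min_lesion_mm2", 0.05))

        max_lesion = float(entry.get("max_lesion_mm2", 0.5))
        if mean_area > 0:
            total_mm2 = rng.gamma(shape=3.0, scale=mean_area / 3.0)
            n = 1 + int(rng.poisson(max(mean_count - 1.0, 0.0)))
            # cap individual blob size so every blob stays placeable in the
            # extrafoveal field, and respect the minimum lesion size
            n = max(n, int(math.ceil(total_mm2 / max_lesion)))
            if total_mm2 >= min_lesion:
                n = max(1, min(n, int(total_mm2 // min_lesion)))
            else:
                n = 1
            for _ in range(20):
                splits = total_mm2 * rng.dirichlet(np.full(n, 6.0))
                if n == 1 or (splits.min() >= min_lesion and splits.max() <= 1.5 * max_lesion):
                    break
                if splits.max() > 1.5 * max_lesion:
                    n += 1
                else:
                    n = max(1, n - 1)
            lesions = np.zeros(shape, bool)
            for area_mm2 in np.sort(splits)[::-1]:
                area_px = area_mm2 / pixel_pitch_mm**2
                q = rng.uniform(0.45, 1.0)
                a = math.sqrt(area_px / (math.pi * q))
                b = q * a
                theta = rng.uniform(0.0, math.pi)
                margin = a + 4.0
                for _attempt in range(200):
                    cr = rng.uniform(margin, shape[0] - 1 - margin)
                    cc = rng.uniform(margin, shape[1] - 1 - margin)
                    gap = math.hypot(cr - fovea_center[0], cc - fovea_center[1])
                    if gap <= fovea_radius_px + a + 6.0:
                        continue
                    ell = _ellipse_mask(shape, (cr, cc), a, b, theta)
                    if not np.any(ell & lesions):
                        lesions |= ell
                        break
            npa |= lesions

    vessel_out = vessel_mask & ~npa
    return vessel_out, npa


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Zero-mean smooth random field with unit-ish amplitude."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    span = np.abs(f).max()
    return f / span if span > 0 else f


def rasterize_scan(
    vessel_mask: np.ndarray,
    npa_mask: np.ndarray,
    shadow_spec: Sequence[dict] | None,
    ssi: float,
    seed: int,
    *,
    slab: Slab | str = Slab.SVC,
    etdrs: int = 10,
    noise_model: dict[str, float] | None = None,
    slab_noise_factor: float = 1.0,
    participant_id: str = "P0000",
    eye_id: str = "P0000_OD",
    visit_index: int = 1,
    fovea_center: tuple[float, float] | None = None,
    fovea_radius_px: float = 0.0,
    pixel_pitch_mm: float = PIXEL_PITCH_MM,
) -> tuple[EnFaceScan, GroundTruth]:
    """Render an (angio, structure) image pair from masks and acquisition state.

    The angiographic channel is vessel flow signal plus additive clipped
    Gaussian decorrelation noise with sd = factor * (a + b*(100 - SSI)); the
    structural channel is a smooth bright reflectance field.  Each shadow in
    ``shadow_spec`` (dicts with ``center``, ``radius_px``, ``attenuation``)
    multiplies BOTH channels by its attenuation inside a soft-edged disk.
    """
    if not 0.0 <= ssi <= 100.0:
        raise ValueError(f"ssi must lie in [0, 100], got {ssi}")
    if noise_model is None:
        noise_model = {"a": 0.02, "b": 0.003}
    shape = vessel_mask.shape
    rng = np.random.default_rng([13, seed])

    # Flow signal: vessels at high decorrelation with gentle spatial
    # variation; the overall flow amplitude scales with signal strength
    # (weak signal yields weak decorrelation contrast).
    variation = 0.5 * (_smooth_field(rng, shape, 12.0) + 1.0)  # in [0, 1]
    amplitude = 0.6 + 0.4 * ssi / 100.0
    angio = vessel_mask * amplitude * (0.65 + 0.30 * variation)

    # Reflectance: bright and smooth; mildly textured when noise is enabled.
    structure = 0.80 + 0.10 * _smooth_field(rng, shape, 20.0)

    # Shadows attenuate the optical signal in both channels.  The additive
    # decorrelation noise floor arises downstream in reconstruction, so it is
    # added AFTER attenuation: inside a shadow the flow signal sinks toward
    # the unchanged noise floor, which is what makes shadowed perfused retina
    # masquerade as nonperfusion.
    shadow_mask = np.zeros(shape, bool)
    if shadow_spec:
        for spec in shadow_spec:
            disk = disk_mask(shape, tuple(spec["center"]), float(spec["radius_px"]))
            att = float(spec["attenuation"])
            soft = ndimage.gaussian_filter(disk.astype(float), 3.0)
            field = 1.0 - (1.0 - att) * soft
            angio = angio * field
            structure = structure * field
            shadow_mask |= disk

    sigma = slab_noise_factor * (noise_model["a"] + noise_model["b"] * (100.0 - ssi))
    if sigma > 0:
        angio = angio + rng.normal(0.0, sigma, shape)
        structure = structure + rng.normal(0.0, 0.25 * sigma, shape)

    # float32 keeps large cohorts comfortably in memory
    angio = np.clip(angio, 0.0, 1.0).astype(np.float32)
    structure = np.clip(structure, 0.0, 1.0).astype(np.float32)

    if fovea_center is None:
        fovea_center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    scan = EnFaceScan(
        angio=angio,
        structure=structure,
        slab=Slab(slab),
        ssi=float(ssi),
        etdrs=int(etdrs),
        participant_id=participant_id,
        eye_id=eye_id,
        visit_index=int(visit_index),
        pixel_pitch_mm=pixel_pitch_mm,
    )
    truth = GroundTruth(
        npa_mask=npa_mask,
        vessel_mask=vessel_mask,
        shadow_mask=shadow_mask,
        fovea_center_px=tuple(fovea_center),
        fovea_radius_px=float(fovea_radius_px),
    )
    return scan, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _sample_shadows(
    rng: np.random.Generator,
    model: dict[str, float],
    shape: tuple[int, int],
    ssi: float = 70.0,
) -> list[dict]:
    prob = model.get("prob", 0.0)
    link = model.get("ssi_link", 0.0)
    prob = float(np.clip(prob * (1.0 + link * (70.0 - ssi)), 0.0, 0.95))
    if rng.uniform() >= prob:
        return []
    n = int(rng.integers(1, int(model.get("max_disks", 2)) + 1))
    out = []
    for _ in range(n):
        radius = rng.uniform(model["radius_lo_px"], model["radius_hi_px"])
        center = (
            rng.uniform(radius, shape[0] - 1 - radius),
            rng.uniform(radius, shape[1] - 1 - radius),
        )
        att = rng.uniform(model["attenuation_lo"], model["attenuation_hi"])
        out.append({"center": center, "radius_px": radius, "attenuation": att})
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[tuple[EnFaceScan, GroundTruth]], pd.DataFrame]:
    """Generate a full clustered cohort.

    Returns the scan records and a long-format cohort table with one row per
    participant x eye x visit x slab, carrying the clustering identifiers the
    statistics layer needs.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (GRID, GRID)
    levels = sorted(config.severity_weights)
    probs = np.array([config.severity_weights[k] for k in levels], float)
    probs = probs / probs.sum()

    records: list[tuple[EnFaceScan, GroundTruth]] = []
    rows: list[dict] = []

    for p in range(config.n_participants):
        pid = f"{config.id_prefix}{p:04d}"
        for e in range(config.eyes_per_participant):
            eye_id = f"{pid}_{'OD' if e == 0 else 'OS'}"
            etdrs = int(levels[rng.choice(len(levels), p=probs)])
            group = severity_group(etdrs)
            fovea_radius = float(
                np.clip(
                    rng.normal(config.fovea_radius_mean_px, config.fovea_radius_sd_px),
                    15.0,
                    45.0,
                )
            )
            fovea_center = (
                (shape[0] - 1) / 2.0 + rng.normal(0.0, 3.0),
                (shape[1] - 1) / 2.0 + rng.normal(0.0, 3.0),
            )
            eye_seed = int(rng.integers(0, 2**31 - 1))

            plexus_masks = {
                slab: render_vessel_network(
                    slab,
                    fovea_radius,
                    eye_seed,
                    shape=shape,
                    fovea_center=fovea_center,
                    slab_params=config.slab_params,
                )
                for slab in PLEXUSES
            }
            inner = np.zeros(shape, bool)
            for m in plexus_masks.values():
                inner |= m

            # One anatomical lesion set per eye, shared across slabs.
            _, npa = plant_npa_lesions(
                inner,
                config.lesion_model,
                etdrs,
                eye_seed,
                fovea_center=fovea_center,
                fovea_radius_px=fovea_radius,
            )
            vessels = {slab: mask & ~npa for slab, mask in plexus_masks.items()}
            vessels[Slab.INNER] = inner & ~npa

            for visit in range(1, config.visits_per_eye + 1):
                ssi = float(
                    np.clip(
                        rng.normal(
                            config.ssi_model[group]["mean"],
                            config.ssi_model[group]["sd"],
                        ),
                        config.ssi_floor,
                        99.0,
                    )
                )
                shadows = _sample_shadows(rng, config.shadow_model, shape, ssi)
                for slab in (Slab.SVC, Slab.ICP, Slab.DCP, Slab.INNER):
                    visit_seed = int(rng.integers(0, 2**31 - 1))
                    scan, truth = rasterize_scan(
                        vessels[slab],
                        npa,
                        shadows,
                        ssi,
                        visit_seed,
                        slab=slab,
                        etdrs=etdrs,
                        noise_model=config.noise_model,
                        slab_noise_factor=float(
                            config.slab_params[slab.value]["noise_factor"]
                        ),
                        participant_id=pid,
                        eye_id=eye_id,
                        visit_index=visit,
                        fovea_center=fovea_center,
                        fovea_radius_px=fovea_radius,
                    )
                    records.append((scan, truth))
                    rows.append(
                        {
                            "scan_index": len(records) - 1,
                            "participant_id": pid,
                            "eye_id": eye_id,
                            "visit_index": visit,
                            "slab": slab.value,
                            "ssi": ssi,
                            "etdrs": etdrs,
                            "severity_group": group,
                            "fovea_radius_px": fovea_radius,
                            "true_npa_mm2": float(npa.sum()) * PIXEL_PITCH_MM**2,
                        }
                    )

    table = pd.DataFrame(rows)
    return records, table


def healthy_cohort_config(
    n_eyes: int,
    seed: int,
    *,
    ssi_mean: float = 75.0,
    ssi_sd: float = 6.0,
    min_ssi: float = 55.0,
    shadows: bool = False,
    id_prefix: str = "H",
) -> CohortConfig:
    """Cohort of healthy-volunteer eyes (ETDRS 10) for RB calibration."""
    cfg = CohortConfig(
        n_participants=n_eyes,
        eyes_per_participant=1,
        visits_per_eye=1,
        severity_weights={10: 1.0},
        seed=seed,
        id_prefix=id_prefix,
    )
    cfg.ssi_model = {
        g: {"mean": ssi_mean, "sd": ssi_sd}
        for g in ("nonreferable", "referable", "vision_threatening")
    }
    cfg.ssi_floor = min_ssi
    if not shadows:
        cfg.shadow_model = dict(cfg.shadow_model, prob=0.0)
    return cfg
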