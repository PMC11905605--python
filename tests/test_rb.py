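"""Rules-based segmenter: vesselness, adaptive binarization, distance
transform, healthy-eye calibration and full-pipeline behavior."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

from npabench import RBParams
from npabench.metrics import evaluate_pair
from npabench.rb import (
    CalibrationError,
    adaptive_binarize,
    calibrate_distance_threshold,
    extrafoveal_region,
    params_with_threshold,
    segment_npa_rb,
    vessel_distance_map,
    vesselness_filter,
)
from npabench.types import Method, NPAMask, disk_mask


def ridge_image(width: int, shape=(96, 96), value=0.9) -> np.ndarray:
    img = np.zeros(shape)
    mid = shape[0] // 2
    img[mid - width // 2 : mid - width // 2 + width, :] = value
    return img


class TestVesselness:
    def test_constant_image_zero_response(self, default_rb_params):
        img = np.full((64, 64), 0.37)
        assert np.allclose(vesselness_filter(img, default_rb_params), 0.0)

    def test_line_response_exceeds_background(self, default_rb_params):
        img = ridge_image(3)
        v = vesselness_filter(img, default_rb_params)
        on_line = v[48, 20:76].min()
        background = v[10:30, 20:76].max()
        assert on_line > background

    def test_scale_selectivity_matches_hessian_oracle(self):
        # a low-contrast ridge of width w responds most near scale w/2;
        # checked against an independent finite-difference Hessian-eigenvalue
        # tubularity oracle (np.gradient path, not the filter's own kernels)
        img = ridge_image(4, shape=(128, 128), value=0.04)

        def oracle_response(image, sigma, beta=0.5, c=0.08):
            sm = ndimage.gaussian_filter(image, sigma)
            gr, gc = np.gradient(sm)
            hrr, hrc = np.gradient(gr)
            _, hcc = np.gradient(gc)
            hrr, hcc, hrc = hrr * sigma**2, hcc * sigma**2, hrc * sigma**2
            tmp = np.sqrt((hrr - hcc) ** 2 + 4 * hrc**2)
            mu1 = (hrr + hcc + tmp) / 2
            mu2 = (hrr + hcc - tmp) / 2
            swap = np.abs(mu1) > np.abs(mu2)
            l1 = np.where(swap, mu2, mu1)
            l2 = np.where(swap, mu1, mu2)
            with np.errstate(invalid="ignore", divide="ignore"):
                rb2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
            resp = np.exp(-rb2 / (2 * beta**2)) * (
                1 - np.exp(-(l1**2 + l2**2) / (2 * c**2))
            )
            return np.where(l2 < 0, resp, 0.0)

        center = (64, 64)
        scales = [1.0, 2.0, 3.0, 5.0, 8.0]
        oracle_by_scale = [oracle_response(img, s)[center] for s in scales]
        assert scales[int(np.argmax(oracle_by_scale))] == 2.0  # ~w/2
        per_scale = [
            vesselness_filter(
                img, replace(RBParams(), vesselness_scales_px=(s,))
            )[center]
            for s in scales
        ]
        assert scales[int(np.argmax(per_scale))] == 2.0
        # ridge response dominates background in both computations
        ridge_v = vesselness_filter(
            img, replace(RBParams(), vesselness_scales_px=(2.0,))
        )
        assert ridge_v[center] > ridge_v[20:40, 20:100].max()
        orc = oracle_response(img, 2.0)
        assert orc[center] > orc[20:40, 20:100].max()

    def test_transpose_invariance(self, default_rb_params):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.uniform(size=(80, 80)), 1.5)
        v = vesselness_filter(img, default_rb_params)
        vt = vesselness_filter(img.T, default_rb_params)
        assert np.allclose(v.T, vt, atol=1e-6)

    def test_degenerate_input_rejected(self, default_rb_params):
        with pytest.raises(ValueError):
            vesselness_filter(np.zeros((2, 2)), default_rb_params)
        with pytest.raises(ValueError):
            vesselness_filter(np.full((32, 32), np.nan), default_rb_params)


class TestAdaptiveBinarize:
    def test_zero_vesselness_empty_mask(self):
        params = replace(RBParams(), binarize_offset=0.0)
        v = np.zeros((64, 64))
        s = np.full((64, 64), 0.8)
        assert not adaptive_binarize(v, s, params).any()

    def test_clean_ridge_vesselness_recovered(self, default_rb_params):
        # a clean synthetic vesselness map of planted ridges with uniform
        # reflectance binarizes back to the ridge support (F1 >= 0.95)
        v = np.zeros((128, 128))
        truth = np.zeros((128, 128), bool)
        for r in range(10, 128, 16):
            v[r : r + 3, :] = 0.9
            truth[r : r + 3, :] = True
        s = np.full_like(v, 0.8)
        mask = adaptive_binarize(v, s, default_rb_params)
        ms = evaluate_pair(
            NPAMask(mask, 1.0, Method.RB), NPAMask(truth, 1.0, Method.TRUTH)
        )
        assert ms.f1 >= 0.95

    def test_compensation_improves_shadow_recall(self, default_rb_params):
        v = np.zeros((128, 128))
        truth = np.zeros((128, 128), bool)
        for r in range(10, 128, 16):
            v[r : r + 3, :] = 0.9
            truth[r : r + 3, :] = True
        shadow = disk_mask(v.shape, (64, 64), 25)
        v = v * np.where(shadow, 0.35, 1.0)
        structure = np.where(shadow, 0.3, 0.8)
        with_comp = adaptive_binarize(
            v, structure, replace(default_rb_params, reflectance_compensation_strength=0.8)
        )
        without = adaptive_binarize(
            v, structure, replace(default_rb_params, reflectance_compensation_strength=0.0)
        )
        recall_with = (with_comp & truth & shadow).sum() / (truth & shadow).sum()
        recall_without = (without & truth & shadow).sum() / (truth & shadow).sum()
        assert recall_with >= recall_without

    def test_window_larger_than_image_rejected(self, default_rb_params):
        with pytest.raises(ValueError):
            adaptive_binarize(np.zeros((16, 16)), np.zeros((16, 16)), default_rb_params)


class TestDistanceMap:
    def test_all_true_gives_zero(self):
        assert np.all(vessel_distance_map(np.ones((10, 10), bool)) == 0)

    def test_three_four_five(self):
        mask = np.zeros((32, 32), bool)
        mask[10, 10] = True
        assert vessel_distance_map(mask)[13, 14] == 5.0

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            mask = rng.uniform(size=(32, 32)) < 0.1
            if not mask.any():
                mask[0, 0] = True
            d = vessel_distance_map(mask)
            rr, cc = np.nonzero(mask)
            gr, gc = np.mgrid[:32, :32]
            brute = np.sqrt(
                ((gr[..., None] - rr) ** 2 + (gc[..., None] - cc) ** 2).min(axis=-1)
            )
            assert np.array_equal(d, brute)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            vessel_distance_map(np.zeros((8, 8), bool))


class TestCalibration:
    def test_self_consistency_on_single_scan(self, healthy_noiseless_cohort, default_rb_params):
        records, table = healthy_noiseless_cohort
        idx = table[table["slab"] == "SVC"]["scan_index"].iloc[0]
        scan, truth = records[idx]
        thr = calibrate_distance_threshold([scan], [truth.npa_mask], default_rb_params)
        params = params_with_threshold(default_rb_params, thr)
        npa = segment_npa_rb(scan, params)
        extraf = extrafoveal_region(
            truth.npa_mask, default_rb_params.fovea_dilation_px
        )
        assert not np.any(npa.mask & extraf)

    def test_threshold_monotonicity(self, healthy_noiseless_cohort, default_rb_params):
        records, table = healthy_noiseless_cohort
        idx = table[table["slab"] == "SVC"]["scan_index"].iloc[0]
        scan, truth = records[idx]
        extraf = extrafoveal_region(truth.npa_mask, 10)
        prev = None
        for thr in (2.0, 4.0, 8.0, 16.0):
            npa = segment_npa_rb(scan, params_with_threshold(default_rb_params, thr))
            area = int((npa.mask & extraf).sum())
            if prev is not None:
                assert area <= prev
            prev = area

    def test_unreachable_criterion_reports_residual(self, healthy_noiseless_cohort):
        records, table = healthy_noiseless_cohort
        idx = table[table["slab"] == "SVC"]["scan_index"].iloc[0]
        scan, truth = records[idx]
        # a grid topping out below the healthy intercapillary distances, with
        # the cleanup stages disabled, cannot silence the extrafoveal response
        bad = replace(
            RBParams(),
            calibration_grid_px=(0.1, 0.5, 0.1),
            min_region_area_mm2=0.0,
            morphology_radius_px=0,
        )
        with pytest.raises(CalibrationError) as err:
            calibrate_distance_threshold([scan], [truth.npa_mask], bad)
        assert err.value.max_residual_mm2 > 0

    def test_non_healthy_scan_rejected(self, dr_noiseless_cohort, default_rb_params):
        records, table = dr_noiseless_cohort
        idx = table["scan_index"].iloc[0]
        scan, truth = records[idx]
        with pytest.raises(ValueError, match="ETDRS"):
            calibrate_distance_threshold([scan], [truth.npa_mask], default_rb_params)


class TestFullSegmentation:
    def test_lesion_detected_with_overlap(self, healthy_noiseless_cohort, dr_noiseless_cohort, default_rb_params):
        hrec, htab = healthy_noiseless_cohort
        sel = htab[htab["slab"] == "SVC"]
        thr = calibrate_distance_threshold(
            [hrec[i][0] for i in sel["scan_index"]],
            [hrec[i][1].npa_mask for i in sel["scan_index"]],
            default_rb_params,
        )
        params = params_with_threshold(default_rb_params, thr)
        drec, dtab = dr_noiseless_cohort
        ious = []
        for i in dtab[dtab["slab"] == "SVC"]["scan_index"]:
            scan, truth = drec[i]
            pred = segment_npa_rb(scan, params)
            ref = NPAMask(truth.npa_mask, scan.pixel_pitch_mm, Method.TRUTH)
            ious.append(evaluate_pair(pred, ref).iou)
        assert np.median(ious) >= 0.5

    def test_min_region_filter_postcondition(self, dr_noiseless_cohort, default_rb_params):
        records, table = dr_noiseless_cohort
        idx = table[table["slab"] == "SVC"]["scan_index"].iloc[0]
        scan, _ = records[idx]
        params = replace(
            params_with_threshold(default_rb_params, 4.0), min_region_area_mm2=0.1
        )
        npa = segment_npa_rb(scan, params)
        labels, n = ndimage.label(npa.mask, structure=np.ones((3, 3), int))
        min_px = 0.1 / scan.pixel_pitch_mm**2
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            assert sizes.min() >= min_px

    def test_shadow_inflates_npa_and_compensation_reduces_it(self, default_rb_params):
        # a shadow disk over perfused retina creates false NPA when signal
        # compensation is off; tuned compensation shrinks the inflation
        from npabench.synthetic import rasterize_scan, render_vessel_network
        from npabench.types import Slab

        vessels = render_vessel_network(Slab.SVC, 28.0, seed=3)
        npa = disk_mask(vessels.shape, (151.5, 151.5), 28.0)
        clean_vessels = vessels & ~npa
        shadow = [{"center": (90.0, 210.0), "radius_px": 25.0, "attenuation": 0.3}]
        params = params_with_threshold(default_rb_params, 4.5)
        inflation = {}
        for strength in (0.0, 0.8):
            p = replace(params, reflectance_compensation_strength=strength)
            areas = {}
            for label, spec in (("clean", None), ("shadowed", shadow)):
                scan, _ = rasterize_scan(clean_vessels, npa, spec, 75.0, 9)
                areas[label] = segment_npa_rb(scan, p).area_mm2
            inflation[strength] = areas["shadowed"] - areas["clean"]
        assert inflation[0.0] > 0.05
        assert inflation[0.8] < inflation[0.0]

    def test_weak_compensation_gives_negative_ssi_bias(self, default_rb_params):
        # healthy eyes spanning SSI 55-95 with quality-linked shadows: with
        # weak compensation, detected NPA correlates negatively with SSI
        # (worse scans read as more nonperfusion)
        from npabench.synthetic import generate_cohort, healthy_cohort_config

        hcfg = healthy_cohort_config(8, seed=2, id_prefix="HC")
        hrec, htab = generate_cohort(hcfg)
        sel = htab[htab["slab"] == "SVC"]
        thr = calibrate_distance_threshold(
            [hrec[i][0] for i in sel["scan_index"]],
            [hrec[i][1].npa_mask for i in sel["scan_index"]],
            default_rb_params,
        )
        weak = replace(
            params_with_threshold(default_rb_params, thr),
            reflectance_compensation_strength=0.0,
        )
        cfg = healthy_cohort_config(50, seed=77, shadows=True)
        cfg.ssi_model = {g: {"mean": 72.0, "sd": 10.0} for g in cfg.ssi_model}
        cfg.ssi_floor = 55.0
        cfg.shadow_model = dict(cfg.shadow_model, prob=0.5, ssi_link=0.06)
        records, table = generate_cohort(cfg)
        areas, ssis = [], []
        for i in table[table["slab"] == "SVC"]["scan_index"]:
            scan, _ = records[i]
            areas.append(segment_npa_rb(scan, weak).area_mm2)
            ssis.append(scan.ssi)
        assert np.corrcoef(ssis, areas)[0, 1] <= 0.0

    def test_lesion_growth_never_shrinks_detection(self, default_rb_params):
        # noiseless monotonicity: enlarging the planted lesion (superset)
        # cannot decrease detected NPA area
        from npabench.synthetic import rasterize_scan, render_vessel_network
        from npabench.types import Slab

        vessels = render_vessel_network(Slab.SVC, 28.0, seed=6)
        params = params_with_threshold(default_rb_params, 4.5)
        prev_area = -1.0
        for radius in (30.0, 40.0, 50.0):
            lesion = disk_mask(vessels.shape, (90.0, 200.0), radius)
            npa = disk_mask(vessels.shape, (151.5, 151.5), 28.0) | lesion
            scan, _ = rasterize_scan(
                vessels & ~npa, npa, None, 100.0, 1, noise_model={"a": 0.0, "b": 0.0}
            )
            area = segment_npa_rb(scan, params).area_mm2
            assert area >= prev_area
            prev_area = area
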