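"""Anchor selection, knot binning and cubic-spline RT mapping."""

import numpy as np
import pandas as pd
import pytest

from omegamap.calibrate import (
    AnchorPoint,
    NoAnchorsError,
    bin_anchors,
    evaluate_mapping,
    fit_rt_mapping,
    map_rt,
    select_anchors,
)
from omegamap.lipids import FattyAcyl, LipidMolecularSpecies
from omegamap.rtdb import RTDB, RTDBEntry


def _db(keys_rts, evidence="SIL-experiment"):
    entries = []
    for i, (key, rt) in enumerate(keys_rts):
        cls, chains = key.split(" ", 1)
        from omegamap.lipids import parse_chain

        fa = tuple(parse_chain(t) for t in chains.split("_"))
        entries.append(RTDBEntry(LipidMolecularSpecies(cls, fa), rt,
                                 frozenset({"b"}), evidence))
    return RTDB(entries=entries, meta={"gradient_span_min": 35.0})


def _anchors(points, group="global"):
    return [AnchorPoint(f"sp{i}", s, t, group=group) for i, (s, t) in enumerate(points)]


class TestSelectAnchors:
    def test_strategy3_takes_all_shared(self):
        db = _db([("PC 16:0_18:1(n−9)", 10.0), ("PC 16:0_18:1(n−7)", 11.0),
                  ("PI 18:0_20:3(n−9)", 12.0)], evidence="standard")
        target = pd.DataFrame({
            "species_key": ["PC 16:0_18:1(n−9)", "PC 16:0_18:1(n−7)", "PI 18:0_20:3(n−9)"],
            "rt_min": [20.0, 22.0, 24.0],
            "reliability": ["standard"] * 3,
        })
        anchors = select_anchors(db, target, strategy=3)
        assert len(anchors) == 3

    def test_disjoint_species_raise_no_anchors(self):
        db = _db([("PC 16:0_18:1(n−9)", 10.0)])
        target = pd.DataFrame({"species_key": ["PI 18:0_20:3(n−9)"], "rt_min": [12.0]})
        with pytest.raises(NoAnchorsError):
            select_anchors(db, target, strategy=3)

    def test_strategy2_reliability_filters(self):
        """50 biological + 3 standard species; 10 with excessive replicate
        spread are excluded, leaving 43 anchors."""
        keys = [f"PC 16:0_{17 + i // 5}:{1 + i % 5}(n−9)" for i in range(50)]
        assert len(set(keys)) == 50
        db_rows = [(k, 5.0 + 0.5 * i) for i, k in enumerate(keys)]
        std_keys = [f"PI 18:0_20:{d}(n−9)" for d in (1, 2, 3)]
        db_rows += [(k, 31.0 + i) for i, k in enumerate(std_keys)]
        db = _db(db_rows)
        rows = []
        for i, k in enumerate(keys):
            sd = 0.2 if i < 10 else 0.01  # first 10: spread beyond threshold
            for r in range(3):
                rows.append({"species_key": k,
                             "rt_min": 5.0 + 0.5 * i + sd * (r - 1),
                             "reliability": "biological"})
        for i, k in enumerate(std_keys):
            rows.append({"species_key": k, "rt_min": 31.0 + i, "reliability": "standard"})
        anchors = select_anchors(db, pd.DataFrame(rows), strategy=2,
                                 replicate_sd_max_min=0.05)
        assert len(anchors) == 43

    def test_strategy1_screens_outliers_against_standards(self):
        db_rows = [(f"PC 16:0_{c}:1(n−9)", float(c)) for c in range(17, 27)]
        db_rows += [("PI 18:0_20:3(n−9)", 15.0), ("PI 18:0_20:4(n−6)", 30.0)]
        db = _db(db_rows)
        rows = [{"species_key": k, "rt_min": rt * 2.0, "reliability": "biological"}
                for k, rt in db_rows[:10]]
        rows[0]["rt_min"] += 5.0  # gross outlier vs the standards' trend
        rows += [{"species_key": "PI 18:0_20:3(n−9)", "rt_min": 30.0, "reliability": "standard"},
                 {"species_key": "PI 18:0_20:4(n−6)", "rt_min": 60.0, "reliability": "standard"}]
        anchors = select_anchors(db, pd.DataFrame(rows), strategy=1,
                                 standards_available=True)
        assert len(anchors) == 11  # 9 biological survive + 2 standards
        assert all(a.species_key != db_rows[0][0] for a in anchors)


class TestBinAnchors:
    def test_distinct_bins_pass_through(self):
        ks, kt = bin_anchors(_anchors([(1.0, 2.0), (2.0, 4.0), (3.0, 6.0), (4.0, 8.0)]),
                             bin_width_min=0.5)
        assert list(ks) == [1.0, 2.0, 3.0, 4.0]
        assert list(kt) == [2.0, 4.0, 6.0, 8.0]

    def test_bin_median(self):
        ks, kt = bin_anchors(_anchors([(1.0, 10.0), (1.1, 10.1), (1.2, 10.4)]),
                             bin_width_min=0.5)
        assert len(ks) == 1
        assert kt[0] == pytest.approx(10.1)

    def test_near_duplicate_knots_remerged(self):
        # effectively duplicate source RTs straddling a bin boundary
        # collapse into one occupancy-weighted knot
        eps = 1e-12
        anchors = _anchors([(1.0 - eps, 1.0), (1.0, 1.2), (1.0, 1.4), (3.0, 3.0)])
        ks, kt = bin_anchors(anchors, bin_width_min=1.0, min_knot_spacing_min=1e-9)
        assert np.all(np.diff(ks) > 0)
        assert len(ks) == 2
        # oracle: brute-force weighted merge of the colliding knots
        assert ks[0] == pytest.approx(((1.0 - eps) + 2 * 1.0) / 3)
        assert kt[0] == pytest.approx((1.0 + 2 * 1.3) / 3)


class TestFitAndMap:
    def test_identity_knots_map_identically(self):
        model = fit_rt_mapping(_anchors([(i, i) for i in range(1, 7)]), 0.5)
        assert model.map("global", 2.5).value == pytest.approx(2.5, abs=1e-9)

    def test_collinear_knots_reproduce_affine_map(self):
        model = fit_rt_mapping(_anchors([(i, 2 * i) for i in range(1, 7)]), 0.5)
        for x in np.linspace(1.0, 6.0, 23):
            assert model.map("global", x).value == pytest.approx(2 * x, abs=1e-9)

    def test_quadratic_warp_interpolation_error(self):
        pts = [(t, t + 0.1 * t * t) for t in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)]
        model = fit_rt_mapping(_anchors(pts), bin_width_min=0.25)
        assert model.map("global", 5.0).value == pytest.approx(7.5, abs=0.05)

    def test_interpolation_exact_at_knots(self):
        pts = [(t, t + 0.1 * t * t) for t in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)]
        model = fit_rt_mapping(_anchors(pts), bin_width_min=0.25)
        for s, t in pts:
            assert model.map("global", s).value == pytest.approx(t, abs=1e-9)

    def test_extrapolation_linear_and_flagged(self):
        model = fit_rt_mapping(_anchors([(i, 2 * i) for i in range(1, 7)]), 0.5)
        res = model.map("global", 8.0)
        assert "extrapolated" in res.flags
        # boundary value + boundary slope x overshoot
        assert res.value == pytest.approx(12.0 + 2.0 * 2.0, abs=1e-9)

    def test_fallback_chain_to_global(self):
        model = fit_rt_mapping(_anchors([(i, 2 * i) for i in range(1, 7)], group="PC"), 0.5)
        res = model.map("PI", 3.0)
        assert "fallback" in res.flags
        assert res.value == pytest.approx(6.0, abs=1e-9)

    def test_sparse_groups_need_global(self):
        with pytest.raises(ValueError):
            fit_rt_mapping([], 0.5)

    def test_monotone_warp_gives_monotone_mapping(self):
        pts = [(t, t + 0.1 * t * t) for t in np.arange(0.0, 10.5, 1.0)]
        model = fit_rt_mapping(_anchors(pts), bin_width_min=0.5)
        xs = np.linspace(0.0, 10.0, 401)
        ys = [model.map("global", float(x)).value for x in xs]
        assert np.all(np.diff(ys) > 0)


class TestEvaluate:
    def test_holdout_equal_to_knots_gives_zero(self):
        anchors = _anchors([(i, 2 * i) for i in range(1, 7)])
        model = fit_rt_mapping(anchors, 0.5)
        report = evaluate_mapping(model, anchors)
        assert report["median_abs_dev_s"] == pytest.approx(0.0, abs=1e-9)

    def test_smooth_warp_no_noise_submedian_second(self):
        rng = np.random.default_rng(3)
        warp = lambda t: t + 2.0 / (1.0 + np.exp(-(t - 15.0) / 4.0))
        src = np.sort(rng.uniform(2.0, 30.0, 30))
        anchors = _anchors([(float(s), float(warp(s))) for s in src])
        hold_src = np.sort(rng.uniform(3.0, 29.0, 30))
        holdout = _anchors([(float(s), float(warp(s))) for s in hold_src])
        model = fit_rt_mapping(anchors, 0.5)
        report = evaluate_mapping(model, holdout)
        assert report["median_abs_dev_s"] < 1.0

    def test_noisy_anchors_median_in_band(self):
        """2 s Gaussian anchor noise: held-out median deviation lands in
        the 1-4 s band expected from the noise model (pooled, 100 seeds)."""
        warp = lambda t: t + 2.0 / (1.0 + np.exp(-(t - 15.0) / 4.0))
        devs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            src = np.sort(rng.uniform(2.0, 30.0, 30))
            noise = rng.normal(0.0, 2.0 / 60.0, 30)
            anchors = _anchors([(float(s), float(warp(s) + e)) for s, e in zip(src, noise)])
            hold_src = np.sort(rng.uniform(3.0, 29.0, 30))
            model = fit_rt_mapping(anchors, 0.5)
            devs.extend(abs(model.map("global", float(s)).value - float(warp(s))) * 60.0
                        for s in hold_src)
        assert 1.0 <= float(np.median(devs)) <= 4.0

    def test_empty_holdout_rejected(self):
        model = fit_rt_mapping(_anchors([(i, i) for i in range(1, 7)]), 0.5)
        with pytest.raises(ValueError):
            evaluate_mapping(model, [])
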