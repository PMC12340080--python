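"""Isotope-effect correction, omega grouping, RT-DB building and merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from omegamap.lipids import FattyAcyl, LipidMolecularSpecies, parse_species
from omegamap.masslist import SchemaError
from omegamap.rtdb import (
    RTDB,
    InvalidRetentionError,
    IsotopeEffectModel,
    RTDBEntry,
    build_rtdb,
    correct_labeled_rt,
    estimate_isotope_effect,
    group_omega_combinations,
    merge_rtdbs,
    rtdb_io,
)


class TestIsotopeEffectModel:
    def test_identical_rts_force_no_effect(self):
        m = estimate_isotope_effect([(20.0, 20.0, 17)], f_a=1.0, t0=1.0)
        assert m.k_ratio == pytest.approx(1.0, abs=1e-12)
        assert m.atie == pytest.approx(1.0, abs=1e-12)

    def test_atie_equals_ratio_when_fa_is_one(self):
        m = IsotopeEffectModel(k_ratio=1.03, f_a=1.0)
        assert m.atie == pytest.approx(1.03, abs=1e-12)

    def test_atie_with_gradient_adjustment(self):
        m = IsotopeEffectModel(k_ratio=1.03, f_a=1.5)
        assert m.atie == pytest.approx(1.02, abs=1e-12)

    @given(st.floats(0.5, 2.0), st.floats(0.1, 5.0))
    def test_atie_algebra(self, k_ratio, f_a):
        m = IsotopeEffectModel(k_ratio=k_ratio, f_a=f_a)
        if k_ratio == 1.0:
            assert m.atie == pytest.approx(1.0, abs=1e-12)
        assert m.atie == pytest.approx((k_ratio - 1) / f_a + 1, abs=1e-12)

    def test_rt_below_dead_time_rejected(self):
        with pytest.raises(InvalidRetentionError):
            estimate_isotope_effect([(0.4, 20.0, 5)], t0=0.5)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            estimate_isotope_effect([])

    def test_per_deuterium_scaling(self):
        # k_H/k_D = 1.0201 for an n_D=2 standard -> per-deuterium ratio 1.01
        t0 = 1.0
        k_d = 19.0 / (1.01**2)
        m = estimate_isotope_effect([(20.0, t0 + k_d * t0, 2)], t0=t0)
        assert m.per_deuterium_ratio == pytest.approx(1.01, rel=1e-9)
        assert m.k_ratio == pytest.approx(1.01**2, rel=1e-9)


class TestCorrectLabeledRT:
    MODEL = IsotopeEffectModel(k_ratio=1.001**17, t0=1.0,
                               per_deuterium_ratio=1.001, n_d_reference=17)

    def test_unlabeled_species_unchanged(self):
        sp = parse_species("PC 16:0_18:1(n−9)")
        assert correct_labeled_rt(sp, 20.0, self.MODEL) == 20.0

    def test_carbon13_label_unchanged(self):
        sp = parse_species("PC D16:1_16:0")  # D = 13C16 label
        assert correct_labeled_rt(sp, 20.0, self.MODEL) == 20.0

    def test_d5_shift_matches_direct_formula(self):
        sp = parse_species("PC C18:3_16:0")  # C = D5 label
        expected = 20.0 + (20.0 - 1.0) * (1.001**5 - 1.0)
        got = correct_labeled_rt(sp, 20.0, self.MODEL)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(20.0952, abs=1e-4)

    def test_two_sil_chains_shift_additively(self):
        sp = parse_species("PC B20:4_C22:5")
        d5 = (20.0 - 1.0) * (1.001**5 - 1.0)
        d11 = (20.0 - 1.0) * (1.001**11 - 1.0)
        assert correct_labeled_rt(sp, 20.0, self.MODEL) == pytest.approx(
            20.0 + d5 + d11, abs=1e-12
        )

    @given(st.floats(2.0, 30.0), st.floats(1.0001, 1.01))
    def test_noiseless_roundtrip(self, rt_native, r):
        """Simulating a labeled RT then correcting recovers the native RT."""
        t0 = 0.5
        model = IsotopeEffectModel(k_ratio=r**17, t0=t0,
                                   per_deuterium_ratio=r, n_d_reference=17)
        sp = parse_species("PC A18:1_16:0")  # D17 label
        rt_obs = t0 + (rt_native - t0) / (r**17)
        assert correct_labeled_rt(sp, rt_obs, model) == pytest.approx(
            rt_native, abs=1e-6
        )


def _entry(text, rt, batch="b1", evidence="SIL-experiment"):
    sp = parse_species(text)
    return RTDBEntry(sp, rt, frozenset({batch}), evidence)


class TestGrouping:
    def test_single_label_runs_aggregate_to_mixed_omega_entry(self):
        entries = [
            _entry("PC 20:4(n−6)_22:5", 20.00, "runB"),
            _entry("PC 20:4_22:5(n−3)", 20.04, "runC"),
            _entry("PC 20:4(n−6)_22:5(n−3)", 20.07, "runBC"),
        ]
        out = group_omega_combinations(entries, grouping_tolerance_s=5.0)
        assert len(out) == 1
        assert out[0].key_omega == "PC 20:4(n−6)_22:5(n−3)"
        assert out[0].source_batches == {"runB", "runC", "runBC"}
        assert out[0].reference_rt == pytest.approx(20.04)

    def test_entries_beyond_tolerance_stay_separate(self):
        entries = [
            _entry("PC 20:4(n−6)_22:5", 20.0),
            _entry("PC 20:4_22:5(n−3)", 20.2),  # 12 s apart
        ]
        out = group_omega_combinations(entries, grouping_tolerance_s=5.0)
        assert len(out) == 2

    def test_idempotent_and_order_invariant(self):
        entries = [
            _entry("PC 20:4(n−6)_22:5", 20.00, "b1"),
            _entry("PC 20:4_22:5(n−3)", 20.03, "b2"),
            _entry("PC 20:4(n−6)_22:5(n−3)", 20.30, "b3"),
        ]
        once = group_omega_combinations(entries, 5.0)
        twice = group_omega_combinations(once, 5.0)
        assert [(e.key_omega, e.reference_rt) for e in once] == [
            (e.key_omega, e.reference_rt) for e in twice
        ]
        rev = group_omega_combinations(entries[::-1], 5.0)
        assert [(e.key_omega, e.reference_rt, e.source_batches) for e in rev] == [
            (e.key_omega, e.reference_rt, e.source_batches) for e in once
        ]

    def test_conflicting_omega_flagged_not_averaged(self):
        entries = [
            _entry("PC 16:0_20:4(n−6)", 20.00),
            _entry("PC 16:0_20:4(n−7)", 20.02),
        ]
        out = group_omega_combinations(entries, 5.0)
        assert len(out) == 1
        assert "conflict" in out[0].flags

    def test_mixed_species_rejected(self):
        with pytest.raises(ValueError):
            group_omega_combinations(
                [_entry("PC 16:0_20:4(n−6)", 20.0), _entry("PC 16:0_18:1(n−9)", 21.0)]
            )


class TestBuildRTDB:
    MODEL = IsotopeEffectModel(k_ratio=1.001**17, t0=0.5,
                               per_deuterium_ratio=1.001, n_d_reference=17)

    def test_single_labeled_identification(self):
        ids = pd.DataFrame([
            {"batch_id": "b1", "lipid_class": "PC", "chains": "A18:1_16:0", "rt_min": 20.0},
        ])
        db, report = build_rtdb(ids, self.MODEL)
        assert len(db) == 1 and len(report) == 0
        e = db.entries[0]
        assert e.key_omega == "PC 16:0_18:1(n−9)"  # label stripped, omega kept
        assert e.reference_rt > 20.0  # deuterated species eluted early; corrected up

    def test_two_label_runs_aggregate(self):
        rt_b = correct_inverse(20.0, 11, self.MODEL)
        rt_c = correct_inverse(20.0, 5, self.MODEL)
        ids = pd.DataFrame([
            {"batch_id": "runB", "lipid_class": "PC", "chains": "B20:4_22:5", "rt_min": rt_b},
            {"batch_id": "runC", "lipid_class": "PC", "chains": "20:4_C22:5", "rt_min": rt_c},
        ])
        db, _ = build_rtdb(ids, self.MODEL)
        assert len(db) == 1
        assert db.entries[0].key_omega == "PC 20:4(n−6)_22:5(n−3)"
        assert db.entries[0].source_batches == {"runB", "runC"}

    def test_unparseable_rows_reported(self):
        ids = pd.DataFrame([
            {"batch_id": "b1", "lipid_class": "PC", "chains": "A18:1_16:0", "rt_min": 20.0},
            {"batch_id": "b1", "lipid_class": "PC", "chains": "Q9:9_??", "rt_min": 21.0},
        ])
        db, report = build_rtdb(ids, self.MODEL)
        assert len(db) == 1
        assert len(report) == 1


def correct_inverse(rt_native, n_d, model):
    """Observed RT of a deuterated species that corrects back to rt_native."""
    return model.t0 + (rt_native - model.t0) / (model.per_deuterium_ratio ** n_d)


class TestMerge:
    def _db(self, specs):
        return RTDB(entries=[_entry(t, rt, b) for t, rt, b in specs],
                    meta={"gradient_span_min": 35.0})

    def test_self_merge_is_identity(self):
        db = self._db([("PC 16:0_18:1(n−9)", 10.0, "b1"),
                       ("PI 18:0_20:3(n−9)", 12.0, "b1")])
        agg = merge_rtdbs([db, db], ["identity", "identity"])
        assert len(agg) == len(db)
        assert sorted(e.key_omega for e in agg) == sorted(e.key_omega for e in db)

    def test_disjoint_species_sum(self):
        a = self._db([("PC 16:0_18:1(n−9)", 10.0, "b1")])
        b = self._db([("PI 18:0_20:3(n−9)", 12.0, "b2")])
        agg = merge_rtdbs([a, b], ["identity", "identity"])
        assert len(agg) == 2

    def test_shared_species_merges_batches(self):
        a = self._db([("PC 16:0_18:1(n−9)", 10.00, "b1")])
        b = self._db([("PC 16:0_18:1(n−9)", 10.03, "b2")])
        agg = merge_rtdbs([a, b], ["identity", "identity"])
        assert len(agg) == 1
        assert agg.entries[0].source_batches == {"b1", "b2"}

    def test_missing_calibration_rejected(self):
        a = self._db([("PC 16:0_18:1(n−9)", 10.0, "b1")])
        with pytest.raises(ValueError):
            merge_rtdbs([a, a], ["identity", None])

    def test_curation_excludes_flagged_outliers(self):
        a = self._db([("PC 16:0_18:1(n−9)", 10.0, "b1"),
                      ("PI 18:0_20:3(n−9)", 12.0, "b1")])
        agg = merge_rtdbs([a], ["identity"], curation_flags={"PI 18:0_20:3(n−9)"})
        assert len(agg) == 1

    def test_merge_never_invents_species(self):
        a = self._db([("PC 16:0_18:1(n−9)", 10.0, "b1"),
                      ("PC 16:0_18:1(n−7)", 11.0, "b1")])
        b = self._db([("PC 16:0_18:1(n−9)", 10.02, "b2")])
        agg = merge_rtdbs([a, b], ["identity", "identity"])
        inputs = {e.key_omega for e in a} | {e.key_omega for e in b}
        assert {e.key_omega for e in agg} <= inputs
        assert len(agg) <= len(a) + len(b)


class TestIO:
    @pytest.mark.parametrize("suffix", [".tsv", ".xlsx"])
    def test_roundtrip(self, tmp_path, suffix):
        db = RTDB(
            entries=[
                _entry("PC 16:0_18:1(n−9)", 10.0),
                RTDBEntry(parse_species("PI 18:0/20:3(n−9)"), 12.0,
                          frozenset({"b1", "b2"}), "standard", frozenset({"extrapolated"})),
            ],
            meta={"gradient_span_min": 35.0, "t0_min": 0.5, "method": "30min"},
        )
        p = tmp_path / f"db{suffix}"
        rtdb_io(db, p)
        back = rtdb_io(p, direction="read")
        assert len(back) == len(db)
        assert back.meta["gradient_span_min"] == 35.0
        assert sorted(e.key_omega for e in back) == sorted(e.key_omega for e in db)
        by_key = {e.key_omega: e for e in back}
        e = by_key["PI 18:0/20:3(n−9)"]
        assert e.species.sn_resolved
        assert e.source_batches == {"b1", "b2"}
        assert e.flags == {"extrapolated"}

    def test_empty_db_roundtrips(self, tmp_path):
        p = tmp_path / "empty.tsv"
        rtdb_io(RTDB(meta={"t0_min": 0.5}), p)
        assert len(rtdb_io(p, direction="read")) == 0

    def test_missing_column_is_named(self, tmp_path):
        db = RTDB(entries=[_entry("PC 16:0_18:1(n−9)", 10.0)])
        df = db.to_frame().drop(columns=["reference_rt_min"])
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(SchemaError, match="reference_rt_min"):
            rtdb_io(p, direction="read")
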