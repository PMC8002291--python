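"""Per-plate mean + k·SD hit calling, dual-read rule, viability flags."""

import numpy as np
import pytest

from reporterscreen import (
    HitCallingModel,
    HitThreshold,
    InsufficientControlsError,
    WellRole,
    activation_threshold,
    call_compound,
    call_screen,
    flag_viability,
    summarize_controls,
)
from reporterscreen.simulate import ScreenSimConfig, simulate_screen

from conftest import make_dataset, make_layout

# make_layout places controls column-major: M0 at A1,B1,C1; M1 solvent at
# D1,E1,F1; TSA at G1,H1; compounds from I1 on.


def _threshold(m, sd, k=3.0, read=1):
    return HitThreshold("P1", read, k, m, sd)


class TestControlSummary:
    def test_mean_and_sample_sd(self, tiny_layout):
        ds = make_dataset(tiny_layout, {1: {"D1": 90, "E1": 100, "F1": 110}})
        summ = summarize_controls(ds.reads[("P1", 1)], tiny_layout, WellRole.M1_SOLVENT)
        assert (summ.m, summ.sd, summ.n) == (100.0, 10.0, 3)

    def test_constant_controls_have_zero_sd(self, tiny_layout):
        ds = make_dataset(tiny_layout, {1: {"D1": 7.0, "E1": 7.0, "F1": 7.0}})
        summ = summarize_controls(ds.reads[("P1", 1)], tiny_layout, WellRole.M1_SOLVENT)
        assert (summ.m, summ.sd) == (7.0, 0.0)

    def test_fewer_than_two_usable_wells_fails(self, tiny_layout):
        ds = make_dataset(tiny_layout, {1: {"D1": 7.0, "E1": float("nan")}})
        with pytest.raises(InsufficientControlsError):
            summarize_controls(ds.reads[("P1", 1)], tiny_layout, WellRole.M1_SOLVENT)


class TestThreshold:
    def test_band_arithmetic(self, tiny_layout):
        ds = make_dataset(tiny_layout, {1: {"D1": 90, "E1": 100, "F1": 110}})
        summ = summarize_controls(ds.reads[("P1", 1)], tiny_layout, WellRole.M1_SOLVENT)
        thr = activation_threshold(summ, k=3)
        assert (thr.upper, thr.lower) == (130.0, 70.0)

    @pytest.mark.parametrize("k,sd,expected", [(0.0, 10.0, 100.0), (3.0, 0.0, 100.0)])
    def test_degenerate_bands_collapse_to_mean(self, k, sd, expected):
        thr = _threshold(100.0, sd, k)
        assert thr.upper == thr.lower == expected

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            _threshold(100.0, 10.0, -1.0)


class TestCallCompound:
    UPPERS = {1: _threshold(100, 10, read=1), 2: _threshold(100, 10, read=2)}

    def test_hit_requires_exceedance_in_both_reads(self):
        call = call_compound("C", {1: 135, 2: 131}, self.UPPERS)
        assert call.status == "hit"
        call = call_compound("C", {1: 135, 2: 129}, self.UPPERS)
        assert call.status == "no_hit"
        assert call.exceeds == {1: True, 2: False}

    def test_signal_exactly_on_threshold_is_not_a_hit(self):
        call = call_compound("C", {1: 130.0, 2: 135.0}, self.UPPERS)
        assert call.exceeds[1] is False and call.status == "no_hit"

    def test_missing_read_gives_incomplete(self):
        call = call_compound("C", {1: 135}, self.UPPERS, expected_reads=2)
        assert call.status == "incomplete"

    def test_inhibitor_uses_lower_band(self):
        call = call_compound("C", {1: 60, 2: 65}, self.UPPERS, direction="inhibitor")
        assert call.status == "hit"


class TestCallScreen:
    def test_noiseless_recovery_of_planted_activators(self):
        cfg = ScreenSimConfig(
            compounds_per_plate=(50,),
            libraries=("LOPAC",),
            read_cv=(0.0, 0.0),
            planted_hits=((5, 5.0), (20, 5.0), (44, 5.0)),
            seed=0,
        )
        ds, truth = simulate_screen(cfg)
        calls, _ = call_screen(ds, k=3)
        hits = {c.compound_id for c in calls if c.status == "hit"}
        assert hits == {c for c, e in truth.effects.items() if e > 1}

    def test_dual_read_hit_set_is_intersection_of_single_read_sets(self):
        cfg = ScreenSimConfig(
            compounds_per_plate=(100,),
            libraries=("L",),
            planted_hits=((1, 3.0), (2, 4.0), (3, 10.0)),
            seed=11,
        )
        ds, _ = simulate_screen(cfg)
        both = {c.compound_id for c in call_screen(ds, k=3)[0] if c.status == "hit"}
        per_read = []
        for idx in (1, 2):
            sub = type(ds)(
                ds.layouts,
                {k: v for k, v in ds.reads.items() if k[1] == idx},
                ds.library_registry,
            )
            per_read.append(
                {c.compound_id for c in call_screen(sub, k=3)[0] if c.status == "hit"}
            )
        assert both == per_read[0] & per_read[1]

    def test_hit_set_shrinks_as_k_grows(self):
        cfg = ScreenSimConfig(
            compounds_per_plate=(200,),
            libraries=("L",),
            planted_hits=tuple(
                (i, m) for i, m in zip(range(0, 60, 3), np.linspace(1.5, 8, 20))
            ),
            seed=7,
        )
        ds, _ = simulate_screen(cfg)
        previous = None
        for k in (1.0, 2.0, 3.0, 4.0):
            hits = {c.compound_id for c in call_screen(ds, k=k)[0] if c.status == "hit"}
            if previous is not None:
                assert hits <= previous
            previous = hits

    def test_thresholds_are_plate_local(self):
        cfg = ScreenSimConfig(
            compounds_per_plate=(30, 30),
            libraries=("L", "L2"),
            planted_hits=((2, 6.0), (40, 6.0)),
            seed=3,
        )
        ds, _ = simulate_screen(cfg)
        baseline = {
            c.compound_id: c.status for c in call_screen(ds, k=3)[0] if c.plate_id == "P2"
        }
        # corrupt every signal on plate P1
        for (plate, _), read in ds.reads.items():
            if plate == "P1":
                for w in read.signal:
                    read.signal[w] *= 50.0
        after = {
            c.compound_id: c.status for c in call_screen(ds, k=3)[0] if c.plate_id == "P2"
        }
        assert baseline == after

    def test_inhibitor_direction_warns(self, tiny_layout):
        sig = {"D1": 100, "E1": 101, "F1": 99, "I1": 50, "J1": 50, "K1": 50}
        ds = make_dataset(tiny_layout, {1: sig, 2: sig})
        with pytest.warns(UserWarning, match="inhibitor"):
            call_screen(ds, k=3, direction="inhibitor")


class TestViabilityFlag:
    def _screen(self, signal2, viability, control_sig=100.0):
        layout = make_layout(compounds=("CPD",))
        sigs = {
            "A1": 10, "B1": 10, "C1": 10,  # M0
            "D1": control_sig, "E1": control_sig + 1, "F1": control_sig - 1,  # M1 solvent
            "G1": 500, "H1": 500,  # TSA
            "I1": signal2,  # compound
        }
        viab = {"D1": 1000.0, "E1": 1000.0, "F1": 1000.0, "I1": viability}
        ds = make_dataset(layout, {1: sigs, 2: sigs}, {2: viab})
        calls, _ = call_screen(ds, k=3)
        return flag_viability(calls, ds, cutoff=0.7)

    def test_low_viability_and_low_signal_is_confounded(self):
        (call,) = self._screen(signal2=40.0, viability=400.0)
        assert call.viability_flag == "viability_confounded"
        assert call.relative_viability == pytest.approx(0.4)

    def test_healthy_compound_unflagged(self):
        (call,) = self._screen(signal2=120.0, viability=850.0)
        assert call.status == "hit"
        assert call.viability_flag == "none"

    def test_reduced_viability_hit_keeps_hit_status(self):
        (call,) = self._screen(signal2=200.0, viability=600.0)
        assert call.status == "hit"
        assert call.viability_flag == "reduced_viability"

    def test_missing_viability_marked_unassessed(self):
        layout = make_layout(compounds=("CPD",))
        sigs = {"D1": 100, "E1": 101, "F1": 99, "I1": 300}
        ds = make_dataset(layout, {1: sigs, 2: sigs})
        calls, _ = call_screen(ds, k=3)
        (call,) = flag_viability(calls, ds)
        assert call.viability_flag == "unassessed"


def test_model_results_surface():
    cfg = ScreenSimConfig(
        compounds_per_plate=(50,),
        libraries=("LOPAC",),
        read_cv=(0.1, 0.1),
        planted_hits=((7, 8.0),),
        planted_cytotoxics=((30, 0.2, 0.25),),
        seed=21,
    )
    ds, _ = simulate_screen(cfg)
    res = HitCallingModel(ds, k=3).fit()
    assert res.hit_ids == {"CPD-00007"}
    counts = res.status_counts()
    assert counts["hit"] + counts["no_hit"] + counts["incomplete"] == 50
    assert {"m1_solvent_cv_percent", "z_factor_m0_vs_m1"} <= set(res.plate_qc.columns)
    text = res.summary()
    assert "hits: 1" in text and "CPD-00007" in text
    table = res.table
    assert len(table) == 50 and "viability_flag" in table.columns
    # cytotoxic compound flagged via the read-2 counterscreen
    flag = table.loc[table.compound_id == "CPD-00030", "viability_flag"].iloc[0]
    assert flag in ("viability_confounded", "reduced_viability")
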