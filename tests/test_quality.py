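import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ambubrs as ab
from ambubrs.simulate import qualification_fixture


@pytest.fixture(scope="module")
def cfg():
    return ab.QualityConfig()


def reasons_of(mask, code):
    return {i for i, r in enumerate(mask.reasons) if code in r}


class TestCuffBlanking:
    def test_window_boundaries(self, cfg):
        beats = [84.0, 86.0, 159.0, 161.0]
        events = ab.EventList(events=[ab.Event("cuff_inflation", "", 100.0, 130.0)])
        mask = ab.blank_cuff(beats, events, cfg)
        # [100-15, 100+60] = [85, 160]
        assert reasons_of(mask, "cuff") == {1, 2}

    def test_no_events_all_pass(self, cfg):
        mask = ab.blank_cuff(np.arange(10.0), ab.EventList(), cfg)
        assert mask.qualified.all()

    def test_overlapping_windows_blank_their_union(self, cfg):
        events = ab.EventList(events=[
            ab.Event("cuff_inflation", "", 100.0, 130.0),
            ab.Event("cuff_inflation", "", 140.0, 170.0),
        ])
        beats = np.arange(80.0, 220.0, 5.0)
        mask = ab.blank_cuff(beats, events, cfg)
        expect = {i for i, t in enumerate(beats) if 85.0 <= t <= 160.0 or 125.0 <= t <= 200.0}
        assert reasons_of(mask, "cuff") == expect


class TestTemplateSNR:
    def test_identical_beats_all_qualified(self, cfg):
        beats = [np.sin(np.linspace(0, np.pi, 80))] * 10
        snr, mask = ab.template_snr(beats, cfg)
        assert mask.qualified.all()
        assert np.all(np.isinf(snr))

    def test_single_noisy_beat_flagged_alone(self, cfg):
        rng = np.random.default_rng(1)
        clean = np.sin(np.linspace(0, np.pi, 80))
        beats = [clean.copy() for _ in range(10)]
        # residual power ~10x template power: far below the 0 dB threshold
        beats[4] = clean + rng.normal(0, np.sqrt(10 * np.mean(clean**2)), 80)
        _, mask = ab.template_snr(beats, cfg)
        assert reasons_of(mask, "snr") == {4}

    def test_pure_noise_mostly_flagged_across_seeds(self, cfg):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            beats = [rng.normal(size=80) for _ in range(50)]
            _, mask = ab.template_snr(beats, cfg)
            fracs.append(1.0 - mask.qualified.mean())
        assert np.mean(fracs) >= 0.9

    def test_fewer_than_five_beats_all_flagged_with_warning(self, cfg):
        with pytest.warns(UserWarning):
            _, mask = ab.template_snr([np.ones(50)] * 3, cfg)
        assert not mask.qualified.any()


class TestPATRange:
    def test_default_range_is_80_to_400_ms(self, cfg):
        assert cfg.pat_valid_range_ms == (80.0, 400.0)

    @pytest.mark.parametrize("pat,bad", [(150.0, False), (40.0, True), (450.0, True),
                                         (80.0, False), (400.0, False)])
    def test_thresholds(self, cfg, pat, bad):
        mask = ab.pat_range_filter([pat], cfg)
        assert ("pat_range" in mask.reasons[0]) == bad

    def test_missing_pat_not_flagged(self, cfg):
        mask = ab.pat_range_filter([np.nan], cfg)
        assert mask.qualified[0]

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(pat=st.floats(1.0, 1000.0))
    def test_flag_iff_outside_pwv_window_property(self, cfg, pat):
        mask = ab.pat_range_filter([pat], cfg)
        lo, hi = cfg.pat_valid_range_ms
        assert mask.qualified[0] == (lo <= pat <= hi)


class TestVariability:
    def test_constant_rr_unflagged(self, cfg):
        mask = ab.variability_filter(np.full(50, 1000.0), cfg=cfg)
        assert mask.qualified.all()

    def test_forty_percent_jump_flagged(self, cfg):
        mask = ab.variability_filter([1000.0, 1000.0, 1400.0, 1000.0], cfg=cfg)
        assert reasons_of(mask, "variability") == {2, 3}  # jump and return

    def test_first_beat_never_flagged(self, cfg):
        mask = ab.variability_filter([5000.0, 1000.0], cfg=cfg)
        assert mask.qualified[0] and not mask.qualified[1]


class TestEpochQualification:
    def _mask_with_qualified(self, n, qualified_idx):
        m = ab.QualityMask.clean(n)
        for i in range(n):
            if i not in qualified_idx:
                m.reasons[i].add("snr")
        return m

    @pytest.mark.parametrize("n_q,disq", [(29, True), (30, False), (60, False)])
    def test_fifty_percent_rule_inclusive(self, cfg, n_q, disq):
        t = np.linspace(0.0, 59.9, 60)
        mask = self._mask_with_qualified(60, set(range(n_q)))
        out = ab.epoch_qualify(t, mask, [60], cfg)
        assert (len(reasons_of(out, "epoch")) > 0) == disq

    def test_zero_ecg_beats_disqualifies_with_warning(self, cfg):
        mask = ab.QualityMask.clean(3)
        with pytest.warns(UserWarning, match="zero ECG"):
            out = ab.epoch_qualify([1.0, 2.0, 3.0], mask, [0], cfg)
        assert reasons_of(out, "epoch") == {0, 1, 2}


class TestMaskAlgebra:
    def test_filters_are_idempotent(self, cfg):
        pat = np.array([150.0, 40.0, 150.0])
        once = ab.pat_range_filter(pat, cfg)
        twice = once.merge(ab.pat_range_filter(pat, cfg))
        assert [set(r) for r in twice.reasons] == [set(r) for r in once.reasons]

    def test_criteria_commute(self, cfg):
        fx = qualification_fixture(seed=2)
        a = ab.blank_cuff(fx["beat_times"], fx["events"], cfg).merge(
            ab.pat_range_filter(fx["pat_ms"], cfg))
        b = ab.pat_range_filter(fx["pat_ms"], cfg).merge(
            ab.blank_cuff(fx["beat_times"], fx["events"], cfg))
        assert [set(r) for r in a.reasons] == [set(r) for r in b.reasons]

    def test_masks_only_remove(self, cfg):
        fx = qualification_fixture(seed=2)
        m1 = ab.pat_range_filter(fx["pat_ms"], cfg)
        m2 = m1.merge(ab.variability_filter(fx["rr_ms"], fx["pat_ms"], cfg))
        assert np.all(m2.qualified <= m1.qualified)


class TestIntegratedFixture:
    def test_five_criteria_flag_exactly_the_planted_defects(self, cfg):
        fx = qualification_fixture(seed=7)
        mask = ab.qualify_beats(
            fx["beat_times"], fx["rr_ms"], fx["pat_ms"], fx["events"],
            beat_waveforms=fx["waveforms"],
            ecg_beats_per_epoch=fx["ecg_beats_per_epoch"], cfg=cfg,
        )
        assert reasons_of(mask, "cuff") == fx["expect_cuff"]
        assert reasons_of(mask, "snr") == fx["expect_snr"]
        assert reasons_of(mask, "pat_range") == fx["expect_pat_range"]
        assert reasons_of(mask, "variability") == fx["expect_variability"]
        flagged_epochs = {int(fx["beat_times"][i] // 60) for i in reasons_of(mask, "epoch")}
        assert flagged_epochs == fx["expect_epoch_epochs"]
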