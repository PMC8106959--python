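"""Axon tracing, length, HM classification, branch counting, abnormality."""

import math

import numpy as np
import pytest

from capscreen import (trace_axon, axon_length, classify_hm, count_branches,
                       score_abnormal, measure_embryo_axons, AxonTrace,
                       AbnormalityRules, generate_embryo, EmbryoGeometry)

from conftest import blank_channel


class TestTraceAndLength:
    def test_straight_vertical_axon_measures_its_row_span(
            self, geometry, straight_axon_channel):
        chan, col = straight_axon_channel
        t = trace_axon(chan, geometry, col)
        assert t.present
        assert len(t.path) == 51
        assert t.tip == (geometry.exit_row + 50, col)
        assert t.length_um == pytest.approx(50.0)

    def test_diagonal_path_length_uses_sqrt2_steps(self):
        path = [(10 + i, 20 + i) for i in range(11)]
        t = AxonTrace(exit_point=path[0], path=path, present=True)
        assert axon_length(t, 1.0) == pytest.approx(10 * math.sqrt(2))

    def test_blank_channel_reports_absent_axon(self, geometry):
        t = trace_axon(blank_channel(geometry), geometry, geometry.exit_cols[0])
        assert not t.present
        with pytest.warns(UserWarning):
            assert axon_length(t, 1.0) == 0.0

    def test_noise_only_channel_reports_absent_axon(self, geometry):
        rng = np.random.default_rng(0)
        chan = 20.0 + rng.normal(0, 10.0, geometry.shape).astype(np.float32)
        t = trace_axon(np.clip(chan, 0, None), geometry, geometry.exit_cols[2])
        assert not t.present

    def test_exit_point_outside_image_is_an_error(self, geometry):
        with pytest.raises(ValueError, match="outside"):
            trace_axon(np.zeros((10, 10), dtype=np.float32), geometry, 5)

    def test_length_invariant_under_anterior_posterior_mirroring(
            self, geometry, chodl_embryo):
        image, truth = chodl_embryo
        chan = image[0]
        mirrored = chan[:, ::-1].copy()
        ncols = geometry.shape[1]
        mirror_geo = EmbryoGeometry(
            pixel_size=geometry.pixel_size, exit_row=geometry.exit_row,
            hm_row=geometry.hm_row,
            ventral_extent_row=geometry.ventral_extent_row,
            exit_cols=tuple(sorted(ncols - 1 - c for c in geometry.exit_cols)),
            shape=geometry.shape)
        for col in geometry.exit_cols:
            t = trace_axon(chan, geometry, col)
            tm = trace_axon(mirrored, mirror_geo, ncols - 1 - col)
            assert t.present == tm.present
            if t.present:
                # thinning order is not mirror-symmetric, so equality is
                # approximate at the pixel level
                assert tm.length_um == pytest.approx(t.length_um, abs=1.5)

    def test_length_invariant_under_translation(self, geometry, chodl_embryo):
        image, _ = chodl_embryo
        shift = 6
        chan = np.zeros_like(image[0])
        chan[shift:, :] = image[0][:-shift, :]
        shifted_geo = EmbryoGeometry(
            pixel_size=geometry.pixel_size, exit_row=geometry.exit_row + shift,
            hm_row=geometry.hm_row + shift,
            ventral_extent_row=geometry.ventral_extent_row + shift,
            exit_cols=geometry.exit_cols, shape=geometry.shape)
        for col in geometry.exit_cols[:4]:
            t = trace_axon(image[0], geometry, col)
            ts = trace_axon(chan, shifted_geo, col)
            if t.present:
                assert ts.length_um == pytest.approx(t.length_um, abs=1e-6)


class TestClassifyHM:
    def _trace_with_tip(self, geometry, tip_row):
        col = geometry.exit_cols[0]
        path = [(r, col) for r in range(geometry.exit_row, tip_row + 1)]
        return AxonTrace(exit_point=path[0], path=path, present=True)

    def test_tip_exactly_on_hm_is_stalled(self, geometry):
        t = self._trace_with_tip(geometry, geometry.hm_row)
        assert classify_hm(t, geometry) == "stalled"

    def test_tip_well_past_hm_is_crossed(self, geometry):
        t = self._trace_with_tip(geometry, geometry.hm_row + 10)
        assert classify_hm(t, geometry, margin_um=2.0) == "crossed"

    def test_absent_axon_is_stalled(self, geometry):
        t = AxonTrace(exit_point=(geometry.exit_row, 0), path=[],
                      present=False)
        assert classify_hm(t, geometry) == "stalled"

    def test_monotone_in_tip_row(self, geometry):
        states = [classify_hm(self._trace_with_tip(geometry, r), geometry)
                  for r in range(geometry.hm_row - 3, geometry.hm_row + 12)]
        # once crossed, moving the tip further ventral never reverts
        first_crossed = states.index("crossed")
        assert all(s == "crossed" for s in states[first_crossed:])
        assert all(s == "stalled" for s in states[:first_crossed])


class TestCountBranches:
    def _axon_with_branch(self, geometry, extent_px):
        chan = blank_channel(geometry)
        col = geometry.exit_cols[2]
        r0 = geometry.exit_row
        chan[r0:r0 + 45, col] = 150.0
        br = r0 + 20
        chan[br, col + 1:col + 1 + extent_px] = 150.0
        return chan, col

    def test_unbranched_axon_counts_zero(self, geometry,
                                         straight_axon_channel):
        chan, col = straight_axon_channel
        t = trace_axon(chan, geometry, col)
        assert count_branches(chan, t, geometry, offset_um=8.0) == 0

    def test_branch_beyond_offset_counts_once_short_branch_never(
            self, geometry):
        chan, col = self._axon_with_branch(geometry, extent_px=12)
        t = trace_axon(chan, geometry, col)
        assert count_branches(chan, t, geometry, offset_um=8.0) == 1
        chan5, col = self._axon_with_branch(geometry, extent_px=5)
        t5 = trace_axon(chan5, geometry, col)
        assert count_branches(chan5, t5, geometry, offset_um=8.0) == 0

    def test_symmetric_under_side_relabeling(self, geometry):
        chan, col = self._axon_with_branch(geometry, extent_px=12)
        mirrored = chan[:, ::-1].copy()
        ncols = geometry.shape[1]
        mirror_geo = EmbryoGeometry(
            pixel_size=geometry.pixel_size, exit_row=geometry.exit_row,
            hm_row=geometry.hm_row,
            ventral_extent_row=geometry.ventral_extent_row,
            exit_cols=tuple(sorted(ncols - 1 - c for c in geometry.exit_cols)),
            shape=geometry.shape)
        tm = trace_axon(mirrored, mirror_geo, ncols - 1 - col)
        assert count_branches(mirrored, tm, mirror_geo, offset_um=8.0) == 1

    def test_absent_axon_counts_zero(self, geometry):
        t = AxonTrace(exit_point=(geometry.exit_row, 0), path=[],
                      present=False)
        assert count_branches(blank_channel(geometry), t, geometry) == 0


class TestSidecarOracle:
    """Measurements against the generator's ground truth."""

    def test_lengths_recover_truth_on_rendered_embryo(self, chodl_embryo,
                                                      chodl_traces):
        _, truth = chodl_embryo
        errs = [abs(t.length_um - a.true_length_um) / a.true_length_um
                for a, t in zip(truth.axons, chodl_traces)
                if a.present and t.present]
        assert np.mean(errs) < 0.03
        assert max(errs) < 0.06

    def test_hm_classification_recovers_truth(self, chodl_embryo,
                                              chodl_traces):
        _, truth = chodl_embryo
        measured = sum(t.hm_status == "crossed" for t in chodl_traces)
        assert measured == truth.n_crossed

    def test_noise_free_rendering_oracle_equality(self):
        # on noise-free renderings presence, HM status and branch counts
        # equal the ground truth for every axon, lengths within 5 %
        for seed in (7, 8, 9):
            image, truth = generate_embryo("chodl-DMSO", seed, noise=False)
            traces = measure_embryo_axons(image[0], truth.geometry)
            for a, t in zip(truth.axons, traces):
                assert t.present == a.present
                status = t.hm_status if t.present else "stalled"
                assert status == ("crossed" if a.crossed_hm else "stalled")
                assert t.branch_count == a.n_branches_beyond(8.0)
                if a.present:
                    assert t.length_um == pytest.approx(a.true_length_um,
                                                        rel=0.05)


class TestScoreAbnormal:
    def _trace(self, present=True, length=55.0, ectopic=0):
        return AxonTrace(exit_point=(0, 0), path=[(0, 0)] if present else [],
                         present=present, length_um=length,
                         ectopic_branch_count=ectopic)

    def test_all_healthy_scores_zero_percent(self):
        rules = AbnormalityRules(min_normal_length_um=43.0)
        flags, pct = score_abnormal([self._trace() for _ in range(8)], rules)
        assert pct == 0.0 and not any(flags)

    def test_missing_short_and_ectopic_axons_are_flagged(self):
        rules = AbnormalityRules(min_normal_length_um=43.0)
        traces = [self._trace(), self._trace(present=False),
                  self._trace(length=20.0), self._trace(ectopic=1)]
        flags, pct = score_abnormal(traces, rules)
        assert flags == [False, True, True, True]
        assert pct == pytest.approx(75.0)

    def test_empty_trace_list_is_an_error(self):
        with pytest.raises(ValueError):
            score_abnormal([], AbnormalityRules(min_normal_length_um=43.0))

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            AbnormalityRules(min_normal_length_um=-1.0)

    def test_uba1_scoring_recovers_truth_fraction(self):
        # mean measured percent-abnormal within 10 % relative of the
        # generator's realized abnormal fraction over 50 embryos
        measured, true = [], []
        for seed in range(50):
            image, truth = generate_embryo("uba1", 30_000 + seed)
            rules = AbnormalityRules.for_geometry(truth.geometry)
            traces = measure_embryo_axons(image[0], truth.geometry)
            _, pct = score_abnormal(traces, rules)
            measured.append(pct)
            true.append(100.0 * truth.abnormal_fraction)
        assert np.mean(measured) == pytest.approx(np.mean(true), rel=0.10)
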