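"""Generator behavior: two-step model, reproducibility, movie and flow truth."""

import math

import numpy as np
import pandas as pd
import pytest

import switchscope as ss
from switchscope.config import (CONSTRUCT_FREE_GFP, CONSTRUCT_GFP,
                                CONSTRUCT_MGFP, ConfigError)
from switchscope.synth import (logistic_level, protein_induction,
                               reporter_response_log10, rise_tau_minutes,
                               sample_birth_to_max)

from conftest import make_static_pedigree


class TestSwitchModel:
    def test_no_predisposition_means_no_events(self, small_switch_cfg):
        cfg = ss.SwitchModelConfig(n_traps=8, trap_capacity=120,
                                   p_predispose=0.0)
        _, gt = ss.simulate_pedigrees(cfg, seed=3, with_traces=False)
        assert len(gt.events) == 0
        assert gt.n_zero_event_traps == cfg.n_traps

    def test_identical_seeds_bitwise_identical(self, small_switch_cfg):
        p1, g1 = ss.simulate_pedigrees(small_switch_cfg, seed=11)
        p2, g2 = ss.simulate_pedigrees(small_switch_cfg, seed=11)
        pd.testing.assert_frame_equal(g1.cells, g2.cells)
        pd.testing.assert_frame_equal(g1.events, g2.events)
        for a, b in zip(p1, p2):
            for name in a.names():
                np.testing.assert_array_equal(a.records[name].trace.values,
                                              b.records[name].trace.values)

    def test_forced_activation_and_separation_bounds(self):
        """With p_activate = 1 and span 4, every clan that gets a chance to
        divide activates, and switching groups sit within 4 divisions of the
        establishing ancestor."""
        cfg = ss.SwitchModelConfig(n_traps=12, trap_capacity=150,
                                   p_predispose=5e-3, p_activate=1.0,
                                   predispose_span=(4, 4))
        _, gt = ss.simulate_pedigrees(cfg, seed=21, with_traces=False)
        assert len(gt.events) > 0
        assert gt.events.separation.between(1, 4).all()
        # every clan whose founder divided produced at least one event
        founders = gt.cells[gt.cells.clan_id.notna()].groupby("clan_id")
        clans_with_divisions = {
            cid for cid, grp in founders
            if len(grp) > 1}
        clans_with_events = set(gt.events.clan_id)
        assert clans_with_events <= set(gt.cells.clan_id.dropna())
        assert clans_with_divisions <= clans_with_events

    def test_opaque_inherited_only_after_rise_midpoint(self):
        cfg = ss.SwitchModelConfig(n_traps=30, trap_capacity=150)
        _, gt = ss.simulate_pedigrees(cfg, seed=2, with_traces=False)
        opaque = gt.cells[gt.cells.class_label == "opaque"]
        switching = gt.cells[gt.cells.class_label == "switching"]
        # no opaque-born cell without a prior activation event in its trap
        for trap_id in opaque.trap_id.unique():
            assert (gt.events.trap_id == trap_id).any()
        # switching cells come in mother-daughter event pairs
        assert set(gt.events.daughter_id) <= set(switching.cell_id)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ss.SwitchModelConfig(p_predispose=1.5).validate()
        with pytest.raises(ConfigError):
            ss.SwitchModelConfig(division_time_mean=-1).validate()
        with pytest.raises(ConfigError):
            ss.SwitchModelConfig(predispose_span=(0, 4)).validate()

    def test_birth_to_max_sampler_range_and_moments(self):
        cfg = ss.SwitchModelConfig()
        rng = np.random.default_rng(0)
        draws = sample_birth_to_max(rng, cfg, 4000)
        lo, hi = cfg.birth_to_max_range
        assert draws.min() >= lo and draws.max() <= hi
        assert abs(draws.mean() - 9.83) < 0.15   # truncated-lognormal mean
        assert abs(draws.std() - 2.63) < 0.15    # truncation tightens the sd


class TestSwitchingTraces:
    def test_trace_kinetics_match_generator(self):
        cfg = ss.SwitchModelConfig(noise_cv=0.0)
        traces, gt = ss.simulate_switching_traces(5, cfg, seed=4)
        tau = rise_tau_minutes(cfg)
        for tr, (_, row) in zip(traces, gt.iterrows()):
            t_min = tr.frames * cfg.frame_interval
            expect = logistic_level(t_min, row.t0_min, tau, 1.0, 40.0)
            np.testing.assert_allclose(tr.values, expect, rtol=1e-12)
            # 10-90 crossing separation of the generating curve is 3 h
            t10 = row.t0_min - tau * math.log(9)
            t90 = row.t0_min + tau * math.log(9)
            assert (t90 - t10) / 60.0 == pytest.approx(3.0, abs=1e-9)
            # the curve reaches 95% of the span at the drawn birth-to-max time
            lvl = logistic_level(np.array([row.birth_to_max_h * 60.0]),
                                 row.t0_min, tau, 1.0, 40.0)[0]
            assert lvl == pytest.approx(1.0 + 0.95 * 39.0, rel=1e-6)


class TestRenderMovie:
    def test_single_white_cell_area_and_metric(self):
        cfg = ss.SwitchModelConfig(n_frames=2)
        ped = make_static_pedigree(["0"])
        movie, masks, gt = ss.render_movie(ped, cfg, canvas_shape=(160, 160),
                                           noise_sd=0.0, dic_noise_sd=0.0,
                                           seed=0)
        mask = masks[0] == 1
        assert mask.sum() == pytest.approx(cfg.white_area, rel=0.05)
        metric = ss.top_pixels_metric(movie.gfp(0), mask)
        assert metric.value == pytest.approx(cfg.white_level, rel=0.05)

    def test_drift_bookkeeping_exact(self):
        cfg = ss.SwitchModelConfig(n_frames=4)
        ped = make_static_pedigree(["0"], n_frames=4)
        drift = np.cumsum(np.vstack([[0, 0]] + [[3, -2]] * 3), axis=0)
        _, _, gt = ss.render_movie(ped, cfg, canvas_shape=(160, 160),
                                   drift=drift, noise_sd=0, dic_noise_sd=0,
                                   seed=0)
        np.testing.assert_array_equal(gt.offsets, drift)

    def test_masks_partition_and_conservation(self, separated_cells_movie):
        _, movie, masks, gt = separated_cells_movie
        labels = set(np.unique(masks[0])) - {0}
        assert labels == set(gt.label_map)
        # every ground-truth cell has nonempty pixels in every live frame
        for lab in labels:
            assert (masks[0] == lab).sum() > 500

    def test_canvas_overflow_drops_cells(self):
        cfg = ss.SwitchModelConfig(n_frames=2)
        ped = make_static_pedigree(["0", "0.1", "0.2"])
        _, _, gt = ss.render_movie(ped, cfg, canvas_shape=(70, 70),
                                   noise_sd=0, dic_noise_sd=0, seed=0)
        assert len(gt.dropped) >= 1
        assert set(gt.label_map.values()) | set(gt.dropped) == {"0", "0.1", "0.2"}


class TestFlowPlate:
    def test_zero_hormone_reporter_at_basal(self, small_flow_cfg):
        cfg = ss.FlowModelConfig(events_per_well=800, hormone_concs=(0.0,),
                                 meas_cv_mcherry=0.0, protein_cv=0.0)
        plate = ss.simulate_strain_day(CONSTRUCT_MGFP, cfg, seed=1)
        intact = plate.events[plate.events.true_label == "intact"]
        med = np.median(np.log10(intact.true_reporter))
        assert med == pytest.approx(cfg.reporter_log10_basal, abs=0.02)

    def test_free_gfp_never_activates_reporter(self, small_flow_cfg):
        plate = ss.simulate_strain_day(CONSTRUCT_FREE_GFP, small_flow_cfg,
                                       seed=2)
        intact = plate.events[plate.events.true_label == "intact"]
        by_conc = intact.groupby("hormone_nM").true_reporter.median()
        assert np.log10(by_conc).max() == pytest.approx(
            small_flow_cfg.reporter_log10_basal, abs=0.05)

    def test_half_max_at_K_exactly(self):
        cfg = ss.FlowModelConfig()
        mid = reporter_response_log10(np.array([cfg.halfmax_mgfp]), cfg,
                                      CONSTRUCT_MGFP)[0]
        assert mid == pytest.approx(
            0.5 * (cfg.reporter_log10_basal + cfg.reporter_log10_max), rel=1e-12)

    def test_monotone_below_decline_threshold(self, small_flow_cfg):
        for construct in (CONSTRUCT_MGFP, CONSTRUCT_GFP):
            plate = ss.simulate_strain_day(construct, small_flow_cfg, seed=3)
            intact = plate.events[plate.events.true_label == "intact"]
            sub = intact[intact.hormone_nM < small_flow_cfg.gfp_decline_threshold]
            med = sub.groupby("hormone_nM").mCherry.median()
            assert (np.diff(med.to_numpy()) > -0.05 * med.to_numpy()[:-1]).all()

    def test_gfp_fusion_declines_at_high_hormone(self, small_flow_cfg):
        plate = ss.simulate_strain_day(CONSTRUCT_GFP, small_flow_cfg, seed=4)
        intact = plate.events[plate.events.true_label == "intact"]
        med = intact.groupby("hormone_nM").true_reporter.median()
        top = med.index.max()
        below = med[med.index < small_flow_cfg.gfp_decline_threshold].max()
        assert med[top] < below

    def test_every_event_labeled(self, small_flow_cfg):
        plate = ss.simulate_strain_day(CONSTRUCT_MGFP, small_flow_cfg, seed=5)
        assert set(plate.events.true_label) <= {"intact", "debris", "aggregate"}
        assert plate.events.true_label.notna().all()

    def test_empty_hormone_list_rejected(self):
        with pytest.raises(ConfigError):
            ss.FlowModelConfig(hormone_concs=()).validate()

    def test_protein_induction_free_gfp_10x(self):
        cfg = ss.FlowModelConfig()
        h = np.array([5.0])
        fusion = protein_induction(h, cfg, CONSTRUCT_MGFP)
        free = protein_induction(h, cfg, CONSTRUCT_FREE_GFP)
        assert free[0] == pytest.approx(10.0 * fusion[0], rel=1e-12)
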