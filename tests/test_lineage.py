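"""Pedigree model, LOESS smoothing, switch calling, and grouping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import switchscope as ss
from switchscope.config import ConfigError, DataError
from switchscope.lineage import (CellRecord, Trace, build_pedigree,
                                 classify_switch, divisions_between,
                                 group_switching_cells, parent_name,
                                 smooth_trace, SwitchCall)


def _records(names, birth=None):
    birth = birth or {}
    return [CellRecord(cell_id=n, trap_id="t", birth_frame=birth.get(n, 0),
                       end_frame=100) for n in names]


class TestBuildPedigree:
    def test_single_root(self):
        ped = build_pedigree(_records(["0"]))
        assert ped.roots == ["0"] and len(ped) == 1

    def test_dotted_names_link_parents(self):
        ped = build_pedigree(_records(["0", "0.1", "0.2", "0.2.1"]))
        assert ped.children_of("0") == ["0.1", "0.2"]
        assert ped.children_of("0.2") == ["0.2.1"]
        assert parent_name("0.2.1") == "0.2"

    def test_orphan_rejected_with_offender(self):
        with pytest.raises(DataError, match="1.1"):
            build_pedigree(_records(["0", "1.1"]))

    def test_duplicate_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            build_pedigree(_records(["0", "0"]))

    def test_daughter_born_before_mother_rejected(self):
        recs = [CellRecord(cell_id="0", birth_frame=10, end_frame=20),
                CellRecord(cell_id="0.1", birth_frame=5, end_frame=20)]
        with pytest.raises(DataError):
            build_pedigree(recs)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.lists(st.integers(1, 3), min_size=0, max_size=3),
                    min_size=1, max_size=12, unique_by=tuple))
    def test_name_tree_roundtrip(self, suffixes):
        """Valid name sets map bijectively onto forests: closing a name set
        under parents and rebuilding returns exactly the same names."""
        names = set()
        for suf in suffixes:
            name = "0" if not suf else "0." + ".".join(map(str, suf))
            while True:
                names.add(name)
                p = parent_name(name)
                if p is None:
                    break
                name = p
        ped = build_pedigree(_records(sorted(names)))
        assert set(ped.names()) == names
        rebuilt = {ped.roots[0]}
        stack = [ped.roots[0]]
        while stack:
            cur = stack.pop()
            for ch in ped.children_of(cur):
                rebuilt.add(ch)
                stack.append(ch)
        assert rebuilt == names

    def test_divisions_between(self):
        assert divisions_between("0", "0.3.1") == 4
        assert divisions_between("0.2", "0.2.1") == 1
        assert divisions_between("0", "0") == 0
        with pytest.raises(DataError):
            divisions_between("0.1", "0.2")


class TestSmoothTrace:
    def test_constant_unchanged(self):
        tr = Trace(frames=np.arange(20), values=np.full(20, 3.0))
        sm = smooth_trace(tr)
        np.testing.assert_allclose(sm.smoothed, 3.0, rtol=1e-9)

    def test_noiseless_logistic_preserved(self):
        t = np.arange(60)
        vals = 1 + 39 / (1 + np.exp(-(t - 30) / 3.4))
        sm = smooth_trace(Trace(frames=t, values=vals), span=0.1)
        assert np.max(np.abs(sm.smoothed - vals)) < 0.01 * vals.max()

    def test_noisy_switching_trace_close_to_truth(self):
        cfg = ss.SwitchModelConfig()
        noiseless, gt = ss.simulate_switching_traces(1, cfg, seed=9)
        rng = np.random.default_rng(1)
        sd = 0.05 * 40.0
        noisy = noiseless[0].values + rng.normal(0, sd, len(noiseless[0]))
        sm = smooth_trace(Trace(frames=noiseless[0].frames, values=noisy),
                          span=0.08)
        assert np.max(np.abs(sm.smoothed - noiseless[0].values)) <= 3 * sd

    def test_invalid_span_rejected(self):
        tr = Trace(frames=np.arange(10), values=np.ones(10))
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ConfigError):
                smooth_trace(tr, span=bad)

    def test_short_trace_rejected(self):
        with pytest.raises(DataError):
            smooth_trace(Trace(frames=np.arange(3), values=np.ones(3)))


class TestClassifySwitch:
    def test_flat_white_trace(self):
        tr = Trace(frames=np.arange(50), values=np.ones(50))
        call = classify_switch(tr, 1.0, 40.0)
        assert call.state == "white"

    def test_born_high_is_opaque(self):
        tr = Trace(frames=np.arange(50), values=np.full(50, 40.0))
        assert classify_switch(tr, 1.0, 40.0).state == "opaque"

    def test_generator_trace_rise_about_3h(self):
        cfg = ss.SwitchModelConfig()
        traces, _ = ss.simulate_switching_traces(10, cfg, seed=3)
        rises = [classify_switch(t, 1.0, 40.0).rise_10_90 for t in traces]
        assert np.mean(rises) == pytest.approx(3.0, abs=0.4)

    def test_birth_to_max_recovered(self):
        cfg = ss.SwitchModelConfig()
        traces, gt = ss.simulate_switching_traces(21, cfg, seed=6)
        tmax = np.array([classify_switch(t, 1.0, 40.0).t_max for t in traces])
        assert np.all(np.isfinite(tmax))
        assert np.mean(tmax) == pytest.approx(gt.birth_to_max_h.mean(), abs=1.2)

    def test_short_trace_low_confidence(self):
        tr = Trace(frames=np.arange(3), values=np.full(3, 40.0))
        call = classify_switch(tr, 1.0, 40.0)
        assert call.state == "white" and call.low_confidence

    def test_monotone_in_trace_values(self):
        """Raising every trace value never flips an opaque call to white."""
        cfg = ss.SwitchModelConfig()
        traces, _ = ss.simulate_switching_traces(5, cfg, seed=8)
        for tr in traces:
            base = classify_switch(tr, 1.0, 40.0)
            raised = Trace(frames=tr.frames, values=tr.values + 2.0)
            up = classify_switch(raised, 1.0, 40.0)
            if base.state in ("switching", "opaque"):
                assert up.state in ("switching", "opaque")

    def test_nucleus_lost_frames_excluded(self):
        vals = np.ones(60)
        vals[40:] = 40.0   # spurious "rise" after nucleus loss
        tr = Trace(frames=np.arange(60), values=vals)
        call = classify_switch(tr, 1.0, 40.0, nucleus_lost_frame=40)
        assert call.state == "white"

    def test_bad_references_rejected(self):
        tr = Trace(frames=np.arange(10), values=np.ones(10))
        with pytest.raises(ConfigError):
            classify_switch(tr, 40.0, 1.0)


def _call(state, t10):
    return SwitchCall(state=state, t_activation_start=t10, t_max=t10 + 2,
                      rise_10_90=3.0)


def _ped(names, birth):
    return build_pedigree(
        [CellRecord(cell_id=n, trap_id="t", birth_frame=birth[n],
                    end_frame=120) for n in names], trap_id="t")


class TestGrouping:
    def test_direct_pair(self):
        ped = _ped(["0", "0.1"], {"0": 0, "0.1": 10})
        calls = {"0": _call("switching", 3.0), "0.1": _call("switching", 1.0)}
        groups = group_switching_cells(ped, calls)
        assert len(groups) == 1
        g = groups[0]
        assert g.label == "direct-pair" and g.pairs == [("0", "0.1")]

    def test_four_cell_synchronous_chain(self):
        # mother, previous daughter, new daughter, granddaughter all rise
        # simultaneously at absolute frame 40
        birth = {"0": 0, "0.1": 10, "0.2": 20, "0.1.1": 25}
        calls = {n: _call("switching", (40 - b) * 12 / 60.0)
                 for n, b in birth.items()}
        ped = _ped(list(birth), birth)
        groups = group_switching_cells(ped, calls)
        assert len(groups) == 1
        g = groups[0]
        assert g.label == "four-cell" and len(g.cells) == 4
        assert len(g.pairs) == 3   # 0-0.1, 0-0.2, 0.1-0.1.1

    def test_mixed_fate_two_groups(self):
        # two asynchronous pairs in one lineage, separated by a
        # non-switching daughter
        birth = {"0": 0, "0.1": 10, "0.2": 20, "0.3": 30, "0.3.1": 40}
        ped = _ped(list(birth), birth)
        calls = {n: _call("white", math.nan) for n in birth}
        calls["0"] = _call("switching", 2.0)       # starts frame 10
        calls["0.1"] = _call("switching", 0.0)     # starts frame 10
        calls["0.3"] = _call("switching", 6.0)     # starts frame 60
        calls["0.3.1"] = _call("switching", 4.0)   # starts frame 60
        groups = group_switching_cells(ped, calls)
        assert len(groups) == 2
        assert all(g.label == "mixed-fate-member" for g in groups)
        seps = sorted(g.separation for g in groups)
        assert seps == [1, 4]   # divisions from the establishing ancestor "0"

    def test_missing_calls_rejected(self):
        ped = _ped(["0", "0.1"], {"0": 0, "0.1": 5})
        with pytest.raises(DataError):
            group_switching_cells(ped, {"0": _call("white", math.nan)})

    def test_roundtrip_separations_within_span(self):
        """Observed mixed-fate separations stay within the generator's
        1-4-division heritability span and match ground truth."""
        cfg = ss.SwitchModelConfig(n_traps=40, trap_capacity=150,
                                   p_predispose=4e-3, p_activate=0.4)
        peds, gt = ss.simulate_pedigrees(cfg, seed=17)
        assert gt.events.separation.between(1, 4).all()
        from switchscope.pipeline import classify_pedigrees
        rc = ss.RunConfig(switch=cfg)
        _, groups_by_trap = classify_pedigrees(peds, rc)
        seps = [g.separation for gs in groups_by_trap.values() for g in gs
                if g.separation is not None]
        assert seps, "expected at least one mixed-fate pedigree"
        assert all(1 <= s <= 4 for s in seps)
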