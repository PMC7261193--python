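"""Contact strength / occupancy / lifetime statistics and map operations."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yap8dna.contact_dynamics import (ContactTimeSeries, build_map, compare_maps,
                                      filter_map, mean_lifetime, occupancy,
                                      pair_stats, run_lengths, strength_series)
from yap8dna.errors import ConfigurationError
from yap8dna.synthetic import MarkovContactSpec, gen_markov_series

P1 = ("monomer1", 7, "ARG")
P2 = ("monomer1", 11, "ARG")


def _dna(i, name="DT"):
    return ("strandW", i, name)


def _events(**pairs):
    """pairs: name -> (protein, dna, itype, counts)"""
    return {(p, d, t): ContactTimeSeries(pair=(p, d), itype=t,
                                         counts=np.asarray(c, dtype=int))
            for p, d, t, c in pairs.values()}


class TestElementaryStats:
    def test_strength_is_elementwise_sum(self):
        s = strength_series([2, 0, 1], [1, 0, 0])
        assert s.tolist() == [3, 0, 1]

    def test_strength_mean_and_population_sd(self):
        stats = pair_stats(np.array([2, 0, 1]), frame_interval=0.1)
        assert stats.strength_mean == pytest.approx(1.0)
        assert stats.strength_sd == pytest.approx(0.816496580927726)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            strength_series([1, 0], [1, 0, 0])

    def test_occupancy_examples(self):
        assert occupancy([1, 1, 0, 1, 0, 0, 1, 1, 1, 0]) == pytest.approx(60.0)
        assert occupancy([1] * 5) == 100.0
        assert occupancy([0] * 5) == 0.0

    def test_lifetime_run_enumeration(self):
        series = [1, 1, 0, 1, 0, 0, 1, 1, 1, 0]
        assert sorted(run_lengths(series).tolist()) == [1, 2, 3]
        assert mean_lifetime(series, 0.1) == pytest.approx(0.2)
        assert mean_lifetime([0, 0, 0], 0.1) == 0.0

    def test_markov_occupancy_within_3se(self):
        spec = MarkovContactSpec(p_on=0.2, p_off=0.2, F=10_000, seed=123)
        series, _ = gen_markov_series(spec)
        p = spec.stationary_occupancy
        # effective sample size ~ F / correlation time; 3 SE with the
        # naive SE inflated by the telegraph autocorrelation factor
        rho = 1 - spec.p_on - spec.p_off
        se = np.sqrt(p * (1 - p) / spec.F * (1 + rho) / (1 - rho))
        assert abs(occupancy(series.astype(int)) / 100 - p) < 3 * se

    def test_markov_lifetime_close_to_inverse_p_off(self):
        spec = MarkovContactSpec(p_on=0.2, p_off=0.1, F=100_000, seed=7)
        series, _ = gen_markov_series(spec)
        mean_frames = mean_lifetime(series.astype(int), 1.0)
        assert mean_frames == pytest.approx(1 / spec.p_off, rel=0.05)


class TestBuildAndFilter:
    def test_single_always_on_contact(self):
        events = _events(a=(P1, _dna(3), "hbond", [1] * 10))
        cmap = build_map(events, frame_interval=0.1)
        stats = cmap.strength["monomer1"][(P1, _dna(3))]
        assert stats.occupancy == 100.0
        assert stats.strength_mean == 1.0
        assert stats.n_events == 1
        assert stats.mean_lifetime == pytest.approx(1.0)  # 10 frames x 0.1 ns

    def test_hbond_and_saltbridge_sum_into_strength(self):
        events = _events(a=(P1, _dna(3), "hbond", [2, 0, 1]),
                         b=(P1, _dna(3), "saltbridge", [1, 0, 0]))
        cmap = build_map(events)
        assert cmap.series[(P1, _dna(3))].tolist() == [3, 0, 1]

    def test_hydrophobic_excluded_from_strength(self):
        events = _events(a=(P1, _dna(3), "hydrophobic", [1, 1, 1]))
        cmap = build_map(events)
        assert cmap.strength == {}
        assert cmap.hydrophobic["monomer1"][(P1, _dna(3))].occupancy == 100.0

    def test_planted_occupancies_reproduced_exactly(self):
        events = _events(a=(P1, _dna(3), "hbond", [1] * 10),
                         b=(P2, _dna(5), "saltbridge", [1, 1, 1, 1] + [0] * 6))
        cmap = build_map(events)
        occs = {p[0]: s.occupancy for p, s in cmap.strength["monomer1"].items()}
        assert occs == {P1: 100.0, P2: 40.0}

    def test_empty_event_set_gives_empty_map(self):
        cmap = build_map({})
        assert cmap.strength == {} and cmap.hydrophobic == {}

    def test_filter_boundary_inclusive_at_25(self):
        events = _events(keep=(P1, _dna(3), "hbond", [1] * 25 + [0] * 75),
                         drop=(P2, _dna(5), "hbond", [1] * 24 + [0] * 76))
        cmap = build_map(events)
        kept = filter_map(cmap, 25.0)
        assert (P1, _dna(3)) in kept.strength["monomer1"]
        assert (P2, _dna(5)) not in kept.strength.get("monomer1", {})

    def test_filter_threshold_zero_is_identity(self):
        events = _events(a=(P1, _dna(3), "hbond", [1, 0, 0, 0]))
        cmap = build_map(events)
        assert filter_map(cmap, 0.0).strength == cmap.strength

    @pytest.mark.parametrize("bad", [-1.0, 100.5])
    def test_filter_threshold_out_of_range(self, bad):
        with pytest.raises(ConfigurationError):
            filter_map(build_map({}), bad)


class TestCompare:
    def test_map_against_itself(self):
        events = _events(a=(P1, _dna(3), "hbond", [1, 2, 0]))
        cmap = build_map(events)
        cmp = compare_maps(cmap, cmap)
        assert cmp.unique_to_a.empty and cmp.unique_to_b.empty
        assert (cmp.table["mean_a"] == cmp.table["mean_b"]).all()
        assert cmp.significant.empty

    def test_missing_pair_flagged_unique(self):
        map_a = build_map(_events(a=(P1, _dna(3), "hbond", [1, 1, 1]),
                                  b=(P2, _dna(5), "hbond", [1, 1, 0])))
        map_b = build_map(_events(a=(P1, _dna(3), "hbond", [1, 1, 1])))
        cmp = compare_maps(map_a, map_b)
        assert len(cmp.unique_to_a) == 1
        assert cmp.unique_to_a.iloc[0]["protein_res"] == 11

    def test_wt_vs_mutant_reports_loss_in_tail_region(self):
        # wild type keeps tail contacts at residues 9-16; the mutant loses
        # them while the shared upstream contact (residue 7) is unchanged
        wt_events = {}
        for r in (7, 9, 12, 16):
            key = (("monomer1", r, "ARG"), _dna(r), "hbond")
            wt_events[key] = ContactTimeSeries(pair=key[:2], itype="hbond",
                                               counts=np.ones(10, dtype=int))
        mut_events = {k: v for k, v in wt_events.items() if k[0][1] == 7}
        cmp = compare_maps(build_map(wt_events), build_map(mut_events))
        lost = cmp.significant
        assert sorted(lost["protein_res"]) == [9, 12, 16]
        assert 7 not in set(lost["protein_res"])


class TestInvariants:
    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_frame_reversal_leaves_stats_unchanged(self, counts):
        fwd = pair_stats(np.array(counts), 0.1)
        rev = pair_stats(np.array(counts[::-1]), 0.1)
        assert fwd.strength_mean == pytest.approx(rev.strength_mean)
        assert fwd.strength_sd == pytest.approx(rev.strength_sd)
        assert fwd.occupancy == rev.occupancy
        assert fwd.mean_lifetime == pytest.approx(rev.mean_lifetime)
        assert fwd.n_events == rev.n_events

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_self_concatenation(self, counts):
        s = np.array(counts)
        double = np.concatenate([s, s])
        assert occupancy(double) == pytest.approx(occupancy(s))
        # run multiset doubles except for a possible boundary merge
        r1, r2 = run_lengths(s), run_lengths(double)
        if s.size and s[0] >= 1 and s[-1] >= 1:
            assert r2.sum() == 2 * r1.sum()
            assert len(r2) == 2 * len(r1) - 1
        else:
            assert len(r2) == 2 * len(r1)

    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_mean_bounded_and_occupancy_consistency(self, counts):
        s = np.array(counts)
        stats = pair_stats(s, 0.1)
        assert stats.strength_mean <= s.max()
        assert (stats.occupancy == 0) == (stats.strength_mean == 0) == (stats.n_events == 0)
        if stats.occupancy == 100.0:
            assert stats.strength_mean >= 1
            assert stats.n_events == 1

    def test_map_building_is_order_independent(self):
        e1 = _events(a=(P1, _dna(3), "hbond", [1, 0, 1]))
        e2 = _events(b=(P2, _dna(5), "saltbridge", [0, 1, 1]))
        ab = build_map({**e1, **e2})
        ba = build_map({**e2, **e1})
        assert ab.strength == ba.strength
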