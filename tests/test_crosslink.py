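"""Sequential saturation, interlinking metrics and Monte-Carlo replication."""

import numpy as np
import pytest

from leverxlink import (
    BindingState,
    CrosslinkerSpec,
    crosslink_curve,
    default_side_nm,
    interlinked_fraction,
    preset,
    run_replicates,
    saturate_binding,
)
from leverxlink.crosslink import Molecule
from leverxlink.seeding import spawn_rng
from leverxlink.surface import LeverField

from ._bruteforce import brute_force_interlinked_fraction, brute_force_saturate


def make_field(anchors, d=100.0):
    anchors = np.asarray(anchors, dtype=float)
    return LeverField(
        anchors=anchors,
        mean_distance_nm=d,
        occupancy_p=0.01,
        seed=0,
        side_length_nm=1000.0,
        in_radius_nm=2.5,
    )


class TestSaturateBinding:
    def test_single_lever_only_singly_bound(self, spec_441):
        state = saturate_binding(make_field([[0, 0]]), spec_441, seed=1)
        assert state.n_bridges == 0
        assert all(m.lever_b is None for m in state.molecules)
        assert state.n_molecules == 2  # two sites, one molecule each

    def test_two_levers_within_reach_bridge(self, spec_441):
        # 50 nm apart, reach 100 nm: the first molecule bridges the pair, and
        # the second also bridges (both levers still expose a free site within
        # reach), consuming all four sites with two doubly bound molecules
        state = saturate_binding(make_field([[0, 0], [50, 0]]), spec_441, seed=3)
        assert state.bridges == {(0, 1)}
        assert state.n_molecules == 2
        assert all(m.lever_b is not None for m in state.molecules)
        assert interlinked_fraction(state) == 1.0

    def test_two_levers_beyond_reach_never_bridge(self, spec_841):
        # 150 nm apart, reach 82 nm: four singly bound molecules
        state = saturate_binding(make_field([[0, 0], [150, 0]]), spec_841, seed=5)
        assert state.n_bridges == 0
        assert state.n_molecules == 4
        assert interlinked_fraction(state) == 0.0

    def test_all_sites_consumed_at_saturation(self, field_d100, spec_441):
        state = saturate_binding(field_d100, spec_441, seed=9)
        assert (state.free_sites == 0).all()
        assert state.sites_consumed() == 2 * state.n_levers

    def test_bridges_respect_reach(self, field_d100, spec_841):
        state = saturate_binding(field_d100, spec_841, seed=13)
        reach = spec_841.reach_nm
        for a, b in state.bridges:
            d = np.hypot(*(field_d100.anchors[a] - field_d100.anchors[b]))
            assert d <= reach + 1e-9

    def test_no_self_bridge(self, field_d100, spec_441):
        state = saturate_binding(field_d100, spec_441, seed=17)
        assert all(m.lever_a != m.lever_b for m in state.molecules)

    def test_seeded_determinism(self, field_d100, spec_441):
        a = saturate_binding(field_d100, spec_441, seed=21)
        b = saturate_binding(field_d100, spec_441, seed=21)
        assert a.bridges == b.bridges
        assert a.molecules == b.molecules

    def test_empty_field_raises(self, spec_441):
        with pytest.raises(ValueError):
            saturate_binding(make_field(np.empty((0, 2))), spec_441, seed=0)

    def test_site_weighted_initial_draw_also_saturates(self, field_d100, spec_441):
        state = saturate_binding(field_d100, spec_441, seed=2, initial_draw="sites")
        assert (state.free_sites == 0).all()


class TestBruteForceOracle:
    """The optimized simulator must replay the literal rules exactly."""

    @pytest.mark.parametrize("case", range(100))
    def test_bridge_sets_identical_on_small_instances(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(1, 9))
        anchors = rng.uniform(0, 250, size=(n, 2))
        span = float(rng.uniform(0, 30))
        spec = CrosslinkerSpec(f"case{case}", span_nm=span)
        fld = make_field(anchors)
        seed = int(rng.integers(0, 2**31))
        state = saturate_binding(fld, spec, seed=seed)
        # shared frozen uniform stream, everything else independent
        uniforms = spawn_rng(seed, "binding_order").random(4 * n)
        bridges, molecules = brute_force_saturate(
            [tuple(a) for a in anchors], spec.reach_nm, uniforms
        )
        assert state.bridges == bridges
        assert [(m.lever_a, m.lever_b) for m in state.molecules] == molecules
        assert interlinked_fraction(state) == pytest.approx(
            brute_force_interlinked_fraction(bridges, n)
        )


class TestInterlinkedFraction:
    def test_no_bridges_zero(self):
        state = BindingState(
            n_levers=3, free_sites=np.zeros(3, int),
            molecules=[Molecule(0, 0, None)], bridges=set(),
        )
        assert interlinked_fraction(state) == 0.0

    def test_chain_counts_all_members(self):
        # A-B, B-C among 4 levers; D isolated -> 3/4
        state = BindingState(
            n_levers=4, free_sites=np.zeros(4, int), molecules=[],
            bridges={(0, 1), (1, 2)},
        )
        assert interlinked_fraction(state) == 0.75

    def test_bounded_by_one(self, field_d100, spec_441):
        state = saturate_binding(field_d100, spec_441, seed=33)
        assert 0.0 <= interlinked_fraction(state) <= 1.0


class TestRunReplicates:
    def test_single_replicate_matches_direct_run(self, spec_441):
        res = run_replicates(100.0, spec_441, n_surfaces=1, n_repeats=1,
                             base_seed=5, side_nm=1000.0)
        assert res.fractions.shape == (1, 1)
        assert 0.0 <= res.fractions[0, 0] <= 1.0
        # composition identity: rerunning returns the identical value
        res2 = run_replicates(100.0, spec_441, n_surfaces=1, n_repeats=1,
                              base_seed=5, side_nm=1000.0)
        assert res.fractions[0, 0] == res2.fractions[0, 0]

    def test_bitwise_reproducible(self, spec_841):
        a = run_replicates(100.0, spec_841, 2, 3, base_seed=8, side_nm=1000.0)
        b = run_replicates(100.0, spec_841, 2, 3, base_seed=8, side_nm=1000.0)
        np.testing.assert_array_equal(a.fractions, b.fractions)

    def test_sparse_limit_fraction_vanishes(self, spec_441):
        # d = 10 x reach: the chance of a reachable neighbor is tiny
        d = 10 * spec_441.reach_nm
        res = run_replicates(d, spec_441, 3, 3, base_seed=2, side_nm=6000.0)
        assert res.mean < 0.05

    def test_default_side_policy(self, spec_441):
        assert default_side_nm(50.0, 100.0) == 2400.0
        assert default_side_nm(200.0, 100.0) == 3600.0

    def test_invalid_counts_raise(self, spec_441):
        with pytest.raises(ValueError):
            run_replicates(100.0, spec_441, n_surfaces=0)


@pytest.fixture(scope="module")
def small_curve():
    specs = [preset("441"), preset("841")]
    return crosslink_curve(specs, distances=(100.0, 200.0), n_surfaces=2,
                           n_repeats=3, base_seed=4, side_nm=1500.0)


class TestCrosslinkCurve:
    def test_factorial_shape(self, small_curve):
        replicates, summary = small_curve
        assert len(summary) == 4
        assert set(summary["spec"]) == {"441", "841"}
        assert len(replicates) == 4 * 6

    def test_fractions_within_unit_interval(self, small_curve):
        replicates, _ = small_curve
        assert replicates["fraction_interlinked"].between(0, 1).all()

    def test_positive_distances_required(self):
        with pytest.raises(ValueError):
            crosslink_curve([preset("441")], distances=(-50.0,))

    def test_mean_nonincreasing_in_distance_and_ordered_by_span(self, small_curve):
        _, summary = small_curve
        for name in ("441", "841"):
            s = summary[summary["spec"] == name].sort_values("mean_distance_nm")
            means = s["mean"].to_numpy()
            ses = (s["sd"] / np.sqrt(s["n"])).to_numpy()
            assert means[1] <= means[0] + 2 * (ses[0] + ses[1])
        for d in (100.0, 200.0):
            s = summary[summary["mean_distance_nm"] == d].set_index("spec")
            se = (s["sd"] / np.sqrt(s["n"]))
            assert s.loc["441", "mean"] >= s.loc["841", "mean"] - 2 * (
                se["441"] + se["841"]
            )
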