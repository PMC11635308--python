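"""Scenario generation and the robustness battery.

The full default battery (33 scenarios on the 0.1°C grid) runs in the
acceptance tests; here scenarios are swept on coarse grids to keep the
suite fast.
"""

import numpy as np
import pytest

from thermolv import (
    Community,
    ParameterError,
    ScenarioSpec,
    default_community,
    evaluate_robustness,
    generate_scenarios,
    pairwise_matchups,
    skewness_metric,
)
from conftest import random_community


class TestPairwise:
    def test_three_species_gives_the_three_named_pairs(self, community):
        pairs = pairwise_matchups(community)
        assert len(pairs) == 3
        assert {tuple(sorted(p.ids)) for p in pairs} == {
            ("S1", "S2"),
            ("S1", "S3"),
            ("S2", "S3"),
        }

    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 6)])
    def test_combinatorial_count(self, n, expected):
        comm = random_community(np.random.default_rng(0), n)
        assert len(pairwise_matchups(comm)) == expected

    def test_pairs_preserve_curves_capacities_and_n0(self, community):
        pair = pairwise_matchups(community)[0]
        for sp, n0 in zip(pair.species, pair.n0):
            idx = community.ids.index(sp.id)
            assert sp.curve == community.species[idx].curve
            assert sp.k == community.species[idx].k
            assert n0 == community.n0[idx]

    def test_single_species_rejected(self):
        comm = random_community(np.random.default_rng(0), 1)
        with pytest.raises(ParameterError):
            pairwise_matchups(comm)


class TestGeneration:
    def test_counting_contract(self, community):
        spec = ScenarioSpec(base_community=community, n_draws=10)
        scenarios = generate_scenarios(spec)
        assert len(scenarios) == 3 * 10 + 3
        axes = {sid.split("-")[0] for sid, _ in scenarios}
        assert axes == {"skew", "spacing", "norm", "pair"}

    def test_seeded_determinism(self, community):
        spec = ScenarioSpec(base_community=community, n_draws=5, seed=11)
        a = generate_scenarios(spec)
        b = generate_scenarios(spec)
        assert [sid for sid, _ in a] == [sid for sid, _ in b]
        for (_, ca), (_, cb) in zip(a, b):
            for sa, sb in zip(ca.species, cb.species):
                assert sa.curve.params == sb.curve.params

    def test_different_seed_different_draws(self, community):
        a = generate_scenarios(ScenarioSpec(base_community=community, seed=1))
        b = generate_scenarios(ScenarioSpec(base_community=community, seed=2))
        pa = a[0][1].species[0].curve.params
        pb = b[0][1].species[0].curve.params
        assert pa != pb

    def test_skew_draws_hit_target_and_preserve_breadth_and_opt(self, community):
        spec = ScenarioSpec(base_community=community, skew_range=(0.2, 0.2), n_draws=1)
        skew_comm = dict(generate_scenarios(spec))["skew-00"]
        for base_sp, sp in zip(community.species, skew_comm.species):
            assert skewness_metric(sp.curve) == pytest.approx(0.2, rel=1e-9)
            assert sp.curve.params.t_opt == base_sp.curve.params.t_opt
            base_w = base_sp.curve.params.t_max - base_sp.curve.params.t_min
            w = sp.curve.params.t_max - sp.curve.params.t_min
            assert w == pytest.approx(base_w, rel=1e-9)

    def test_spacing_draw_of_5_centers_optima_at_32_37_42(self, community):
        spec = ScenarioSpec(
            base_community=community, spacing_range=(5.0, 5.0), n_draws=1
        )
        spaced = dict(generate_scenarios(spec))["spacing-00"]
        opts = sorted(s.curve.params.t_opt for s in spaced.species)
        assert opts == pytest.approx([32.0, 37.0, 42.0], abs=1e-9)
        # rigid shift preserves skewness
        for base_sp, sp in zip(community.species, spaced.species):
            assert skewness_metric(sp.curve) == pytest.approx(
                skewness_metric(base_sp.curve), rel=1e-9
            )

    def test_normalization_axis_rescales_to_common_peak(self, community):
        spec = ScenarioSpec(base_community=community, normalize=True, n_draws=2)
        for sid, comm in generate_scenarios(spec):
            if sid.startswith("norm"):
                for sp in comm.species:
                    assert sp.curve.params.r_peak == pytest.approx(1.0)

    def test_unnormalized_axis_keeps_drawn_peaks(self, community):
        spec = ScenarioSpec(base_community=community, normalize=False, n_draws=3)
        peaks = [
            sp.curve.params.r_peak
            for sid, comm in generate_scenarios(spec)
            if sid.startswith("norm")
            for sp in comm.species
        ]
        assert len(set(round(p, 12) for p in peaks)) > 1
        assert all(0.5 <= p <= 2.0 for p in peaks)

    def test_invalid_spec_rejected(self, community):
        with pytest.raises(ParameterError):
            ScenarioSpec(base_community=community, n_draws=0)
        with pytest.raises(ParameterError):
            ScenarioSpec(base_community=community, spacing_range=(0.0, 1.0))
        with pytest.raises(ParameterError):
            ScenarioSpec(base_community=community, subset_sizes=(2, 5))


class TestRobustness:
    def test_empty_scenario_list_rejected(self):
        with pytest.raises(ParameterError):
            evaluate_robustness([])

    def test_default_ranges_all_flags_hold_coarse(self, community):
        """Reasonable skew/spacing variation preserves the hand-over pattern."""
        spec = ScenarioSpec(base_community=community, n_draws=3, seed=5)
        summary = evaluate_robustness(generate_scenarios(spec), step=0.5)
        assert summary.n_failed == 0
        assert summary.n_monotone == summary.n_scenarios
        assert summary.n_intermediate_persists == summary.n_scenarios
        assert summary.n_tied == 0

    def test_degenerate_spacing_produces_ties(self, community):
        """Near-identical optima are flagged as non-informative ties."""
        spec = ScenarioSpec(
            base_community=community,
            spacing_range=(0.0005, 0.005),
            subset_sizes=(3,),
            n_draws=4,
            seed=0,
        )
        scenarios = [s for s in generate_scenarios(spec) if s[0].startswith("spacing")]
        summary = evaluate_robustness(scenarios, step=0.5)
        assert summary.n_tied >= 1

    def test_extreme_spacing_breaks_complete_handover(self, community):
        """Optima spread so far apart that the cold species never grows in-grid."""
        spec = ScenarioSpec(
            base_community=community,
            spacing_range=(17.5, 20.0),
            subset_sizes=(3,),
            n_draws=2,
            seed=0,
        )
        scenarios = [s for s in generate_scenarios(spec) if s[0].startswith("spacing")]
        summary = evaluate_robustness(scenarios, step=0.5)
        assert summary.n_complete < summary.n_scenarios

    def test_pairwise_winner_has_higher_growth_rate(self, community):
        """Two-species outcomes never contradict the growth-rate ranking."""
        from thermolv import growth_rate, run_temperature_sweep

        for pair in pairwise_matchups(community):
            sweep = run_temperature_sweep(pair, 30.0, 40.0, 1.0)
            for i, T in enumerate(sweep.grid):
                rates = pair.rates_at(float(T))
                if np.all(rates > 0):
                    assert sweep.dominant[i] == pair.ids[int(np.argmax(rates))]

    def test_summary_reproducible_bit_for_bit(self, community):
        spec = ScenarioSpec(
            base_community=community, n_draws=2, subset_sizes=(3,), seed=9
        )
        a = evaluate_robustness(generate_scenarios(spec), step=1.0)
        b = evaluate_robustness(generate_scenarios(spec), step=1.0)
        assert a == b
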