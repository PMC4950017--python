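"""Logit-linear extra-pair event drawing and paternity permutation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedbias import (EppScenario, assign_epy, draw_ep_events,
                     ep_selection_gradient, pair_weights, permute_paternity,
                     simulate_trait, structure_summary)
from pedbias.theory import compute_bias_statistics


class TestPairWeights:
    def test_uniform_case_two_males(self):
        w = pair_weights(["a", "b"], {"a": 0.3, "b": -1.2},
                         EppScenario("i", beta=0.0))
        assert w.loc["a", "b"] == pytest.approx(0.5)
        assert w.loc["b", "a"] == pytest.approx(0.5)
        assert w.loc["a", "a"] == 0.0

    def test_scenario_i_log_four_gives_one_to_four_odds(self):
        w = pair_weights(["lo", "hi"], {"lo": 0.0, "hi": 1.0},
                         EppScenario("i", beta=np.log(4.0)))
        assert w.loc["lo", "hi"] == pytest.approx(0.2)
        assert w.loc["hi", "lo"] == pytest.approx(0.8)

    @pytest.mark.parametrize("sid", ["i", "ii", "iii", "iv", "v"])
    def test_normalization_to_machine_precision(self, sid):
        rng = np.random.default_rng(3)
        ids = [f"m{k}" for k in range(40)]
        z = dict(zip(ids, rng.standard_normal(40)))
        xy = {i: tuple(rng.uniform(0, 1000, 2)) for i in ids}
        w = pair_weights(ids, z, EppScenario(sid, beta=0.7, lam=-0.01),
                         locations=xy)
        assert abs(w.to_numpy().sum() - 1.0) < 1e-12

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(shift=st.floats(-5, 5),
           sid=st.sampled_from(["iii", "iv", "v"]),
           seed=st.integers(0, 100))
    def test_difference_scenarios_translation_invariant(self, shift, sid, seed):
        rng = np.random.default_rng(seed)
        ids = [f"m{k}" for k in range(8)]
        z = rng.standard_normal(8)
        sc = EppScenario(sid, beta=0.9)
        w1 = pair_weights(ids, dict(zip(ids, z)), sc)
        w2 = pair_weights(ids, dict(zip(ids, z + shift)), sc)
        np.testing.assert_allclose(w1.to_numpy(), w2.to_numpy(), atol=1e-12)

    def test_missing_locations_rejected_when_distance_matters(self):
        with pytest.raises(ValueError, match="locations"):
            pair_weights(["a", "b"], {"a": 0.0, "b": 1.0},
                         EppScenario("i", beta=0.1, lam=-0.01))

    def test_overflowing_weights_suggest_rescaling(self):
        with pytest.raises(ValueError, match="rescale"):
            pair_weights(["a", "b"], {"a": 0.0, "b": 1e308},
                         EppScenario("i", beta=10.0))


class TestAssignEpy:
    def test_single_offspring_certain(self):
        assert assign_epy(["o1"], 0.0, seed=0) == frozenset({"o1"})

    def test_no_additional_young(self):
        for s in range(20):
            assert len(assign_epy(list("abcd"), 0.0, seed=s)) == 1

    def test_whole_brood_with_certainty(self):
        assert assign_epy(list("abcd"), 1.0, seed=0) == frozenset("abcd")


def uniform_weights(males):
    n = len(males)
    w = np.ones((n, n)) - np.eye(n)
    return pd.DataFrame(w / w.sum(), index=males, columns=males)


class TestDrawEpEvents:
    BROODS = {"a": ("Ba", ["oa"]), "b": ("Bb", ["ob"]), "c": ("Bc", ["oc"])}

    def test_zero_events(self):
        assert draw_ep_events(uniform_weights(list("abc")), 0,
                              self.BROODS, 0) == []

    def test_exhaustion_cuckolds_every_father_once(self):
        ev = draw_ep_events(uniform_weights(list("abc")), 3, self.BROODS, 1)
        assert sorted(e.social_father for e in ev) == ["a", "b", "c"]
        assert all(e.extra_pair_male != e.social_father for e in ev)

    def test_too_many_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            draw_ep_events(uniform_weights(list("abc")), 4, self.BROODS, 0)

    def test_uniform_sampling_distribution(self):
        # beta = lambda = 0: each of the 6 ordered pairs has probability 1/6
        rng = np.random.default_rng(0)
        w = uniform_weights(list("abc"))
        counts = {}
        n = 30000
        for _ in range(n):
            e = draw_ep_events(w, 1, self.BROODS, rng)[0]
            key = (e.extra_pair_male, e.social_father)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 6) < 4 * se


class TestPermutePaternity:
    def test_zero_events_is_identity(self, small_population, small_trait):
        ped = small_population.social
        genetic, tr2, events = permute_paternity(
            ped, small_trait, EppScenario("i", 0.0), {}, 0.5, seed=0)
        assert events == []
        np.testing.assert_array_equal(tr2.z, small_trait.z)
        np.testing.assert_array_equal(genetic.genetic_sire_idx,
                                      ped.social_sire_idx)

    def test_no_social_father_in_two_events(self, small_population,
                                            small_trait):
        pop = small_population
        _, _, events = permute_paternity(
            pop.social, small_trait, EppScenario("iv", 1.6, pop.config.lambda_ref),
            pop.n_events_per_year, pop.p_additional, seed=1)
        fathers = [e.social_father for e in events]
        assert len(fathers) == len(set(fathers))

    def test_epy_fraction_tracks_reference_rate(self, small_population):
        pop = small_population
        n_off = sum(1 for i in pop.social if i.social_sire_id is not None)
        fracs = []
        for s in range(30):
            tr = simulate_trait(pop.social, "social", 0.5, seed=300 + s)
            genetic, _, events = permute_paternity(
                pop.social, tr, EppScenario("ii", 0.4, pop.config.lambda_ref),
                pop.n_events_per_year, pop.p_additional, seed=400 + s)
            epy = sum(len(e.reassigned_offspring) for e in events)
            fracs.append(epy / n_off)
        target = pop.config.epy_rate
        se = np.sqrt(target * (1 - target) / n_off) / np.sqrt(30)
        # event count is conditioned on the reference; only within-event
        # additional-young sampling varies
        assert abs(np.mean(fracs) - target) < 0.02

    def test_null_epm_choice_independent_of_father_phenotype(
            self, small_population):
        pop = small_population
        slopes = []
        for s in range(100):
            tr = simulate_trait(pop.social, "social", 0.5, seed=600 + s)
            genetic, tr2, events = permute_paternity(
                pop.social, tr, EppScenario("i", 0.0, pop.config.lambda_ref),
                pop.n_events_per_year, pop.p_additional, seed=700 + s)
            z = tr2.z_map()
            zf = np.array([z[e.social_father] for e in events])
            ze = np.array([z[e.extra_pair_male] for e in events])
            slopes.append(np.polyfit(zf, ze, 1)[0])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 2 * se + 0.02

    def test_scenario_v_raises_epm_father_similarity(self, small_population):
        pop = small_population
        def mean_beta_e_z(beta, seeds):
            vals = []
            for s in seeds:
                tr = simulate_trait(pop.social, "social", 0.5, seed=s)
                genetic, tr2, _ = permute_paternity(
                    pop.social, tr,
                    EppScenario("v", beta, pop.config.lambda_ref),
                    pop.n_events_per_year, pop.p_additional, seed=s + 1)
                st = compute_bias_statistics(pop.social, genetic, tr2)
                vals.append(st.beta_e_z)
            return np.mean(vals)
        seeds = range(2000, 2060)
        assert mean_beta_e_z(1.6, seeds) > mean_beta_e_z(0.0, seeds)

    def test_structure_preserved_under_null_permutation(self, small_population):
        # trait-independent permutations conditioned on the reference pedigree
        # leave every paternity-structure count consistent with the observed
        # genetic pedigree (the permutation changes links, not structure)
        pop = small_population
        ref = structure_summary(pop.genetic, "genetic",
                                reference=pop.social).as_dict()
        dists = {k: [] for k in ref}
        for s in range(100):
            tr = simulate_trait(pop.social, "social", 0.5, seed=5000 + s)
            genetic, _, _ = permute_paternity(
                pop.social, tr, EppScenario("i", 0.0, pop.config.lambda_ref),
                pop.n_events_per_year, pop.p_additional, seed=5100 + s)
            s_perm = structure_summary(genetic, "genetic",
                                       reference=pop.social).as_dict()
            for k, v in s_perm.items():
                dists[k].append(v)
        for k, obs in ref.items():
            lo, hi = np.percentile(dists[k], [2.5, 97.5])
            assert lo <= obs <= hi, (k, obs, lo, hi)


class TestSelectionGradientEquivalence:
    """The strength parameter acts as a standardized selection gradient."""

    @staticmethod
    def run(scenario_id, beta, n_males=300, n_events=90, reps=40):
        rng = np.random.default_rng(12345)
        grads = []
        ids = [f"m{k}" for k in range(n_males)]
        broods = {i: (f"B{i}", [f"o{i}"]) for i in ids}
        for _ in range(reps):
            z = dict(zip(ids, rng.standard_normal(n_males)))
            w = pair_weights(ids, z, EppScenario(scenario_id, beta))
            ev = draw_ep_events(w, n_events, broods, rng)
            grads.append(ep_selection_gradient(ev, z, ids))
        return float(np.mean(grads))

    @pytest.mark.parametrize("beta", [0.1, 0.2, 0.4])
    def test_scenario_i_gradient_matches_beta(self, beta):
        assert abs(self.run("i", beta) - beta) < 0.1

    @pytest.mark.parametrize("beta", [0.1, 0.2, 0.4])
    def test_scenario_iii_gradient_is_twice_beta(self, beta):
        assert abs(self.run("iii", beta) - 2 * beta) < 0.1
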