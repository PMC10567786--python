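"""Likelihood, fitting, goodness of fit and standard errors."""

import numpy as np
import pytest

import lineup2ht as l2
from lineup2ht.model import category_probabilities


def counts(label, cp, ca):
    return l2.ResponseCounts(label, *cp, *ca)


def closed_form_mle(rc):
    """Moment estimator of the b = dA = 0 sub-model, which equals the MLE:
    g from the CA selection rate, dP from the CP rejection rate."""
    g = (rc.ca_suspect + rc.ca_filler) / rc.ca_total
    dP = 1.0 - rc.cp_reject / (rc.cp_total * (1.0 - g))
    return dP, g


class TestLogLikelihood:
    def test_all_zero_counts_give_zero(self, guessing_only_spec):
        data = [counts("a", (0, 0, 0), (0, 0, 0))]
        assert l2.log_likelihood(guessing_only_spec, data, [0.4, 0.3]) == 0.0

    def test_certain_categories_give_zero(self, guessing_only_spec):
        # dP=1 puts all CP mass on suspect; g=... irrelevant for CP; choose
        # CA counts 0 so only the certain CP category contributes: 10*log 1
        data = [counts("a", (10, 0, 0), (0, 0, 0))]
        assert l2.log_likelihood(guessing_only_spec, data, [1.0, 0.3]) == 0.0

    def test_hand_computed_value(self, guessing_only_spec):
        # g=1, c=1/3: CA probabilities (1/3, 2/3, 0); CP identical with dP=0.
        # counts 5/5/0 on (1/3,2/3,0) per tree: 5 ln(1/3) + 5 ln(2/3) each.
        data = [counts("a", (5, 5, 0), (5, 5, 0))]
        want = 2 * (5 * np.log(1 / 3) + 5 * np.log(2 / 3))
        got = l2.log_likelihood(guessing_only_spec, data, [0.0, 1.0])
        assert got == pytest.approx(want, abs=1e-10)

    def test_impossible_count_gives_minus_inf(self, guessing_only_spec):
        # g=0 makes selections impossible; a positive filler count clashes
        data = [counts("a", (0, 3, 7), (0, 0, 10))]
        assert l2.log_likelihood(guessing_only_spec, data, [0.0, 0.0]) == -np.inf

    def test_missing_condition_rejected(self, exp1):
        spec, data = exp1
        with pytest.raises(ValueError, match="mismatch"):
            l2.log_likelihood(spec, data[:-1], np.full(spec.n_free, 0.5))
        with pytest.raises(ValueError, match="duplicate"):
            l2.log_likelihood(spec, data + [data[0]], np.full(spec.n_free, 0.5))


class TestFit:
    def test_self_consistency_on_model_generated_counts(self, exp1):
        """Counts manufactured as rounded expected counts at known parameters
        are recovered nearly exactly, with G^2 near 0."""
        spec, _ = exp1
        truth = np.array([0.45, 0.3, 0.5, 0.35, 0.35, 0.55, 0.2, 0.4, 0.08, 0.12])
        per_cond = l2.expand_parameters(spec, truth)
        n = 200_000
        data = []
        for cond in spec.conditions:
            p = category_probabilities(per_cond[cond.label], cond.sampling_constant)
            cp = [round(n * v) for v in p.cp]
            ca = [round(n * v) for v in p.ca]
            cp[2] = n - cp[0] - cp[1]
            ca[2] = n - ca[0] - ca[1]
            data.append(counts(cond.label, cp, ca))
        res = l2.fit(spec, data, l2.FitOptions(n_starts=3))
        np.testing.assert_allclose(res.free_values, truth, atol=1e-4)
        assert res.g_squared < 0.01

    def test_closed_form_sub_model_matches_optimizer(self, guessing_only_spec):
        """On counts consistent with the b = dA = 0 sub-model the moment
        estimator (g from the CA selection rate, dP from the CP rejection
        rate) is the MLE; the optimizer must land on it.  With dP=0.6, g=0.4,
        c=1/3 and tree totals 750 every expected count is an integer."""
        data = [counts("a", (490, 80, 180), (100, 200, 450))]
        res = l2.fit(guessing_only_spec, data, l2.FitOptions(n_starts=5))
        dP, g = closed_form_mle(data[0])
        assert (dP, g) == (0.6, 0.4)
        assert res.estimates["dP"] == pytest.approx(dP, abs=1e-6)
        assert res.estimates["g"] == pytest.approx(g, abs=1e-6)
        assert res.g_squared == pytest.approx(0.0, abs=1e-8)

    def test_grid_search_never_beats_optimizer_2param(self, guessing_only_spec):
        """Dense 0.001-step grid over (dP, g) as an independent oracle."""
        data = [counts("a", (130, 40, 30), (22, 48, 130))]
        res = l2.fit(guessing_only_spec, data)
        # independent vectorized likelihood written from the tree definition
        dP, g = np.meshgrid(
            np.arange(0.001, 1.0, 0.001), np.arange(0.001, 1.0, 0.001), indexing="ij"
        )
        c = 1 / 3
        cp = np.stack(
            [dP + (1 - dP) * g * c, (1 - dP) * g * (1 - c), (1 - dP) * (1 - g)]
        )
        ca = np.stack([g * c, g * (1 - c), 1 - g])
        obs = data[0].as_array()
        ll = sum(obs[i] * np.log(cp[i]) for i in range(3))
        ll += sum(obs[3 + i] * np.log(ca[i]) for i in range(3))
        assert ll.max() <= res.log_likelihood + 1e-4

    def test_grid_search_never_beats_optimizer_3param(self):
        """Three free parameters: coarse grid with local refinement."""
        cond = l2.LineupCondition("a", "sequential", 3, n_participants=100)
        spec = l2.ModelSpec(
            conditions=(cond,),
            restrictions={
                ("dP", "a"): "dP",
                ("dA", "a"): "dA",
                ("g", "a"): "g",
                ("b", "a"): 0.0,
            },
            free_parameter_names=("dP", "dA", "g"),
        )
        data = [counts("a", (120, 50, 30), (30, 60, 110))]
        res = l2.fit(spec, data)
        obs = data[0].as_array()
        c = 1 / 3

        def ll_grid(dP, dA, g):
            cp = [dP + (1 - dP) * g * c, (1 - dP) * g * (1 - c), (1 - dP) * (1 - g)]
            ca = [(1 - dA) * g * c, (1 - dA) * g * (1 - c), dA + (1 - dA) * (1 - g)]
            out = 0.0
            for i in range(3):
                out += obs[i] * np.log(np.maximum(cp[i], 1e-300))
                out += obs[3 + i] * np.log(np.maximum(ca[i], 1e-300))
            return out

        coarse = np.arange(0.01, 1.0, 0.01)
        dP, dA, g = np.meshgrid(coarse, coarse, coarse, indexing="ij")
        vals = ll_grid(dP, dA, g)
        k = np.unravel_index(np.argmax(vals), vals.shape)
        center = np.array([coarse[k[0]], coarse[k[1]], coarse[k[2]]])
        fine = [np.clip(center[i] + np.arange(-0.01, 0.011, 0.001), 0.001, 0.999) for i in range(3)]
        dP, dA, g = np.meshgrid(*fine, indexing="ij")
        best = max(vals[k], ll_grid(dP, dA, g).max())
        assert best <= res.log_likelihood + 1e-4

    def test_condition_and_category_permutation_invariance(self, exp1):
        spec, data = exp1
        base = l2.fit(spec, data, l2.FitOptions(n_starts=3))
        # permute condition order in both spec and data
        perm = [2, 0, 3, 1]
        spec_p = l2.ModelSpec(
            conditions=tuple(spec.conditions[i] for i in perm),
            restrictions=spec.restrictions,
            free_parameter_names=spec.free_parameter_names,
        )
        res = l2.fit(spec_p, [data[i] for i in reversed(perm)], l2.FitOptions(n_starts=3))
        assert res.g_squared == pytest.approx(base.g_squared, abs=1e-6)
        for name in spec.free_parameter_names:
            assert res.estimates[name] == pytest.approx(base.estimates[name], abs=1e-5)

    def test_multistart_stability_on_study_data(self, exp1, exp2):
        """20 random restarts land on the same optimum for both datasets."""
        for spec, data in (exp1, exp2):
            a = l2.fit(spec, data, l2.FitOptions(n_starts=20, seed=11))
            b = l2.fit(spec, data, l2.FitOptions(n_starts=20, seed=99))
            assert a.g_squared == pytest.approx(b.g_squared, abs=1e-6)
            assert a.n_starts_agreeing >= 18

    def test_expected_counts_preserve_tree_totals(self, exp1_base_fit, exp1):
        _, data = exp1
        by_label = {rc.condition_label: rc for rc in data}
        for label, row in exp1_base_fit.expected_counts.items():
            assert row[:3].sum() == pytest.approx(by_label[label].cp_total, abs=1e-6)
            assert row[3:].sum() == pytest.approx(by_label[label].ca_total, abs=1e-6)

    def test_g_squared_equals_twice_loglik_gap_to_saturated(self, exp1_base_fit, exp1):
        _, data = exp1
        ll_sat = 0.0
        for rc in data:
            arr = rc.as_array()
            for tree in (arr[:3], arr[3:]):
                ll_sat += (tree * np.log(tree / tree.sum())).sum()
        want = 2 * (ll_sat - exp1_base_fit.log_likelihood)
        assert exp1_base_fit.g_squared == pytest.approx(want, abs=1e-8)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_empty_tree_rejected(self, guessing_only_spec):
        with pytest.raises(ValueError, match="tree totals"):
            l2.fit(guessing_only_spec, [counts("a", (0, 0, 0), (1, 2, 3))])

    def test_totals_warning_against_participant_count(self):
        cond = l2.LineupCondition("a", "sequential", 3, n_participants=50)
        spec = l2.ModelSpec(
            conditions=(cond,),
            restrictions={
                ("dP", "a"): "dP",
                ("g", "a"): "g",
                ("b", "a"): 0.0,
                ("dA", "a"): 0.0,
            },
        )
        data = [counts("a", (40, 30, 29), (20, 30, 50))]  # 99 != 2*50
        with pytest.warns(UserWarning, match="tree totals"):
            l2.fit(spec, data, l2.FitOptions(n_starts=1))


class TestStandardErrors:
    def test_doubling_counts_shrinks_se_by_sqrt2(self, exp1):
        spec, data = exp1
        doubled = [
            l2.ResponseCounts(rc.condition_label, *(2 * v for v in (
                rc.cp_suspect, rc.cp_filler, rc.cp_reject,
                rc.ca_suspect, rc.ca_filler, rc.ca_reject,
            )))
            for rc in data
        ]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)  # totals no longer match n
            res1 = l2.fit(spec, data, l2.FitOptions(n_starts=3))
            res2 = l2.fit(spec, doubled, l2.FitOptions(n_starts=3))
        for name in spec.free_parameter_names:
            ratio = res1.standard_errors[name] / res2.standard_errors[name]
            assert ratio == pytest.approx(np.sqrt(2), rel=0.01)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_boundary_estimate_flagged_undefined(self, guessing_only_spec):
        # counts that push dP to the ceiling: no CP rejections at all and a
        # CA profile forcing g toward the CP selection mix
        data = [counts("a", (100, 0, 0), (30, 60, 10))]
        res = l2.fit(guessing_only_spec, data)
        assert res.estimates["dP"] > 1 - 1e-4
        assert np.isnan(res.standard_errors["dP"])
        assert np.isfinite(res.standard_errors["g"])
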