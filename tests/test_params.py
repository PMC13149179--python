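"""Hybrid CPT construction operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periobn.network import Cpt, NetworkError
from periobn.params import (
    CountTable,
    RankedNodeSpec,
    bias_resample,
    combine_expert_tables,
    composite_prior,
    count_table_from_cohort,
    expand_coarse_cpt,
    fuse_dataset_counts,
    marginal_data_prior,
    parse_ratio,
    posterior_cpt,
    ranked_cpt,
    uniform_prior,
)

B = ("False", "True")


def _cpt(values, node="X", parents=(), parent_states=None):
    return Cpt(node, B, parents, parent_states or {}, values)


def _counts(values, node="X", parents=(), parent_states=None, prov=""):
    return CountTable(node, B, parents, parent_states or {}, values, prov)


class TestRatioAndUniform:
    def test_parse_ratio(self):
        assert parse_ratio("1:20") == (1.0, 20.0)
        assert parse_ratio("1.5:1") == (1.5, 1.0)
        assert parse_ratio("15:1:2") == (15.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            parse_ratio("5")

    def test_uniform_rows(self):
        cpt = uniform_prior("X", B)
        np.testing.assert_allclose(cpt.flat(), [0.5, 0.5])
        cpt3 = uniform_prior(
            "Y", ("a", "b", "c"), ("P",), {"P": B}
        )
        assert cpt3.values.shape == (2, 3)
        np.testing.assert_allclose(cpt3.values, 1 / 3)


class TestExpertCombination:
    def test_mean_of_two_experts(self):
        merged = combine_expert_tables(
            [_cpt([0.60, 0.40]), _cpt([0.65, 0.35])]
        )
        np.testing.assert_allclose(merged.flat(), [0.625, 0.375])

    def test_single_expert_identity(self):
        one = _cpt([0.2, 0.8])
        np.testing.assert_allclose(
            combine_expert_tables([one]).flat(), one.flat()
        )

    def test_three_experts_match_direct_average(self, rng):
        rows = rng.dirichlet(np.ones(3), size=3)
        tables = [
            Cpt("X", ("a", "b", "c"), (), {}, r) for r in rows
        ]
        merged = combine_expert_tables(tables)
        expected = rows.mean(axis=0)
        expected = expected / expected.sum()
        np.testing.assert_allclose(merged.flat(), expected, atol=1e-12)

    def test_signature_mismatch(self):
        other = Cpt("Y", B, (), {}, [0.5, 0.5])
        with pytest.raises(NetworkError, match="signature"):
            combine_expert_tables([_cpt([0.5, 0.5]), other])

    @given(st.permutations(range(3)))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm):
        rows = [[0.1, 0.9], [0.4, 0.6], [0.7, 0.3]]
        tables = [_cpt(rows[i]) for i in range(3)]
        base = combine_expert_tables(tables).flat()
        shuffled = combine_expert_tables([tables[i] for i in perm]).flat()
        np.testing.assert_allclose(base, shuffled, atol=1e-12)


class TestCompositePrior:
    def test_degenerate_weight(self):
        a, b = _cpt([0.8, 0.2]), _cpt([0.2, 0.8])
        np.testing.assert_allclose(
            composite_prior([(a, 1.0), (b, 0.0)]).flat(), a.flat()
        )

    def test_identical_components(self):
        a = _cpt([0.3, 0.7])
        np.testing.assert_allclose(
            composite_prior([(a, 2.0), (a, 5.0)]).flat(), a.flat()
        )

    def test_weighted_mixture(self):
        a, b = _cpt([0.8, 0.2]), _cpt([0.2, 0.8])
        np.testing.assert_allclose(
            composite_prior([(a, 5.0), (b, 1.0)]).flat(), [0.7, 0.3]
        )


class TestExpandCoarse:
    def _coarse(self):
        # coarse parent: risk group Low/High
        return Cpt(
            "X", B, ("G",), {"G": ("Low", "High")}, [[0.9, 0.1], [0.4, 0.6]]
        )

    def test_piecewise_constant_expansion(self):
        fine = expand_coarse_cpt(
            self._coarse(),
            {"G": ("b1", "b2", "b3")},
            {"G": {"b1": "Low", "b2": "High", "b3": "High"}},
        )
        np.testing.assert_allclose(fine.values[0], [0.9, 0.1])
        np.testing.assert_allclose(fine.values[1], [0.4, 0.6])
        np.testing.assert_allclose(fine.values[2], [0.4, 0.6])

    def test_identity_map_unchanged(self):
        coarse = self._coarse()
        fine = expand_coarse_cpt(
            coarse, {"G": ("Low", "High")},
            {"G": {"Low": "Low", "High": "High"}},
        )
        np.testing.assert_allclose(fine.values, coarse.values)

    def test_ordinal_interpolation_midpoint(self):
        # 5 fine states; categories centred at indices 0.5 and 3.5; the
        # fine state at index 2 sits exactly between -> average row
        fine_states = tuple(f"f{i}" for i in range(5))
        mapping = {"f0": "Low", "f1": "Low", "f2": "Low",
                   "f3": "High", "f4": "High"}
        # centres: Low at mean(0,1,2)=1, High at mean(3,4)=3.5 -> f2 not mid
        # use a symmetric map instead
        mapping = {"f0": "Low", "f1": "Low", "f2": "High", "f3": "High",
                   "f4": "High"}
        # centres: Low=0.5, High=3.0; midpoint index 1.75 is not a state.
        # Simplest exact case: two fine states per category, middle state
        # equidistant.
        fine_states = ("f0", "f1", "f2", "f3", "f4")
        mapping = {"f0": "Low", "f1": "Low", "f2": "Low", "f3": "High",
                   "f4": "High"}
        fine = expand_coarse_cpt(
            self._coarse(), {"G": fine_states}, {"G": mapping},
            interpolate=("G",),
        )
        # centres: Low at 1.0, High at 3.5; f2 at weight (2-1)/(3.5-1)=0.4
        expected = 0.6 * np.array([0.9, 0.1]) + 0.4 * np.array([0.4, 0.6])
        np.testing.assert_allclose(fine.values[2], expected)
        # states at or beyond the centres are constant
        np.testing.assert_allclose(fine.values[0], [0.9, 0.1])
        np.testing.assert_allclose(fine.values[4], [0.4, 0.6])

    def test_unmapped_state_raises(self):
        with pytest.raises(NetworkError, match="unmapped"):
            expand_coarse_cpt(
                self._coarse(), {"G": ("b1", "b2")}, {"G": {"b1": "Low"}}
            )


class TestFuseCounts:
    def test_identity(self):
        t = _counts([30, 10])
        out = fuse_dataset_counts([(t, 1.0)])
        np.testing.assert_allclose(out.counts, t.counts)

    def test_equal_datasets(self):
        t1, t2 = _counts([30, 10]), _counts([30, 10])
        out = fuse_dataset_counts([(t1, 1.0), (t2, 1.0)])
        np.testing.assert_allclose(out.counts, [60, 20])

    def test_one_to_twenty_mass_share(self):
        q = _counts([100, 100], prov="questionnaire")
        e = _counts([1000, 0], prov="ehr")
        out = fuse_dataset_counts([(q, 1.0), (e, 20.0)])
        # EHR carries 20/21 of the combined 1,200 mass
        np.testing.assert_allclose(out.total, 1200.0)
        np.testing.assert_allclose(
            out.counts[1] / out.total, (1 / 21) * 0.5, atol=1e-12
        )


class TestPosterior:
    def test_zero_data_weight_returns_prior(self):
        prior = _cpt([0.5, 0.5])
        post = posterior_cpt(prior, _counts([30, 10]), (1.0, 0.0))
        np.testing.assert_allclose(post.flat(), prior.flat())

    def test_ml_limit(self):
        prior = _cpt([0.5, 0.5])
        post = posterior_cpt(prior, _counts([30, 10]), (1e-12, 1.0))
        np.testing.assert_allclose(post.flat(), [0.75, 0.25], atol=1e-9)

    def test_one_to_one_pseudo_counts(self):
        prior = _cpt([0.5, 0.5])
        post = posterior_cpt(prior, _counts([30, 10]), (1.0, 1.0))
        np.testing.assert_allclose(post.flat(), [0.625, 0.375])

    def test_empty_row_returns_prior_row(self):
        prior = Cpt("X", B, ("P",), {"P": B}, [[0.9, 0.1], [0.3, 0.7]])
        counts = _counts([[0, 0], [5, 15]], parents=("P",), parent_states={"P": B})
        post = posterior_cpt(prior, counts, (1.0, 4.0))
        np.testing.assert_allclose(post.values[0], [0.9, 0.1])

    def test_consistency_as_counts_grow(self):
        prior = _cpt([0.5, 0.5])
        for n in (10, 1000, 100000):
            post = posterior_cpt(prior, _counts([3 * n, n]), (1.0, 10.0))
            # converges to the empirical 0.75 at fixed ratio
            assert abs(post.flat()[0] - (0.75 * 10 + 0.5) / 11) < 1e-9


class TestMarginalDataPrior:
    def test_full_subset_is_plain_normalization(self):
        counts = _counts([[8, 2], [1, 9]], parents=("P",), parent_states={"P": B})
        cpt = marginal_data_prior(counts, ("P",), {"P": B})
        np.testing.assert_allclose(cpt.values, [[0.8, 0.2], [0.1, 0.9]])

    def test_empty_subset_broadcasts_marginal(self):
        counts = _counts([40, 10])
        cpt = marginal_data_prior(counts, ("P",), {"P": B})
        np.testing.assert_allclose(cpt.values, [[0.8, 0.2], [0.8, 0.2]])

    def test_projection_constant_over_unobserved_parent(self):
        counts = _counts([[8, 2], [1, 9]], parents=("P",), parent_states={"P": B})
        cpt = marginal_data_prior(
            counts, ("P", "Q"), {"P": B, "Q": ("u", "v", "w")}
        )
        for q in range(3):
            np.testing.assert_allclose(cpt.values[0, q], [0.8, 0.2])
            np.testing.assert_allclose(cpt.values[1, q], [0.1, 0.9])

    def test_zero_projection_falls_back_to_uniform(self):
        counts = _counts([[0, 0], [1, 3]], parents=("P",), parent_states={"P": B})
        cpt = marginal_data_prior(counts, ("P",), {"P": B})
        np.testing.assert_allclose(cpt.values[0], [0.5, 0.5])


class TestBiasResample:
    def _inverse(self, eps):
        # P(observed | true) rows indexed by true state
        return Cpt(
            "obs", B, ("X",), {"X": B},
            [[1 - eps, eps], [eps, 1 - eps]],
        )

    def test_identity_misclassification(self):
        out = bias_resample(_counts([90, 10]), self._inverse(0.0))
        np.testing.assert_allclose(out.counts, [90, 10])

    def test_symmetric_flip_solves_exactly(self):
        # 0.9a + 0.1b = 90, 0.1a + 0.9b = 10 -> (100, 0), on the boundary
        out = bias_resample(_counts([90, 10]), self._inverse(0.1))
        np.testing.assert_allclose(out.counts, [100, 0], atol=1e-9)

    def test_negative_solution_is_clipped_and_logged(self):
        # observed more extreme than the flip can explain -> x1 < 0
        out = bias_resample(_counts([95, 5]), self._inverse(0.1))
        assert out.clip_events == [()]
        np.testing.assert_allclose(out.counts, [100, 0], atol=1e-9)
        np.testing.assert_allclose(out.counts.sum(), 100.0)

    def test_round_trip_recovers_truth(self, rng):
        """Forward-corrupting true counts then correcting recovers the true
        proportions when no clipping occurs."""
        true = np.array([700.0, 300.0])
        eps = 0.15
        m = np.array([[1 - eps, eps], [eps, 1 - eps]])
        observed = m.T @ true  # expected observed counts
        out = bias_resample(
            _counts(observed), self._inverse(eps)
        )
        np.testing.assert_allclose(out.counts, true, atol=1e-9)
        assert out.clip_events == []

    def test_singular_matrix_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            bias_resample(_counts([5, 5]), self._inverse(0.5))


class TestRankedCpt:
    def _spec(self, weights, thresholds):
        return RankedNodeSpec(
            node="R",
            node_states=("Bad", "Medium", "Good"),
            parents=("P1", "P2"),
            parent_states={
                "P1": ("Bad", "Medium", "Good"),
                "P2": ("Bad", "Medium", "Good"),
            },
            parent_weights=weights,
            parent_scores={
                "P1": {"Bad": 0.0, "Medium": 0.5, "Good": 1.0},
                "P2": {"Bad": 0.0, "Medium": 0.5, "Good": 1.0},
            },
            thresholds=thresholds,
        )

    def test_identity_mapping_single_parent(self):
        spec = RankedNodeSpec(
            node="R", node_states=("Bad", "Medium", "Good"),
            parents=("P",),
            parent_states={"P": ("Bad", "Medium", "Good")},
            parent_weights={"P": 1.0},
            parent_scores={"P": {"Bad": 0.0, "Medium": 0.5, "Good": 1.0}},
            thresholds=(0.25, 0.75),
        )
        cpt = ranked_cpt(spec)
        np.testing.assert_allclose(cpt.values, np.eye(3))

    def test_mixed_parents_hit_middle_level(self):
        cpt = ranked_cpt(self._spec({"P1": 0.5, "P2": 0.5}, (0.34, 0.67)))
        row = cpt.row({"P1": "Good", "P2": "Bad"})  # score 0.5
        np.testing.assert_allclose(row, [0.0, 1.0, 0.0])

    def test_boundary_goes_to_higher_level(self):
        cpt = ranked_cpt(self._spec({"P1": 0.5, "P2": 0.5}, (0.25, 0.75)))
        row = cpt.row({"P1": "Medium", "P2": "Bad"})  # score exactly 0.25
        np.testing.assert_allclose(row, [0.0, 1.0, 0.0])

    def test_monotonicity(self):
        """Improving any parent state never lowers the assigned level."""
        cpt = ranked_cpt(self._spec({"P1": 0.7, "P2": 0.3}, (0.34, 0.67)))
        levels = cpt.values.argmax(axis=-1)
        assert np.all(np.diff(levels, axis=0) >= 0)
        assert np.all(np.diff(levels, axis=1) >= 0)

    def test_softened_rows_are_distributions(self):
        cpt = ranked_cpt(
            self._spec({"P1": 0.5, "P2": 0.5}, (0.34, 0.67)), temperature=0.2
        )
        np.testing.assert_allclose(cpt.values.sum(-1), 1.0, atol=1e-12)
        assert (cpt.values > 0).all()

    def test_bad_thresholds(self):
        with pytest.raises(ValueError, match="ascending"):
            self._spec({"P1": 0.5, "P2": 0.5}, (0.7, 0.3))


class TestCountFromCohort:
    def test_crosstab_matches_pandas(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {
                "P": rng.choice(["False", "True"], 500),
                "X": rng.choice(["False", "True"], 500),
            }
        )
        table = count_table_from_cohort(df, "X", B, ("P",), {"P": B})
        expected = pd.crosstab(df["P"], df["X"])
        np.testing.assert_allclose(
            table.counts, expected.loc[list(B), list(B)].to_numpy()
        )

    def test_unseen_state_raises(self):
        import pandas as pd

        df = pd.DataFrame({"P": ["False"], "X": ["weird"]})
        with pytest.raises(ValueError, match="unseen"):
            count_table_from_cohort(df, "X", B, ("P",), {"P": B})
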