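import numpy as np
import pytest

from eventdep.design_io import ItemMeta, ResponseDataset, order_items
from eventdep.irt_core import (
    GUESS_SIX_AFC,
    ItemParams,
    TraitDistribution,
    UnidimensionalFit,
    response_probability,
)
from eventdep.residual_dependency import (
    Q3Matrix,
    bias_correct,
    dependency,
    dependency_from_fit,
    q3_statistic,
    residual_matrix,
    subset_by_judgement,
)


def _manual_fit(beta, theta, gamma=GUESS_SIX_AFC):
    I, N = len(beta), len(theta)
    return UnidimensionalFit(
        items=ItemParams(
            [f"i{j}" for j in range(I)], np.asarray(beta, float),
            np.ones(I), np.full(I, gamma),
        ),
        trait=TraitDistribution(1.0),
        theta=np.asarray(theta, float),
        person_ids=[f"p{i}" for i in range(N)],
        loglik=0.0,
        converged=True,
        n_iter=1,
    )


class TestResiduals:
    def test_residual_is_observed_minus_probability(self):
        fit = _manual_fit([0.0], [0.0])
        U = np.array([[1.0]])
        expected = 1.0 - response_probability(0.0, 0.0)
        assert residual_matrix(U, fit)[0, 0] == pytest.approx(expected)

    def test_wrong_response_at_chance_gives_minus_gamma(self):
        # theta -> -inf limit approximated with a very hard item
        fit = _manual_fit([40.0], [0.0])
        U = np.array([[0.0]])
        assert residual_matrix(U, fit)[0, 0] == pytest.approx(-1 / 6, abs=1e-9)

    def test_missing_responses_give_missing_residuals(self):
        fit = _manual_fit([0.0, 0.0], [0.0, 0.5])
        U = np.array([[1.0, np.nan], [0.0, 1.0]])
        R = residual_matrix(U, fit)
        assert np.isnan(R[0, 1]) and not np.isnan(R).all()

    def test_mean_residual_near_zero_after_fit(self, li_fit):
        U, fit, _ = li_fit
        R = residual_matrix(U, fit)
        item_means = np.abs(np.nanmean(R, axis=0))
        assert item_means.mean() < 0.01
        assert item_means.max() < 0.04


class TestQ3:
    def test_matches_direct_correlation_oracle(self):
        r1 = np.array([0.2, -0.3, 0.1, -0.1, 0.1])
        r2 = np.array([0.3, -0.2, 0.0, -0.2, 0.1])
        q3 = q3_statistic(np.column_stack([r1, r2]), ["a", "b"], min_persons=2)
        oracle = np.corrcoef(r1, r2)[0, 1]
        assert q3.values[0, 1] == pytest.approx(oracle, abs=1e-12)
        assert q3.values[1, 0] == pytest.approx(oracle, abs=1e-12)

    def test_identical_and_negated_residuals(self):
        r = np.array([0.5, -0.2, 0.1, -0.4, 0.3])
        q3 = q3_statistic(np.column_stack([r, r, -r]), ["a", "b", "c"], min_persons=2)
        assert q3.values[0, 1] == pytest.approx(1.0)
        assert q3.values[0, 2] == pytest.approx(-1.0)

    def test_diagonal_undefined_and_symmetric(self, li_fit):
        U, fit, _ = li_fit
        q3 = q3_statistic(residual_matrix(U, fit), fit.items.item_ids)
        assert np.isnan(np.diagonal(q3.values)).all()
        np.testing.assert_allclose(q3.values, q3.values.T)

    def test_pairs_below_person_threshold_are_undefined(self):
        R = np.full((12, 2), np.nan)
        R[:, 0] = np.linspace(-0.5, 0.5, 12)
        R[:5, 1] = [0.1, -0.2, 0.3, 0.0, -0.1]  # only 5 joint persons
        with pytest.raises(ValueError, match="undefined"):
            q3_statistic(R, ["a", "b"], min_persons=10)


class TestBiasCorrection:
    def test_correction_shifts_by_expected_bias(self):
        values = np.array([[np.nan, -1 / 179], [-1 / 179, np.nan]])
        q3 = Q3Matrix(values=values, item_ids=["a", "b"], corrected=False)
        corrected = bias_correct(q3, n_items=180)
        assert corrected.values[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_two_item_correction_adds_one(self):
        q3 = Q3Matrix(np.array([[np.nan, 0.0], [0.0, np.nan]]), ["a", "b"])
        assert bias_correct(q3).values[0, 1] == pytest.approx(1.0)

    def test_double_correction_is_an_error(self):
        q3 = Q3Matrix(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="already"):
            bias_correct(bias_correct(q3))


def _two_event_meta():
    metas = []
    for e, cond in (("e1", "CL"), ("e2", "CL")):
        for b, (cue, tgt) in enumerate(
            [("animal", "object"), ("object", "location"), ("location", "animal")]
        ):
            metas.append(ItemMeta(f"{e}-{cue}", e, cond, cue, tgt, False, b + 1))
    return order_items(metas)


class TestDependency:
    def test_eq3_arithmetic_on_constant_blocks(self):
        metas = _two_event_meta()
        I = 6
        values = np.full((I, I), 0.02)
        events = [m.event_id for m in metas]
        for j in range(I):
            for k in range(I):
                if events[j] == events[k]:
                    values[j, k] = 0.10
        np.fill_diagonal(values, np.nan)
        q3 = Q3Matrix(values, [m.item_id for m in metas], corrected=True)
        est = dependency(q3, metas)
        assert est.D == pytest.approx(0.08)
        assert (est.K, est.L) == (6, 9)

    def test_equal_means_give_zero(self):
        metas = _two_event_meta()
        values = np.full((6, 6), 0.05)
        np.fill_diagonal(values, np.nan)
        q3 = Q3Matrix(values, [m.item_id for m in metas], corrected=True)
        assert dependency(q3, metas).D == pytest.approx(0.0)

    def test_matches_exhaustive_pair_enumeration(self):
        metas = _two_event_meta()
        rng = np.random.default_rng(8)
        values = rng.normal(0, 0.1, (6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, np.nan)
        q3 = Q3Matrix(values, [m.item_id for m in metas], corrected=True)
        est = dependency(q3, metas)
        # brute force over all 15 unordered pairs
        events = [m.event_id for m in metas]
        within, between = [], []
        for j in range(6):
            for k in range(j + 1, 6):
                (within if events[j] == events[k] else between).append(values[j, k])
        assert est.D == pytest.approx(np.mean(within) - np.mean(between), abs=1e-12)
        assert est.K == len(within) and est.L == len(between)

    def test_uncorrected_matrix_is_rejected(self):
        metas = _two_event_meta()
        q3 = Q3Matrix(np.zeros((6, 6)), [m.item_id for m in metas], corrected=False)
        with pytest.raises(ValueError, match="bias-corrected"):
            dependency(q3, metas)

    def test_unknown_condition_is_an_error(self, li_fit):
        U, fit, ordered = li_fit
        with pytest.raises(ValueError, match="unknown condition"):
            dependency_from_fit(U, fit, ordered, condition="no-such-loop")

    def test_invariant_under_person_relabelling(self, li_fit):
        U, fit, ordered = li_fit
        d1 = dependency_from_fit(U, fit, ordered).D
        rng = np.random.default_rng(4)
        perm = rng.permutation(U.shape[0])
        fit2 = UnidimensionalFit(
            items=fit.items, trait=fit.trait, theta=fit.theta[perm],
            person_ids=[fit.person_ids[i] for i in perm],
            loglik=fit.loglik, converged=True, n_iter=fit.n_iter,
        )
        d2 = dependency_from_fit(U[perm], fit2, ordered).D
        assert d2 == pytest.approx(d1, abs=1e-12)


class TestConditionDependency:
    def test_pair_counts_for_fifteen_event_condition(self):
        # 15 events x 3 items: K = 15 * C(3,2) = 45, L = C(45,2) - 45 = 945
        from eventdep.synthetic_experiment import exp1_design, generate_study

        spec = exp1_design(n_persons=60, seed=9)
        dataset, metas = generate_study(
            spec, variance_by_condition={c: 0.0 for c in spec.conditions}, seed=9
        )
        from eventdep.design_io import to_matrix
        from eventdep.irt_core import fit_matrix

        ordered = order_items(metas)
        U, persons, item_ids = to_matrix(dataset, ordered)
        fit = fit_matrix(U, item_ids, persons, quad_nodes=21, tol=1e-4)
        est = dependency_from_fit(U, fit, ordered, condition="CL")
        assert (est.K, est.L) == (45, 945)

    def test_restriction_on_single_condition_data_is_identity(self, li_fit):
        U, fit, ordered = li_fit
        cl_items = [m for m in ordered if m.condition == "CL"]
        cl_cols = [j for j, m in enumerate(ordered) if m.condition == "CL"]
        sub_fit = UnidimensionalFit(
            items=ItemParams(
                [m.item_id for m in cl_items],
                fit.items.beta[cl_cols], np.ones(len(cl_cols)),
                fit.items.gamma[cl_cols],
            ),
            trait=fit.trait, theta=fit.theta, person_ids=fit.person_ids,
            loglik=fit.loglik, converged=True, n_iter=1,
        )
        d_restricted = dependency_from_fit(
            U[:, cl_cols], sub_fit, cl_items, condition="CL",
            n_items_bias=len(cl_cols),
        )
        d_overall = dependency_from_fit(
            U[:, cl_cols], sub_fit, cl_items, n_items_bias=len(cl_cols)
        )
        assert d_restricted.D == pytest.approx(d_overall.D)


class TestJudgementSubsets:
    def test_matching_subset_is_identity(self, tiny_dataset):
        all_r = tiny_dataset.records.assign(judgement="R")
        ds = ResponseDataset(all_r)
        assert subset_by_judgement(ds, "remember").n_records == ds.n_records

    def test_absent_label_is_an_error(self, tiny_dataset):
        all_r = ResponseDataset(tiny_dataset.records.assign(judgement="R"))
        with pytest.raises(ValueError, match="absent"):
            subset_by_judgement(all_r, "know")

    def test_subset_bookkeeping(self, tiny_dataset):
        n_r = int((tiny_dataset.records["judgement"] == "R").sum())
        assert subset_by_judgement(tiny_dataset, "R").n_records == n_r
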