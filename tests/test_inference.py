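import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from eventdep.design_io import order_items, to_matrix
from eventdep.irt_core import fit_matrix
from eventdep.residual_dependency import dependency_from_fit
# aliased so pytest does not collect the library entry points as tests
from eventdep.inference import (
    add_one_p,
    adjust_pvalues,
    assign_judgements,
    order_conditional_dependency,
    test_dependency_difference as difference_test,
    test_dependency_null as null_test,
)
from eventdep.synthetic_experiment import (
    ANIMACY_CONDITIONS,
    ANIMACY_SCHEME,
    DesignSpec,
    generate_study,
)


class TestAddOneP:
    def test_observed_above_every_null_draw_hits_the_floor(self):
        null = np.linspace(-0.1, 0.1, 99)
        assert add_one_p(null, 0.5, "greater") == pytest.approx(1 / 100)
        assert add_one_p(null, 0.5, "two") == pytest.approx(2 / 100)

    def test_two_tailed_caps_at_one(self):
        assert add_one_p(np.zeros(9), 0.0, "two") == 1.0

    @given(
        draws=st.lists(st.floats(-1, 1), min_size=5, max_size=60),
        obs=st.floats(-2, 2),
    )
    @settings(max_examples=60, deadline=None)
    def test_p_is_never_zero_and_bounded(self, draws, obs):
        for tails in ("greater", "less", "two"):
            p = add_one_p(np.array(draws), obs, tails)
            assert 1 / (len(draws) + 1) <= p <= 1.0


class TestHolm:
    def test_single_p_is_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_two_p_step_down(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.04]), [0.02, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_adjusted_dominate_raw_and_are_monotone(self, p):
        adj = adjust_pvalues(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.2, 1.4])


class TestAssignJudgements:
    def test_degenerate_proportions_label_everything(self, tiny_dataset):
        out = assign_judgements(tiny_dataset, {"R": 1.0, "K": 0.0, "N": 0.0}, seed=1)
        assert set(out.records["judgement"]) == {"R"}

    def test_label_frequencies_track_proportions(self, li_study):
        dataset, _ = li_study
        out = assign_judgements(
            dataset, {"R": 1 / 3, "K": 1 / 3, "N": 1 / 3}, seed=5
        )
        props = out.judgement_proportions()
        for lab in ("R", "K", "N"):
            assert props[lab] == pytest.approx(1 / 3, abs=0.02)

    def test_same_seed_is_deterministic(self, tiny_dataset):
        a = assign_judgements(tiny_dataset, {"R": 0.5, "K": 0.5, "N": 0.0}, seed=3)
        b = assign_judgements(tiny_dataset, {"R": 0.5, "K": 0.5, "N": 0.0}, seed=3)
        assert a.records.equals(b.records)

    def test_malformed_proportions_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            assign_judgements(tiny_dataset, {"R": 0.9, "K": 0.3, "N": 0.0}, seed=0)


class TestNullTest:
    def test_same_seed_same_p(self, li_study):
        dataset, metas = li_study
        kwargs = dict(condition="CL", B=19, seed=42, quad_nodes=21,
                      bootstrap_quad_nodes=13)
        r1 = null_test(dataset, metas, **kwargs)
        r2 = null_test(dataset, metas, **kwargs)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_draws, r2.null_draws)
        assert 1 / 20 <= r1.p <= 1.0

    def test_judgement_bootstrap_path_runs_and_reproduces(self, li_study):
        dataset, metas = li_study
        labelled = assign_judgements(
            dataset, {"R": 0.5, "K": 0.3, "N": 0.2}, seed=8
        )
        kwargs = dict(condition=None, judgement="R", B=5, seed=4,
                      quad_nodes=21, bootstrap_quad_nodes=13, min_persons=5)
        r1 = null_test(labelled, metas, **kwargs)
        r2 = null_test(labelled, metas, **kwargs)
        assert r1.p == r2.p
        assert 1 / 6 <= r1.p <= 1.0


class TestDifferenceTest:
    def test_both_negative_dependencies_are_not_tested(self):
        spec = DesignSpec(
            conditions=dict(ANIMACY_CONDITIONS),
            element_scheme={c: ANIMACY_SCHEME for c in ANIMACY_CONDITIONS},
            events_per_condition=4,
            n_persons=80,
            seed=0,
        )
        dataset, metas = generate_study(
            spec, variance_by_condition={c: 0.0 for c in spec.conditions}, seed=0
        )
        res = difference_test(
            dataset, metas, "CL", "OL-ao", B=9, seed=1, quad_nodes=21
        )
        assert res.not_tested
        assert res.p is None
        assert res.d_a.D < 0 and res.d_b.D < 0
        assert res.per_focal == {}

    def test_structure_and_determinism(self, dependent_study):
        dataset, metas = dependent_study
        kwargs = dict(B=19, seed=77, quad_nodes=21, bifactor_quad_nodes=(11, 9),
                      bifactor_tol=1e-2, bifactor_max_iter=40,
                      bootstrap_quad_nodes=13)
        r1 = difference_test(dataset, metas, "CL", "OL-ao", **kwargs)
        r2 = difference_test(dataset, metas, "CL", "OL-ao", **kwargs)
        assert not r1.not_tested
        assert set(r1.per_focal) == {"CL", "OL-ao"}
        assert r1.p == max(r.p for r in r1.per_focal.values())
        assert r1.p == r2.p
        assert r1.observed_diff == pytest.approx(r2.observed_diff)
        # the closed loop carries the event variance here, so Ddiff > 0
        assert r1.observed_diff > 0


class TestOrderConditional:
    @staticmethod
    def _flagged_study(flag_all=True, seed=6):
        spec = DesignSpec(
            conditions=dict(ANIMACY_CONDITIONS),
            element_scheme={c: ANIMACY_SCHEME for c in ANIMACY_CONDITIONS},
            events_per_condition=4,
            n_persons=100,
            seed=seed,
        )
        dataset, metas = generate_study(
            spec, variance_by_condition={c: 0.0 for c in spec.conditions}, seed=seed
        )
        if flag_all:
            metas = [replace(m, animate_first=True) for m in metas]
        return dataset, metas

    def test_uniform_flags_make_the_analysis_unconditional(self):
        dataset, metas = self._flagged_study(flag_all=True)
        est, boot = order_conditional_dependency(
            dataset, metas, "CL", animate_first=True, B=9, seed=2, quad_nodes=21,
        )
        ordered = order_items(metas)
        U, persons, item_ids = to_matrix(dataset, ordered)
        fit = fit_matrix(U, item_ids, persons, quad_nodes=21)
        unconditional = dependency_from_fit(U, fit, ordered, condition="CL")
        assert est.D == pytest.approx(unconditional.D, abs=1e-10)
        assert 0 < boot.p <= 1

    def test_no_matching_event_is_an_error(self):
        dataset, metas = self._flagged_study(flag_all=True)
        with pytest.raises(ValueError, match="matches"):
            order_conditional_dependency(
                dataset, metas, "CL", animate_first=False, B=5, seed=0
            )

    def test_condition_with_only_animate_associations_is_excluded(self):
        dataset, metas = self._flagged_study(flag_all=True)
        # OL-ol excludes object-location, so both presented pairs involve
        # the animal; presentation order regarding animacy is undefined
        with pytest.raises(ValueError, match="animate"):
            order_conditional_dependency(
                dataset, metas, "OL-ol", animate_first=True, B=5, seed=0
            )

    def test_missing_flags_are_an_error(self):
        dataset, metas = self._flagged_study(flag_all=False)
        stripped = [replace(m, animate_first=None) for m in metas]
        with pytest.raises(ValueError, match="flag"):
            order_conditional_dependency(
                dataset, stripped, "CL", animate_first=True, B=5, seed=0
            )
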