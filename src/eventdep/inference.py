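"""Parametric-bootstrap inference for the dependency index D.

The sampling distribution of D is unknown, so p values come from two
parametric bootstraps:

* **Null of local independence** — simulate datasets from the fitted
  unidimensional model (item difficulties from the data, trait drawn
  Normal(0, estimated variance)), recompute D in each, and report a
  two-tailed add-one p value for the observed D.

* **Condition differences** — simulate datasets from the fitted
  bifactor model with *every* event's specific-trait variance set to
  the focal condition's estimate; the null statistic is
  Ddiff = D(a) - D(b), tested one-tailed.  Each condition of the pair
  serves as focal in turn; the reported headline p is the more
  conservative (maximum) of the two.  Pairs where both observed D are
  negative are not tested (the contrast is not of interest there).

Recollection-judgement subsets reuse both machines: bootstrap datasets
receive random R/K/N labels at the empirical proportions, are subset,
and the model is refit before D is recomputed.  A presentation-order
variant conditions D on whether an association involving the animate
element was studied first, by declaring non-matching events' responses
missing and refitting.

All p values use the add-one rule p = (1 + #{null >= observed}) / (1 + B),
so they are never exactly zero; two-tailed p is 2 * min(lower, upper)
capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .design_io import (
    ItemMeta,
    ResponseDataset,
    JUDGEMENT_LABELS,
    drop_unobserved_items,
    from_matrix,
    order_items,
    to_matrix,
)
from .irt_core import (
    GUESS_SIX_AFC,
    ZeroVarianceItemError,
    fit_matrix,
    simulate_matrix,
)
from .bifactor import (
    BifactorFit,
    BifactorParams,
    fit_bifactor,
    simulate_bifactor_batch,
    simulate_bifactor_matrix,
)
from .residual_dependency import (
    MIN_PAIR_PERSONS,
    DependencyEstimate,
    bias_correct,
    dependency,
    dependency_from_fit,
    q3_statistic,
    residual_matrix,
    subset_by_judgement,
)

logger = logging.getLogger("eventdep")

#: Default bootstrap size (at least 1,000 samples are recommended to
#: keep the Monte-Carlo error of p values small).
DEFAULT_B = 1000

_MAX_RETRIES = 3
_MAX_FAILURE_RATE = 0.05


class BootstrapFailureError(RuntimeError):
    """Too many bootstrap replicates failed (degenerate simulated data)."""


@dataclass
class BootstrapResult:
    observed: float
    null_draws: np.ndarray
    p: float
    tails: str
    B: int
    seed: int
    n_failed: int = 0
    focal: Optional[str] = None

    def __post_init__(self) -> None:
        self.null_draws = np.asarray(self.null_draws, dtype=float)


@dataclass
class DifferenceTestResult:
    """Both focal-condition bootstraps for one condition contrast."""

    condition_a: str
    condition_b: str
    observed_diff: float
    d_a: DependencyEstimate
    d_b: DependencyEstimate
    per_focal: dict[str, BootstrapResult] = field(default_factory=dict)
    p: Optional[float] = None
    not_tested: bool = False


# ---------------------------------------------------------------------------
# p-value machinery
# ---------------------------------------------------------------------------

def add_one_p(null_draws: np.ndarray, observed: float, tails: str = "two") -> float:
    """Add-one bootstrap p value; ``tails`` in {"greater", "less", "two"}."""
    null_draws = np.asarray(null_draws, dtype=float)
    B = len(null_draws)
    p_hi = (1 + int(np.sum(null_draws >= observed))) / (B + 1)
    p_lo = (1 + int(np.sum(null_draws <= observed))) / (B + 1)
    if tails == "greater":
        return p_hi
    if tails == "less":
        return p_lo
    if tails == "two":
        return min(1.0, 2.0 * min(p_hi, p_lo))
    raise ValueError(f"unknown tails {tails!r}")


def adjust_pvalues(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment for multiple comparisons."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def assign_judgements(
    dataset: ResponseDataset, proportions: dict[str, float], seed: int
) -> ResponseDataset:
    """Attach independent multinomial R/K/N labels to every response.

    Used by the bootstrap, which assumes judgements are randomly
    distributed across persons and items at their empirical proportions.
    """
    probs = np.array([float(proportions.get(lab, 0.0)) for lab in JUDGEMENT_LABELS])
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError(f"judgement proportions must be >= 0 and sum to 1: {proportions}")
    rng = np.random.default_rng(seed)
    labels = rng.choice(np.array(JUDGEMENT_LABELS), size=dataset.n_records, p=probs)
    df = dataset.records.copy()
    df["judgement"] = labels
    return ResponseDataset(df)


# ---------------------------------------------------------------------------
# D on (possibly subset) data — the quantity every bootstrap recomputes
# ---------------------------------------------------------------------------

def _dependency_of_dataset(
    dataset: ResponseDataset,
    meta: Sequence[ItemMeta],
    condition: Optional[str],
    judgement: Optional[str],
    gamma: float,
    quad_nodes: int,
    min_persons: int,
    tol: float = 1e-5,
    warm_start: Optional[tuple[dict[str, float], float]] = None,
) -> DependencyEstimate:
    """Subset (optionally), refit the unidimensional model, compute D.

    ``warm_start`` is an optional ``({item_id: beta}, variance)`` pair;
    bootstrap replicates start EM at the generating parameters, which
    cuts the iteration count without changing the fixed point.
    """
    scope = "all"
    if judgement is not None:
        dataset = subset_by_judgement(dataset, judgement)
        meta = drop_unobserved_items(dataset, meta)
        scope = judgement
    ordered = order_items(meta)
    U, persons, item_ids = to_matrix(dataset, ordered)
    beta_init, variance_init = None, 1.0
    if warm_start is not None:
        beta_map, variance_init = warm_start
        beta_init = np.array([beta_map[i] for i in item_ids])
    fit = fit_matrix(
        U, item_ids, persons, gamma=gamma, quad_nodes=quad_nodes, tol=tol,
        beta_init=beta_init, variance_init=variance_init,
    )
    return dependency_from_fit(
        U, fit, ordered, condition=condition, min_persons=min_persons,
        judgement_scope=scope,
    )


def _screened_batch(simulate_rows, B: int, seed: int) -> tuple[np.ndarray, int]:
    """Simulate B complete replicates, redrawing any that contain a
    zero-variance item (those cannot be fit); replicates still
    degenerate after the retries are dropped and counted as failed."""
    rng = np.random.default_rng(seed)
    U3 = simulate_rows(rng, B)
    n_failed = 0
    for _ in range(_MAX_RETRIES):
        colsum = U3.sum(axis=1)
        bad = np.any((colsum == 0) | (colsum == U3.shape[1]), axis=1)
        if not bad.any():
            break
        U3[bad] = simulate_rows(rng, int(bad.sum()))
    else:
        colsum = U3.sum(axis=1)
        bad = np.any((colsum == 0) | (colsum == U3.shape[1]), axis=1)
        n_failed = int(bad.sum())
        U3 = U3[~bad]
    if n_failed > _MAX_FAILURE_RATE * B:
        raise BootstrapFailureError(
            f"{n_failed}/{B} bootstrap replicates degenerate even after retries"
        )
    return U3, n_failed


def _batched_condition_Ds(
    U3: np.ndarray,
    ordered: Sequence[ItemMeta],
    conditions: Sequence[Optional[str]],
    gamma: float,
    quad_nodes: int,
    tol: float,
    beta_init: np.ndarray,
    variance_init: float,
    max_iter: int = 40,
) -> dict[Optional[str], np.ndarray]:
    """Refit every complete bootstrap replicate and read off its D values.

    Vectorised version of fit -> residuals -> Q3 -> bias correction -> D
    across the replicate axis; the estimator is the same as in the
    long-format pipeline.
    """
    from .irt_core import fit_matrix_batch
    from scipy.special import expit

    beta, variance, theta = fit_matrix_batch(
        U3, gamma=gamma, quad_nodes=quad_nodes, tol=tol, max_iter=max_iter,
        beta_init=beta_init, variance_init=variance_init,
    )
    B, N, I = U3.shape
    p = gamma + (1 - gamma) * expit(theta[..., None] - beta[:, None, :])
    R = U3 - p
    Rc = R - R.mean(axis=1, keepdims=True)
    cov = np.matmul(Rc.transpose(0, 2, 1), Rc)
    sd = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 1e-24))
    corr = cov / (sd[:, :, None] * sd[:, None, :])
    corr += 1.0 / (I - 1)  # Q3 bias correction

    item_ids = [m.item_id for m in ordered]
    lookup = {m.item_id: m for m in ordered}
    events = np.array([lookup[i].event_id for i in item_ids])
    conds = np.array([lookup[i].condition for i in item_ids])
    upper = np.triu(np.ones((I, I), dtype=bool), k=1)
    same = events[:, None] == events[None, :]
    out: dict[Optional[str], np.ndarray] = {}
    for cond in conditions:
        if cond is None:
            scope = upper
        else:
            inc = conds == cond
            scope = upper & inc[:, None] & inc[None, :]
        wmask, bmask = scope & same, scope & ~same
        out[cond] = corr[:, wmask].mean(axis=1) - corr[:, bmask].mean(axis=1)
    return out


def _bootstrap_loop(B, seed, simulate_and_measure):
    """Common retry/failure accounting for bootstrap replicates."""
    ss = np.random.SeedSequence(seed)
    draws = []
    n_failed = 0
    for child in ss.spawn(B):
        grand = child.spawn(_MAX_RETRIES + 1)
        for attempt in range(_MAX_RETRIES + 1):
            sub_seed = int(grand[attempt].generate_state(1)[0] % (2**31 - 1))
            try:
                draws.append(simulate_and_measure(sub_seed))
                break
            except (ZeroVarianceItemError, ValueError) as err:
                logger.debug("bootstrap replicate failed (%s); retrying", err)
        else:
            n_failed += 1
    if n_failed > _MAX_FAILURE_RATE * B:
        raise BootstrapFailureError(
            f"{n_failed}/{B} bootstrap replicates failed even after retries"
        )
    return np.asarray(draws), n_failed


# ---------------------------------------------------------------------------
# approach 1: null of local independence
# ---------------------------------------------------------------------------

def test_dependency_null(
    dataset: ResponseDataset,
    meta: Sequence[ItemMeta],
    condition: Optional[str] = None,
    judgement: Optional[str] = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: int = 61,
    bootstrap_quad_nodes: int = 21,
    min_persons: int = MIN_PAIR_PERSONS,
) -> BootstrapResult:
    """Two-tailed parametric-bootstrap test of D against local independence.

    Simulates ``B`` datasets from the unidimensional fit of the observed
    data; with ``judgement`` given, each simulated dataset receives
    random labels at the empirical proportions and is subset the same
    way as the observed data before D is recomputed.
    """
    ordered = order_items(meta)
    U, persons, item_ids = to_matrix(dataset, ordered)
    fit = fit_matrix(U, item_ids, persons, gamma=gamma, quad_nodes=quad_nodes)
    observed = _dependency_of_dataset(
        dataset, ordered, condition, judgement, gamma, quad_nodes, min_persons
    ).D
    proportions = dataset.judgement_proportions() if judgement is not None else None
    n_persons = len(persons)
    warm = (dict(zip(item_ids, fit.items.beta)), fit.trait.variance)

    if judgement is None:
        # complete-data replicates: use the vectorised refit engine
        def sim_rows(rng: np.random.Generator, k: int) -> np.ndarray:
            theta = rng.normal(
                0.0, np.sqrt(fit.trait.variance), size=(k, n_persons)
            )
            p = gamma + (1 - gamma) / (
                1 + np.exp(-(theta[..., None] - fit.items.beta[None, None, :]))
            )
            return (rng.random(p.shape) < p).astype(float)

        U3, n_failed = _screened_batch(sim_rows, B, seed)
        null_draws = _batched_condition_Ds(
            U3, ordered, [condition], gamma, bootstrap_quad_nodes, 1e-3,
            fit.items.beta, fit.trait.variance,
        )[condition]
    else:

        def one_draw(sub_seed: int) -> float:
            rng = np.random.default_rng(sub_seed)
            Ub = simulate_matrix(
                fit.items.beta, fit.trait.variance, n_persons, rng, gamma=gamma
            )
            ds = from_matrix(Ub, [f"b{i}" for i in range(n_persons)], item_ids)
            ds = assign_judgements(
                ds, proportions, seed=int(rng.integers(2**31 - 1))
            )
            return _dependency_of_dataset(
                ds, ordered, condition, judgement, gamma, bootstrap_quad_nodes,
                min_persons, tol=1e-4, warm_start=warm,
            ).D

        null_draws, n_failed = _bootstrap_loop(B, seed, one_draw)
    return BootstrapResult(
        observed=observed,
        null_draws=null_draws,
        p=add_one_p(null_draws, observed, tails="two"),
        tails="two",
        B=len(null_draws),
        seed=seed,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# approach 2: condition differences via the bifactor model
# ---------------------------------------------------------------------------

def test_dependency_difference(
    dataset: ResponseDataset,
    meta: Sequence[ItemMeta],
    condition_a: str,
    condition_b: str,
    judgement: Optional[str] = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: int = 61,
    bifactor_quad_nodes: tuple[int, int] = (21, 13),
    bifactor_tol: float = 1e-3,
    bifactor_max_iter: int = 100,
    bootstrap_quad_nodes: int = 21,
    bootstrap_tol: float = 1e-3,
    min_persons: int = MIN_PAIR_PERSONS,
    bifactor_fit: Optional[BifactorFit] = None,
) -> DifferenceTestResult:
    """One-tailed bootstrap test of Ddiff = D(a) - D(b) between conditions.

    Guard: if both conditions' observed D are negative the contrast is
    returned as *not tested* (no p value).  Otherwise each condition
    serves as focal in turn: ``B`` datasets are simulated from the
    bifactor fit with all event variances set to the focal condition's
    estimate, Ddiff is recomputed per dataset, and the add-one one-tailed
    p is the proportion of null Ddiff at or above the observed one.  The
    headline ``p`` is the maximum over the two focal conditions.
    """
    ordered = order_items(meta)
    U, persons, item_ids = to_matrix(dataset, ordered)
    n_persons = len(persons)
    uni = fit_matrix(U, item_ids, persons, gamma=gamma, quad_nodes=quad_nodes)
    if judgement is None:
        q3_obs = bias_correct(
            q3_statistic(residual_matrix(U, uni), item_ids, min_persons=min_persons)
        )
        d_a = dependency(q3_obs, ordered, condition=condition_a)
        d_b = dependency(q3_obs, ordered, condition=condition_b)
    else:
        d_a = _dependency_of_dataset(
            dataset, ordered, condition_a, judgement, gamma, quad_nodes, min_persons
        )
        d_b = _dependency_of_dataset(
            dataset, ordered, condition_b, judgement, gamma, quad_nodes, min_persons
        )
    observed = d_a.D - d_b.D
    result = DifferenceTestResult(
        condition_a=condition_a,
        condition_b=condition_b,
        observed_diff=observed,
        d_a=d_a,
        d_b=d_b,
    )
    if d_a.D < 0 and d_b.D < 0:
        result.not_tested = True
        logger.info(
            "both conditions show negative dependency (%.3f, %.3f); "
            "difference not tested", d_a.D, d_b.D,
        )
        return result

    if bifactor_fit is None:
        # rough moment-style warm start: a condition's D scales with its
        # event variance, so seed the EM near the right magnitude
        init_vars = {}
        for cond in {m.condition for m in ordered}:
            try:
                if judgement is None:
                    d_c = dependency(q3_obs, ordered, condition=cond).D
                else:
                    d_c = 0.025
            except ValueError:
                d_c = 0.025
            init_vars[cond] = float(np.clip(10.0 * d_c, 0.05, 2.0))
        init = BifactorParams(
            item_ids=list(item_ids),
            beta=uni.items.beta,
            gamma=uni.items.gamma,
            general_variance=uni.trait.variance,
            event_variances=init_vars,
        )
        bifactor_fit = fit_bifactor(
            dataset, ordered, gamma=gamma, quad_nodes=bifactor_quad_nodes,
            tol=bifactor_tol, max_iter=bifactor_max_iter, init=init,
        )
    proportions = dataset.judgement_proportions() if judgement is not None else None

    ss = np.random.SeedSequence(seed)
    focal_seeds = {
        cond: int(child.generate_state(1)[0] % (2**31 - 1))
        for cond, child in zip(
            (condition_a, condition_b), ss.spawn(2)
        )
    }
    for focal in (condition_a, condition_b):
        focal_variance = bifactor_fit.params.event_variances[focal]
        params = bifactor_fit.params.with_all_event_variances(focal_variance)
        # unidimensional refits of bifactor data see roughly the general
        # variance plus a share of the event variance; close enough to warm-start
        warm = (
            dict(zip(params.item_ids, params.beta)),
            params.general_variance + focal_variance / 3.0,
        )

        if judgement is None:
            def sim_rows(rng: np.random.Generator, k: int) -> np.ndarray:
                return simulate_bifactor_batch(params, ordered, n_persons, rng, k)

            U3, n_failed = _screened_batch(sim_rows, B, focal_seeds[focal])
            Ds = _batched_condition_Ds(
                U3, ordered, [condition_a, condition_b], gamma,
                bootstrap_quad_nodes, bootstrap_tol,
                params.beta, warm[1],
            )
            null_draws = Ds[condition_a] - Ds[condition_b]
        else:

            def one_draw(sub_seed: int) -> float:
                rng = np.random.default_rng(sub_seed)
                Ub = simulate_bifactor_matrix(params, ordered, n_persons, rng)
                ds = from_matrix(Ub, [f"b{i}" for i in range(n_persons)], item_ids)
                ds = assign_judgements(
                    ds, proportions, seed=int(rng.integers(2**31 - 1))
                )
                ds = subset_by_judgement(ds, judgement)
                sub_ordered = order_items(drop_unobserved_items(ds, ordered))
                # the subset is the same for both conditions: refit once,
                # read off both condition Ds from the same corrected Q3
                Uref, pref, iref = to_matrix(ds, sub_ordered)
                fit_b = fit_matrix(
                    Uref, iref, pref, gamma=gamma,
                    quad_nodes=bootstrap_quad_nodes, tol=bootstrap_tol,
                    beta_init=np.array([warm[0][i] for i in iref]),
                    variance_init=warm[1],
                )
                q3 = bias_correct(
                    q3_statistic(
                        residual_matrix(Uref, fit_b), iref, min_persons=min_persons
                    )
                )
                da = dependency(q3, sub_ordered, condition=condition_a).D
                db = dependency(q3, sub_ordered, condition=condition_b).D
                return da - db

            null_draws, n_failed = _bootstrap_loop(B, focal_seeds[focal], one_draw)
        result.per_focal[focal] = BootstrapResult(
            observed=observed,
            null_draws=null_draws,
            p=add_one_p(null_draws, observed, tails="greater"),
            tails="greater",
            B=len(null_draws),
            seed=focal_seeds[focal],
            n_failed=n_failed,
            focal=focal,
        )
    result.p = max(r.p for r in result.per_focal.values())
    return result


# ---------------------------------------------------------------------------
# presentation-order conditional analysis
# ---------------------------------------------------------------------------

def _animate_pair(pair: frozenset, animate_labels: set[str]) -> bool:
    return any(el in animate_labels for el in pair)


def order_conditional_dependency(
    dataset: ResponseDataset,
    meta: Sequence[ItemMeta],
    condition: str,
    animate_first: bool,
    B: int = DEFAULT_B,
    seed: int = 0,
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: int = 61,
    bootstrap_quad_nodes: int = 21,
    min_persons: int = MIN_PAIR_PERSONS,
    animate_labels: frozenset = frozenset({"animal"}),
) -> tuple[DependencyEstimate, BootstrapResult]:
    """Dependency conditioned on presentation order regarding animacy.

    Responses of events whose ``animate_first`` flag does not match are
    declared missing, the model is refit on the retained items, and D is
    recomputed for ``condition`` together with a null bootstrap in which
    the event-wise masking is re-applied at the observed proportion.

    A condition in which every *presented* association involves the
    animate element is excluded (presentation order regarding animacy is
    not defined there), as are conditions whose events carry no
    animate-first flag.
    """
    ordered = order_items(meta)
    conds = {m.condition for m in ordered}
    if condition not in conds:
        raise ValueError(f"unknown condition {condition!r}")
    cond_items = [m for m in ordered if m.condition == condition]
    presented = [m.association for m in cond_items if not m.inference]
    if presented and all(_animate_pair(p, set(animate_labels)) for p in presented):
        raise ValueError(
            f"condition {condition!r} presented only associations involving "
            f"the animate element; presentation order is undefined there"
        )
    # only events carrying a flag are in scope (events without an animate
    # element have no defined presentation order and are set aside)
    flags = {
        m.event_id: m.animate_first
        for m in ordered
        if m.animate_first is not None
    }
    if not flags:
        raise ValueError("no event carries an animate_first flag")
    if any(m.animate_first is None for m in cond_items):
        raise ValueError(
            f"condition {condition!r} has events without animate_first flags"
        )

    matching_events = {e for e, v in flags.items() if v == animate_first}
    if not {m.event_id for m in cond_items} & matching_events:
        raise ValueError(
            f"no event of condition {condition!r} matches animate_first={animate_first}"
        )

    # observed-side analysis: mask non-matching events, refit, D
    def masked_dependency(ds: ResponseDataset, keep_events: set[str]) -> DependencyEstimate:
        kept = ds.records.loc[
            ds.records["item_id"].map(
                {m.item_id: m.event_id for m in ordered}
            ).isin(keep_events)
        ]
        sub = ResponseDataset(kept.reset_index(drop=True))
        sub_meta = drop_unobserved_items(sub, ordered)
        sub_ordered = order_items(sub_meta)
        Us, ps, iids = to_matrix(sub, sub_ordered)
        fit = fit_matrix(Us, iids, ps, gamma=gamma, quad_nodes=quad_nodes)
        return dependency_from_fit(
            Us, fit, sub_ordered, condition=condition, min_persons=min_persons
        )

    est = masked_dependency(dataset, matching_events)

    # per-condition proportion of matching events drives the bootstrap masks
    events_by_cond: dict[str, list[str]] = {}
    for m in ordered:
        if m.event_id not in flags:
            continue  # out of scope: no presentation-order flag
        lst = events_by_cond.setdefault(m.condition, [])
        if m.event_id not in lst:
            lst.append(m.event_id)
    prop_by_cond = {
        c: float(np.mean([flags[e] == animate_first for e in evs]))
        for c, evs in events_by_cond.items()
    }

    U, persons, item_ids = to_matrix(dataset, ordered)
    full_fit = fit_matrix(U, item_ids, persons, gamma=gamma, quad_nodes=quad_nodes)
    n_persons = len(persons)

    def one_draw(sub_seed: int) -> float:
        rng = np.random.default_rng(sub_seed)
        Ub = simulate_matrix(
            full_fit.items.beta, full_fit.trait.variance, n_persons, rng,
            gamma=gamma,
        )
        ds = from_matrix(Ub, [f"b{i}" for i in range(n_persons)], item_ids)
        keep = {
            e
            for c, evs in events_by_cond.items()
            for e in evs
            if rng.random() < prop_by_cond[c]
        }
        # the focal condition must retain at least 2 events for pairs to exist
        return masked_dependency(ds, keep).D

    null_draws, n_failed = _bootstrap_loop(B, seed, one_draw)
    boot = BootstrapResult(
        observed=est.D,
        null_draws=null_draws,
        p=add_one_p(null_draws, est.D, tails="two"),
        tails="two",
        B=len(null_draws),
        seed=seed,
        n_failed=n_failed,
    )
    return est, boot


def results_frame(results: Sequence) -> pd.DataFrame:
    """Flatten bootstrap results into the per-contrast CSV layout."""
    rows = []
    for res in results:
        if isinstance(res, DifferenceTestResult):
            rows.append(
                {
                    "scope": "difference",
                    "conditions": f"{res.condition_a}-{res.condition_b}",
                    "observed": res.observed_diff,
                    "p": np.nan if res.not_tested else res.p,
                    "not_tested": res.not_tested,
                    "B": 0 if res.not_tested else next(
                        iter(res.per_focal.values())
                    ).B,
                }
            )
        else:
            rows.append(
                {
                    "scope": "null-test",
                    "conditions": "",
                    "observed": res.observed,
                    "p": res.p,
                    "not_tested": False,
                    "B": res.B,
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_B",
    "BootstrapResult",
    "DifferenceTestResult",
    "BootstrapFailureError",
    "add_one_p",
    "adjust_pvalues",
    "assign_judgements",
    "test_dependency_null",
    "test_dependency_difference",
    "order_conditional_dependency",
    "results_frame",
]
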