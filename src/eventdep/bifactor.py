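"""Bifactor extension: event-specific latent traits on top of the 3PL.

Each person carries one general memory trait plus one specific trait per
event; the item linear predictor is

    eta_ij = theta_i + tau_{i,e(j)} - beta_j,
    theta_i ~ N(0, v_g),  tau_{i,e} ~ N(0, v_{c(e)}),  all independent,

with loadings fixed to 1 and the guessing floor as in the
unidimensional model.  The specific-trait variances are constrained
equal across the events of one loop condition (events are randomly
generated, so they are exchangeable within condition); those variances
are the model's measure of within-event retrieval dependency and feed
the parametric bootstrap of the difference test.

Because events are conditionally independent given the general trait,
the marginal likelihood collapses to a one-dimensional outer quadrature
over the general trait times per-event one-dimensional inner quadratures
over the specific traits.  Estimation is EM with damped Fisher scoring
in the M-step (generalised EM: every accepted step improves the
expected complete-data log-likelihood), parameterised by the trait
*scales* on fixed Gauss-Hermite grids so the discretised likelihood
ascends monotonically.  Specific-trait scales are bounded below at 0;
boundary estimates are reported as variance 0 with a flag.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .design_io import (
    ItemMeta,
    ResponseDataset,
    from_matrix,
    order_items,
    to_matrix,
)
from .irt_core import (
    BETA_BOUND,
    GUESS_SIX_AFC,
    _check_variance,
    fit_matrix,
    gauss_hermite,
)

logger = logging.getLogger("eventdep")

# free event-trait scales are floored just above 0 so the scoring step can
# leave the boundary (at exactly 0 the score vanishes identically)
_MIN_SCALE = 1e-4
_BOUNDARY_SCALE = 1e-3


@dataclass
class BifactorParams:
    """Item difficulties plus general and per-condition event variances."""

    item_ids: list[str]
    beta: np.ndarray
    gamma: np.ndarray
    general_variance: float
    event_variances: dict[str, float]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.general_variance <= 0:
            raise ValueError("general trait variance must be positive")
        for cond, v in self.event_variances.items():
            if v < 0:
                raise ValueError(f"event variance for {cond!r} must be >= 0")

    def with_all_event_variances(self, value: float) -> "BifactorParams":
        """Copy with every condition's event variance set to ``value``
        (the focal-condition device of the difference-test bootstrap)."""
        return BifactorParams(
            item_ids=list(self.item_ids),
            beta=self.beta.copy(),
            gamma=self.gamma.copy(),
            general_variance=self.general_variance,
            event_variances={c: float(value) for c in self.event_variances},
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "bifactor-3pl-fixed-guessing",
                "item_ids": self.item_ids,
                "beta": self.beta.tolist(),
                "gamma": self.gamma.tolist(),
                "general_variance": self.general_variance,
                "event_variances": self.event_variances,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BifactorParams":
        doc = json.loads(text)
        return cls(
            item_ids=doc["item_ids"],
            beta=np.asarray(doc["beta"]),
            gamma=np.asarray(doc["gamma"]),
            general_variance=doc["general_variance"],
            event_variances=doc["event_variances"],
        )


@dataclass
class BifactorFit:
    params: BifactorParams
    loglik: float
    converged: bool
    n_iter: int
    boundary: dict[str, bool] = field(default_factory=dict)
    loglik_path: np.ndarray = field(repr=False, default=None)


def _event_structure(ordered: Sequence[ItemMeta]):
    """Item -> event index, event -> condition index, grouped items."""
    event_ids = list(dict.fromkeys(m.event_id for m in ordered))
    e_index = {e: k for k, e in enumerate(event_ids)}
    conditions = list(dict.fromkeys(m.condition for m in ordered))
    c_index = {c: k for k, c in enumerate(conditions)}
    item_event = np.array([e_index[m.event_id] for m in ordered])
    event_condition = np.full(len(event_ids), -1, dtype=int)
    for m in ordered:
        event_condition[e_index[m.event_id]] = c_index[m.condition]
    items_of_event = [np.nonzero(item_event == e)[0] for e in range(len(event_ids))]
    return event_ids, conditions, item_event, event_condition, items_of_event


def _curves_b(gamma, eta):
    p = gamma + (1.0 - gamma) * expit(eta)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p), np.log1p(-p), p


def _grid_score_info(eta, gamma, r, n, multiplier):
    """Score/information for a shift of eta with gradient ``multiplier``."""
    _, _, p = _curves_b(gamma, eta)
    psi = (p - gamma) / (1.0 - gamma)
    dp = (1.0 - gamma) * psi * (1.0 - psi)
    w = dp / (p * (1.0 - p))
    score = np.sum((r - n * p) * w * multiplier)
    info = np.sum(n * dp * w * multiplier**2)
    return score, info


def fit_bifactor(
    dataset: ResponseDataset,
    meta: Sequence[ItemMeta],
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: tuple[int, int] = (31, 21),
    tol: float = 1e-4,
    max_iter: int = 200,
    init: Optional[BifactorParams] = None,
    fix_event_variances: Optional[dict[str, float]] = None,
) -> BifactorFit:
    """Fit the bifactor model by MML/EM with nested quadrature.

    ``quad_nodes`` is (outer, inner): outer nodes integrate the general
    trait, inner nodes each event's specific trait.  ``init`` warm-starts
    the difficulties and variances (a unidimensional fit is used when
    absent).  ``fix_event_variances`` pins named conditions' variances
    (e.g. all to 0 to recover the nested unidimensional likelihood).
    """
    ordered = order_items(meta)
    U, persons, item_ids = to_matrix(dataset, ordered)
    return fit_bifactor_matrix(
        U, item_ids, persons, ordered, gamma=gamma, quad_nodes=quad_nodes,
        tol=tol, max_iter=max_iter, init=init,
        fix_event_variances=fix_event_variances,
    )


def fit_bifactor_matrix(
    U: np.ndarray,
    item_ids: Sequence[str],
    person_ids: Sequence[str],
    ordered: Sequence[ItemMeta],
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: tuple[int, int] = (31, 21),
    tol: float = 1e-4,
    max_iter: int = 200,
    init: Optional[BifactorParams] = None,
    fix_event_variances: Optional[dict[str, float]] = None,
) -> BifactorFit:
    U = np.asarray(U, dtype=float)
    N, I = U.shape
    _check_variance(U, item_ids)
    event_ids, conditions, item_event, event_condition, items_of_event = (
        _event_structure(ordered)
    )
    E, C = len(event_ids), len(conditions)
    for c, cond in enumerate(conditions):
        if int((event_condition == c).sum()) < 2:
            warnings.warn(
                f"condition {cond!r} has fewer than 2 events; its event-trait "
                f"variance is weakly identified",
                stacklevel=2,
            )

    obs = ~np.isnan(U)
    U0 = np.nan_to_num(U)
    M = obs.astype(float)
    UM = U0 * M

    Qo, Qi = quad_nodes
    zo, wo = gauss_hermite(Qo)
    yi, wi = gauss_hermite(Qi)
    logwo, logwi = np.log(wo), np.log(wi)
    QG = Qo * Qi

    # --- initialisation ---
    if init is not None:
        beta = np.clip(init.beta.copy(), -BETA_BOUND, BETA_BOUND)
        s_g = float(np.sqrt(init.general_variance))
        t = np.array(
            [np.sqrt(max(init.event_variances.get(c, 0.25), 0.0)) for c in conditions]
        )
    else:
        uni = fit_matrix(
            U, item_ids, person_ids, gamma=gamma, quad_nodes=Qo, tol=1e-4,
            max_iter=200,
        )
        beta = uni.items.beta.copy()
        s_g = float(np.sqrt(uni.trait.variance))
        t = np.full(C, 0.5)
    fixed_mask = np.zeros(C, dtype=bool)
    if fix_event_variances:
        for cond, v in fix_event_variances.items():
            if cond not in conditions:
                raise ValueError(f"unknown condition {cond!r}")
            c = conditions.index(cond)
            t[c] = np.sqrt(max(float(v), 0.0))
            fixed_mask[c] = True
    gam = np.full(I, gamma)
    item_cond = event_condition[item_event]

    def eta_of(beta_, s_g_, t_):
        """Per-item eta on the (outer, inner) grid, flattened: (I, QG)."""
        base = s_g_ * zo[:, None] + t_[item_cond][:, None, None] * yi[None, :]
        # base: (I, Qo, Qi)
        return (base - beta_[:, None, None]).reshape(I, QG)

    loglik_path = []
    loglik = -np.inf
    converged = False
    r_counts = np.zeros((I, QG))
    n_counts = np.zeros((I, QG))
    for iteration in range(1, max_iter + 1):
        eta = eta_of(beta, s_g, t)
        lp, l1p, _ = _curves_b(gam[:, None], eta)
        delta = lp - l1p
        # per person/event log-density on the grid, via small matmuls
        G = np.empty((N, E, QG))
        for e, jj in enumerate(items_of_event):
            G[:, e, :] = M[:, jj] @ l1p[jj] + UM[:, jj] @ delta[jj]
        G4 = G.reshape(N, E, Qo, Qi)
        a = logsumexp(G4 + logwi[None, None, None, :], axis=3)  # (N, E, Qo)
        b = logwo[None, :] + a.sum(axis=1)  # (N, Qo)
        person_ll = logsumexp(b, axis=1)
        new_loglik = float(person_ll.sum())
        loglik_path.append(new_loglik)
        if iteration > 1 and new_loglik - loglik < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

        post_z = np.exp(b - person_ll[:, None])  # (N, Qo)
        # joint posterior over (z, y) per person/event
        J = np.exp(G4 + logwi[None, None, None, :] - a[..., None])
        J *= post_z[:, None, :, None]
        J2 = J.reshape(N, E, QG)
        for e, jj in enumerate(items_of_event):
            r_counts[jj] = UM[:, jj].T @ J2[:, e, :]
            n_counts[jj] = M[:, jj].T @ J2[:, e, :]

        # --- M-step ---
        # beta: damped per-item scoring
        for _ in range(2):
            eta = eta_of(beta, s_g, t)
            lp, l1p, p = _curves_b(gam[:, None], eta)
            ell = np.sum(r_counts * lp + (n_counts - r_counts) * l1p, axis=1)
            psi = (p - gam[:, None]) / (1.0 - gam[:, None])
            dp = (1.0 - gam[:, None]) * psi * (1.0 - psi)
            w = dp / (p * (1.0 - p))
            score = -np.sum((r_counts - n_counts * p) * w, axis=1)
            info = np.sum(n_counts * dp * w, axis=1)
            step = score / np.maximum(info, 1e-10)
            new_beta = np.clip(beta + step, -BETA_BOUND, BETA_BOUND)
            for _half in range(12):
                lp2, l1p2, _ = _curves_b(gam[:, None], eta_of(new_beta, s_g, t))
                new_ell = np.sum(
                    r_counts * lp2 + (n_counts - r_counts) * l1p2, axis=1
                )
                worse = new_ell < ell - 1e-12
                if not worse.any():
                    break
                new_beta = np.where(worse, (beta + new_beta) / 2.0, new_beta)
            beta = np.where(new_ell >= ell, new_beta, beta)

        # general-trait scale: multiplier is the outer node value
        zgrid = np.broadcast_to(
            zo[None, :, None], (I, Qo, Qi)
        ).reshape(I, QG)
        for _ in range(2):
            eta = eta_of(beta, s_g, t)
            ell = _expected_total(gam, eta, r_counts, n_counts)
            score, info = _grid_score_info(eta, gam[:, None], r_counts, n_counts, zgrid)
            new_sg = max(s_g + score / max(info, 1e-10), 1e-3)
            for _half in range(12):
                if (
                    _expected_total(gam, eta_of(beta, new_sg, t), r_counts, n_counts)
                    >= ell - 1e-12
                ):
                    break
                new_sg = (s_g + new_sg) / 2.0
            else:
                new_sg = s_g
            s_g = new_sg

        # event-trait scales, one per condition
        for c in range(C):
            if fixed_mask[c]:
                continue
            jj = np.nonzero(item_cond == c)[0]
            ygrid = np.broadcast_to(
                yi[None, None, :], (len(jj), Qo, Qi)
            ).reshape(len(jj), QG)
            t_c = t[c]
            for _ in range(2):
                eta = eta_of(beta, s_g, t)[jj]
                ell = _expected_total(gam[jj], eta, r_counts[jj], n_counts[jj])
                score, info = _grid_score_info(
                    eta, gam[jj][:, None], r_counts[jj], n_counts[jj], ygrid
                )
                new_tc = max(t_c + score / max(info, 1e-10), _MIN_SCALE)
                t_try = t.copy()
                for _half in range(12):
                    t_try[c] = new_tc
                    if (
                        _expected_total(
                            gam[jj], eta_of(beta, s_g, t_try)[jj],
                            r_counts[jj], n_counts[jj],
                        )
                        >= ell - 1e-12
                    ):
                        break
                    new_tc = (t_c + new_tc) / 2.0
                else:
                    new_tc = t_c
                t_c = new_tc
                t[c] = t_c
    else:
        logger.info("bifactor EM stopped at max_iter=%d (converged flag unset)", max_iter)

    # final likelihood at the returned parameters
    eta = eta_of(beta, s_g, t)
    lp, l1p, _ = _curves_b(gam[:, None], eta)
    delta = lp - l1p
    G = np.empty((N, E, QG))
    for e, jj in enumerate(items_of_event):
        G[:, e, :] = M[:, jj] @ l1p[jj] + UM[:, jj] @ delta[jj]
    G4 = G.reshape(N, E, Qo, Qi)
    a = logsumexp(G4 + logwi[None, None, None, :], axis=3)
    loglik = float(logsumexp(logwo[None, :] + a.sum(axis=1), axis=1).sum())

    boundary = {
        cond: bool(not fixed_mask[c] and t[c] <= _BOUNDARY_SCALE)
        for c, cond in enumerate(conditions)
    }
    params = BifactorParams(
        item_ids=list(item_ids),
        beta=beta,
        gamma=gam,
        general_variance=s_g * s_g,
        event_variances={
            cond: 0.0 if boundary[cond] else float(t[c] ** 2)
            for c, cond in enumerate(conditions)
        },
    )
    return BifactorFit(
        params=params,
        loglik=loglik,
        converged=converged,
        n_iter=iteration,
        boundary=boundary,
        loglik_path=np.asarray(loglik_path),
    )


def _expected_total(gam, eta, r, n):
    lp, l1p, _ = _curves_b(np.asarray(gam)[:, None], eta)
    return float(np.sum(r * lp + (n - r) * l1p))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_bifactor_matrix(
    params: BifactorParams,
    ordered: Sequence[ItemMeta],
    n_persons: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate a persons x items matrix from the bifactor model."""
    event_ids, conditions, item_event, event_condition, _ = _event_structure(ordered)
    ev_sd = np.array(
        [np.sqrt(params.event_variances[conditions[c]]) for c in event_condition]
    )
    theta = rng.normal(0.0, np.sqrt(params.general_variance), size=n_persons)
    tau = rng.normal(0.0, 1.0, size=(n_persons, len(event_ids))) * ev_sd[None, :]
    eta = theta[:, None] + tau[:, item_event] - params.beta[None, :]
    p = params.gamma[None, :] + (1.0 - params.gamma[None, :]) * expit(eta)
    return (rng.random(p.shape) < p).astype(float)


def simulate_bifactor_batch(
    params: BifactorParams,
    ordered: Sequence[ItemMeta],
    n_persons: int,
    rng: np.random.Generator,
    n_replicates: int,
) -> np.ndarray:
    """Simulate a (replicates, persons, items) stack from the bifactor model."""
    event_ids, conditions, item_event, event_condition, _ = _event_structure(ordered)
    ev_sd = np.array(
        [np.sqrt(params.event_variances[conditions[c]]) for c in event_condition]
    )
    theta = rng.normal(
        0.0, np.sqrt(params.general_variance), size=(n_replicates, n_persons)
    )
    tau = (
        rng.normal(0.0, 1.0, size=(n_replicates, n_persons, len(event_ids)))
        * ev_sd[None, None, :]
    )
    eta = theta[..., None] + tau[:, :, item_event] - params.beta[None, None, :]
    p = params.gamma[None, None, :] + (1.0 - params.gamma[None, None, :]) * expit(eta)
    return (rng.random(p.shape) < p).astype(float)


def simulate_bifactor(
    params: BifactorParams,
    meta: Sequence[ItemMeta],
    n_persons: int,
    seed: int,
    judgement_proportions: Optional[dict[str, float]] = None,
) -> ResponseDataset:
    """Draw a dataset from the bifactor model.

    Optional ``judgement_proportions`` (label -> probability, summing to
    1) attach independent multinomial remember/know/no-recognition
    labels to every response, mirroring the bootstrap's assumption that
    judgements are randomly distributed across persons and items.
    """
    rng = np.random.default_rng(seed)
    ordered = order_items(meta)
    if [m.item_id for m in ordered] != list(params.item_ids):
        ordered = [
            {m.item_id: m for m in meta}[i] for i in params.item_ids
        ]
    U = simulate_bifactor_matrix(params, ordered, n_persons, rng)
    persons = [f"sim{i:05d}" for i in range(n_persons)]
    dataset = from_matrix(U, persons, params.item_ids)
    if judgement_proportions is not None:
        from .inference import assign_judgements

        dataset = assign_judgements(
            dataset, judgement_proportions, seed=int(rng.integers(2**31 - 1))
        )
    return dataset


__all__ = [
    "BifactorParams",
    "BifactorFit",
    "fit_bifactor",
    "fit_bifactor_matrix",
    "simulate_bifactor",
    "simulate_bifactor_matrix",
]
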