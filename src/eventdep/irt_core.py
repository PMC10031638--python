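"""Unidimensional fixed-discrimination, fixed-guessing 3PL model.

The response model for person ``i`` and item ``j`` is

    P(u_ij = 1 | theta_i) = gamma_j + (1 - gamma_j) * logistic(alpha_j * (theta_i - beta_j))

with discrimination ``alpha_j`` fixed to 1 and the guessing floor
``gamma_j`` fixed to the stochastic guessing probability of the test
format (1/6 for six-alternative forced choice).  Only the item
difficulties ``beta_j`` and the latent-trait variance are estimated; the
trait mean is fixed to 0 for identification.

Estimation is marginal maximum likelihood: the trait is integrated out
on a fixed Gauss-Hermite grid (the trait is parameterised as
``theta = s * z`` with ``z`` standard normal, so the grid never moves
and the EM ascent is exact for the discretised likelihood).  The M-step
takes damped Fisher-scoring steps for each ``beta_j`` and for the trait
scale ``s``, accepting a step only if it improves the expected
complete-data log-likelihood; the marginal log-likelihood is therefore
non-decreasing over iterations.  Missing responses simply drop out of
the likelihood (missing-at-random), which is what the judgement-subset
and presentation-order analyses rely on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit, logsumexp

from .design_io import ItemMeta, ResponseDataset, from_matrix, order_items, to_matrix

logger = logging.getLogger("eventdep")

#: Guessing probability of a six-alternative forced-choice trial.
GUESS_SIX_AFC = 1.0 / 6.0

#: Difficulties are clipped here to keep near-degenerate items finite.
BETA_BOUND = 8.0

_MIN_SCALE = 1e-3


class ZeroVarianceItemError(ValueError):
    """An item's observed responses are constant; its difficulty is not
    estimable (all-correct items push beta to -inf, all-wrong to +inf)."""

    def __init__(self, item_ids: Sequence[str]):
        self.item_ids = list(item_ids)
        super().__init__(
            f"items with zero response variance: {self.item_ids[:8]}"
            + ("..." if len(self.item_ids) > 8 else "")
        )


def gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights integrating against the standard normal."""
    z, w = hermegauss(n)
    return z, w / w.sum()


def response_probability(theta, beta, gamma: float = GUESS_SIX_AFC, alpha: float = 1.0):
    """Probability of a correct response under the fixed-guessing 3PL."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must lie in [0, 1), got {gamma}")
    theta = np.asarray(theta, dtype=float)
    return gamma + (1.0 - gamma) * expit(alpha * (theta - np.asarray(beta, dtype=float)))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ItemParams:
    item_ids: list[str]
    beta: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("item difficulties must be finite")
        if np.any(self.gamma >= 1.0) or np.any(self.gamma < 0.0):
            raise ValueError("guessing probabilities must lie in [0, 1)")


@dataclass
class TraitDistribution:
    """Latent-trait distribution: Normal(0, variance)."""

    variance: float
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("trait variance must be positive")


@dataclass
class UnidimensionalFit:
    items: ItemParams
    trait: TraitDistribution
    theta: np.ndarray
    person_ids: list[str]
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "unidimensional-3pl-fixed-guessing",
                "item_ids": self.items.item_ids,
                "beta": self.items.beta.tolist(),
                "alpha": self.items.alpha.tolist(),
                "gamma": self.items.gamma.tolist(),
                "trait_variance": self.trait.variance,
                "person_ids": self.person_ids,
                "theta": self.theta.tolist(),
                "loglik": self.loglik,
                "converged": self.converged,
                "n_iter": self.n_iter,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "UnidimensionalFit":
        doc = json.loads(text)
        return cls(
            items=ItemParams(
                doc["item_ids"],
                np.asarray(doc["beta"]),
                np.asarray(doc["alpha"]),
                np.asarray(doc["gamma"]),
            ),
            trait=TraitDistribution(doc["trait_variance"]),
            theta=np.asarray(doc["theta"]),
            person_ids=doc["person_ids"],
            loglik=doc["loglik"],
            converged=doc["converged"],
            n_iter=doc["n_iter"],
        )


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _check_variance(U: np.ndarray, item_ids: Sequence[str]) -> None:
    obs = ~np.isnan(U)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        n_correct = np.nansum(U, axis=0)
    degenerate = (n_obs == 0) | (n_correct == 0) | (n_correct == n_obs)
    if degenerate.any():
        raise ZeroVarianceItemError([item_ids[j] for j in np.nonzero(degenerate)[0]])


def _log_item_curves(beta, gamma, eta_grid):
    """log P and log(1-P) on a grid of eta = theta - beta offsets.

    ``eta_grid``: array broadcastable as nodes x items of theta values.
    """
    p = gamma + (1.0 - gamma) * expit(eta_grid - beta)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p), np.log1p(-p), p


def _expected_loglik(beta, gamma, theta_nodes, r, n):
    """Expected complete-data log-likelihood per item, summed over nodes."""
    lp, l1p, _ = _log_item_curves(beta[:, None], gamma[:, None], theta_nodes[None, :])
    return np.sum(r * lp + (n - r) * l1p, axis=1)


def _scoring_direction(beta, gamma, theta_nodes, r, n, multiplier):
    """Fisher-scoring score and information for a linear-predictor shift.

    ``multiplier`` is d(eta)/d(param) on the node grid: -1 for beta,
    ``z`` for the trait scale.  Arrays are items x nodes.
    """
    lp, l1p, p = _log_item_curves(beta[:, None], gamma[:, None], theta_nodes[None, :])
    psi = expit(theta_nodes[None, :] - beta[:, None])
    dp = (1.0 - gamma[:, None]) * psi * (1.0 - psi)
    w = dp / (p * (1.0 - p))
    score = (r - n * p) * w * multiplier
    info = n * dp * w * multiplier**2
    return score, info


def fit_matrix(
    U: np.ndarray,
    item_ids: Sequence[str],
    person_ids: Sequence[str],
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: int = 61,
    tol: float = 1e-5,
    max_iter: int = 500,
    beta_init: Optional[np.ndarray] = None,
    variance_init: float = 1.0,
) -> UnidimensionalFit:
    """Fit the model on a persons x items 0/1 matrix with NaN missingness.

    This is the computational core behind :func:`fit_unidimensional`;
    bootstrap loops call it directly to skip the long-format plumbing.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must lie in [0, 1), got {gamma}")
    U = np.asarray(U, dtype=float)
    N, I = U.shape
    _check_variance(U, item_ids)
    obs = ~np.isnan(U)
    U0 = np.nan_to_num(U)
    M = obs.astype(float)

    z, w = gauss_hermite(quad_nodes)
    logw = np.log(w)

    if beta_init is None:
        # start from the guessing-corrected logit of the item proportions
        prop = np.clip(U0.sum(0) / M.sum(0), gamma + 1e-3, 1.0 - 1e-3)
        core = np.clip((prop - gamma) / (1.0 - gamma), 1e-3, 1 - 1e-3)
        beta = np.clip(-np.log(core / (1.0 - core)), -BETA_BOUND, BETA_BOUND)
    else:
        beta = np.clip(np.asarray(beta_init, dtype=float).copy(), -BETA_BOUND, BETA_BOUND)
    s = float(np.sqrt(variance_init))
    gam = np.full(I, gamma)

    loglik_path = []
    loglik = -np.inf
    converged = False
    for iteration in range(1, max_iter + 1):
        theta_nodes = s * z
        lp, l1p, _ = _log_item_curves(beta[:, None], gam[:, None], theta_nodes[None, :])
        # person x node log-likelihood
        L = U0 @ lp + (M - U0) @ l1p  # (N, Q)
        A = L + logw[None, :]
        person_ll = logsumexp(A, axis=1)
        new_loglik = float(person_ll.sum())
        post = np.exp(A - person_ll[:, None])

        loglik_path.append(new_loglik)
        if new_loglik - loglik < tol and iteration > 1:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

        # expected counts on the grid
        r = U0.T @ post  # (I, Q)
        n = M.T @ post

        # --- M-step: damped scoring for beta ---
        for _ in range(3):
            ell = _expected_loglik(beta, gam, theta_nodes, r, n)
            score, info = _scoring_direction(
                beta, gam, theta_nodes, r, n, multiplier=-1.0
            )
            step = score.sum(1) / np.maximum(info.sum(1), 1e-10)
            new_beta = np.clip(beta + step, -BETA_BOUND, BETA_BOUND)
            for _half in range(12):
                new_ell = _expected_loglik(new_beta, gam, theta_nodes, r, n)
                worse = new_ell < ell - 1e-12
                if not worse.any():
                    break
                new_beta = np.where(worse, (beta + new_beta) / 2.0, new_beta)
            beta = np.where(new_ell >= ell, new_beta, beta)
        if np.any(np.abs(beta) >= BETA_BOUND - 1e-9):
            logger.debug("difficulty bound |beta| = %.1f reached", BETA_BOUND)

        # --- M-step: damped scoring for the trait scale s ---
        for _ in range(2):
            theta_nodes = s * z
            ell = _expected_loglik(beta, gam, theta_nodes, r, n).sum()
            score, info = _scoring_direction(
                beta, gam, theta_nodes, r, n, multiplier=z[None, :]
            )
            step = score.sum() / max(info.sum(), 1e-10)
            new_s = max(s + step, _MIN_SCALE)
            for _half in range(12):
                if (
                    _expected_loglik(beta, gam, new_s * z, r, n).sum()
                    >= ell - 1e-12
                ):
                    break
                new_s = (s + new_s) / 2.0
            else:
                new_s = s
            s = new_s
    else:
        logger.warning("EM did not converge in %d iterations", max_iter)

    # final E-step quantities for EAP scores at the returned parameters
    theta_nodes = s * z
    lp, l1p, _ = _log_item_curves(beta[:, None], gam[:, None], theta_nodes[None, :])
    A = U0 @ lp + (M - U0) @ l1p + np.log(w)[None, :]
    person_ll = logsumexp(A, axis=1)
    post = np.exp(A - person_ll[:, None])
    theta = post @ theta_nodes
    loglik = float(person_ll.sum())

    return UnidimensionalFit(
        items=ItemParams(list(item_ids), beta, np.ones(I), gam),
        trait=TraitDistribution(variance=s * s),
        theta=theta,
        person_ids=list(person_ids),
        loglik=loglik,
        converged=converged,
        n_iter=iteration,
        loglik_path=np.asarray(loglik_path),
    )


def fit_unidimensional(
    dataset: ResponseDataset,
    meta: Sequence[ItemMeta],
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: int = 61,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> UnidimensionalFit:
    """Fit the fixed-guessing 3PL by MML on a long-format dataset.

    Items are taken in the canonical (condition, event, cue type) order.
    """
    ordered = order_items(meta)
    U, persons, item_ids = to_matrix(dataset, ordered)
    return fit_matrix(
        U, item_ids, persons, gamma=gamma, quad_nodes=quad_nodes, tol=tol,
        max_iter=max_iter,
    )


def marginal_loglik(
    U: np.ndarray, beta: np.ndarray, variance: float,
    gamma: float = GUESS_SIX_AFC, quad_nodes: int = 61,
) -> float:
    """Quadrature marginal log-likelihood at given parameters."""
    z, w = gauss_hermite(quad_nodes)
    obs = ~np.isnan(U)
    U0 = np.nan_to_num(np.asarray(U, dtype=float))
    M = obs.astype(float)
    gam = np.full(U.shape[1], gamma)
    lp, l1p, _ = _log_item_curves(
        np.asarray(beta)[:, None], gam[:, None], (np.sqrt(variance) * z)[None, :]
    )
    A = U0 @ lp + (M - U0) @ l1p + np.log(w)[None, :]
    return float(logsumexp(A, axis=1).sum())


def fit_matrix_batch(
    U3: np.ndarray,
    gamma: float = GUESS_SIX_AFC,
    quad_nodes: int = 21,
    tol: float = 1e-3,
    max_iter: int = 80,
    beta_init: Optional[np.ndarray] = None,
    variance_init: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the model to a stack of complete-data replicates at once.

    ``U3`` is (replicates, persons, items) with no missing cells — the
    shape of parametric-bootstrap draws, which this vectorised EM exists
    to serve (one EM iteration for all replicates costs a few batched
    matmuls instead of ``B`` separate fits).  Same estimator and
    fixed point as :func:`fit_matrix`; returns ``(beta, variance,
    theta)`` with leading replicate axes.  Callers must screen out
    replicates containing zero-variance items beforehand.
    """
    U3 = np.asarray(U3, dtype=float)
    B, N, I = U3.shape
    z, w = gauss_hermite(quad_nodes)
    logw = np.log(w)

    if beta_init is None:
        prop = np.clip(U3.mean(axis=1), gamma + 1e-3, 1 - 1e-3)
        core = np.clip((prop - gamma) / (1 - gamma), 1e-3, 1 - 1e-3)
        beta = np.clip(-np.log(core / (1 - core)), -BETA_BOUND, BETA_BOUND)
    else:
        beta = np.tile(
            np.clip(np.asarray(beta_init, dtype=float), -BETA_BOUND, BETA_BOUND),
            (B, 1),
        )
    s = np.full(B, np.sqrt(variance_init))

    def curves(beta_, s_):
        # eta[b, q, j] = s_b z_q - beta_bj
        eta = s_[:, None, None] * z[None, :, None] - beta_[:, None, :]
        p = gamma + (1 - gamma) * expit(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p), np.log1p(-p), p

    def e_ell(beta_, s_, r, n):
        lp, l1p, _ = curves(beta_, s_)
        # r, n are (B, I, Q); lp is (B, Q, I)
        return np.sum(
            r * lp.transpose(0, 2, 1) + (n - r) * l1p.transpose(0, 2, 1),
            axis=2,
        )

    loglik = np.full(B, -np.inf)
    for iteration in range(1, max_iter + 1):
        lp, l1p, _ = curves(beta, s)
        dl = (lp - l1p).transpose(0, 2, 1)  # (B, I, Q)
        base = l1p.sum(axis=2)  # (B, Q)
        L = np.matmul(U3, dl) + base[:, None, :]  # (B, N, Q)
        A = L + logw[None, None, :]
        amax = A.max(axis=2, keepdims=True)
        expA = np.exp(A - amax)
        norm = expA.sum(axis=2)
        person_ll = amax[..., 0] + np.log(norm)
        new_loglik = person_ll.sum(axis=1)
        if iteration > 1 and np.all(new_loglik - loglik < tol):
            loglik = new_loglik
            break
        loglik = new_loglik
        post = expA / norm[..., None]  # (B, N, Q)

        r = np.matmul(U3.transpose(0, 2, 1), post)  # (B, I, Q)
        n = np.broadcast_to(post.sum(axis=1)[:, None, :], r.shape)

        # single damped scoring round each for beta and the trait scale
        # (generalised EM; curves are shared between score and objective)
        lpT = lp.transpose(0, 2, 1)
        l1pT = l1p.transpose(0, 2, 1)
        ell = np.sum(r * lpT + (n - r) * l1pT, axis=2)  # (B, I)
        p = np.exp(lpT)
        dp = (p - gamma) * (1 - (p - gamma) / (1 - gamma))
        wgt = dp / (p * (1 - p))
        resid = (r - n * p) * wgt
        score_b = -resid.sum(axis=2)
        info_b = np.sum(n * dp * wgt, axis=2)
        new_beta = np.clip(
            beta + score_b / np.maximum(info_b, 1e-10), -BETA_BOUND, BETA_BOUND
        )
        for _half in range(10):
            new_ell = e_ell(new_beta, s, r, n)
            worse = new_ell < ell - 1e-12
            if not worse.any():
                break
            new_beta = np.where(worse, (beta + new_beta) / 2, new_beta)
        beta = np.where(new_ell >= ell, new_beta, beta)

        lp, l1p, p3 = curves(beta, s)
        lpT = lp.transpose(0, 2, 1)
        l1pT = l1p.transpose(0, 2, 1)
        ell_s = np.sum(r * lpT + (n - r) * l1pT, axis=(1, 2))  # (B,)
        pT = p3.transpose(0, 2, 1)
        dp = (pT - gamma) * (1 - (pT - gamma) / (1 - gamma))
        wgt = dp / (pT * (1 - pT))
        zmul = z[None, None, :]
        score_s = np.sum((r - n * pT) * wgt * zmul, axis=(1, 2))
        info_s = np.sum(n * dp * wgt * zmul**2, axis=(1, 2))
        new_s = np.maximum(s + score_s / np.maximum(info_s, 1e-10), _MIN_SCALE)
        for _half in range(10):
            new_ell = e_ell(beta, new_s, r, n).sum(axis=1)
            worse = new_ell < ell_s - 1e-12
            if not worse.any():
                break
            new_s = np.where(worse, (s + new_s) / 2, new_s)
        s = np.where(new_ell >= ell_s, new_s, s)

    # EAP scores at the final parameters
    lp, l1p, _ = curves(beta, s)
    dl = (lp - l1p).transpose(0, 2, 1)
    L = np.matmul(U3, dl) + l1p.sum(axis=2)[:, None, :]
    A = L + logw[None, None, :]
    amax = A.max(axis=2, keepdims=True)
    expA = np.exp(A - amax)
    post = expA / expA.sum(axis=2, keepdims=True)
    theta = np.einsum("bnq,bq->bn", post, s[:, None] * z[None, :])
    return beta, s**2, theta


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_matrix(
    beta: np.ndarray,
    variance: float,
    n_persons: int,
    rng: np.random.Generator,
    gamma: float = GUESS_SIX_AFC,
) -> np.ndarray:
    """Simulate a complete persons x items response matrix."""
    theta = rng.normal(0.0, np.sqrt(variance), size=n_persons)
    p = response_probability(theta[:, None], np.asarray(beta)[None, :], gamma)
    return (rng.random(p.shape) < p).astype(float)


def simulate_unidimensional(
    fit: UnidimensionalFit, n_persons: int, seed: int
) -> ResponseDataset:
    """Draw a dataset from a fitted unidimensional model.

    Persons are fresh draws theta ~ Normal(0, fitted variance);
    responses are Bernoulli with the fixed-guessing 3PL probabilities.
    """
    rng = np.random.default_rng(seed)
    U = simulate_matrix(
        fit.items.beta, fit.trait.variance, n_persons, rng,
        gamma=float(fit.items.gamma[0]) if len(fit.items.gamma) else GUESS_SIX_AFC,
    )
    persons = [f"sim{i:05d}" for i in range(n_persons)]
    return from_matrix(U, persons, fit.items.item_ids)


__all__ = [
    "GUESS_SIX_AFC",
    "BETA_BOUND",
    "ZeroVarianceItemError",
    "ItemParams",
    "TraitDistribution",
    "UnidimensionalFit",
    "gauss_hermite",
    "response_probability",
    "fit_matrix",
    "fit_matrix_batch",
    "fit_unidimensional",
    "marginal_loglik",
    "simulate_matrix",
    "simulate_unidimensional",
]
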