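"""Yen's Q3 residual correlations and the retrieval-dependency index D.

Under local independence the latent trait explains every inter-item
relationship, so the correlation across persons of two items' model
residuals (Yen's Q3) should be zero up to its small-sample bias of
-1/(I-1), I the number of fitted items.  Event-specific binding
violates local independence for item pairs probing the same event, so
the bias-corrected within-event mean Q3 should exceed the between-event
mean.  The dependency index is

    D = mean(corrected Q3, within-event pairs) - mean(corrected Q3, between-event pairs)

computed over the K within- and L between-event unordered pairs.
Missingness (judgement subsets, presentation-order conditioning) is
handled by pairwise-complete correlations with a minimum joint-person
count per pair; excluded pairs drop out of both means with K and L
adjusted accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .design_io import (
    ItemMeta,
    ResponseDataset,
    _JUDGEMENT_ALIASES,
    order_items,
    to_matrix,
)
from .irt_core import UnidimensionalFit, response_probability

logger = logging.getLogger("eventdep")

#: Pairs with fewer jointly observed persons than this are undefined.
MIN_PAIR_PERSONS = 10


@dataclass
class Q3Matrix:
    """Symmetric item x item residual-correlation matrix.

    The diagonal and any pair with too few jointly observed persons or a
    degenerate residual vector are NaN.  ``corrected`` records whether
    the +1/(I-1) bias correction has been applied.
    """

    values: np.ndarray
    item_ids: list[str]
    corrected: bool = False

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


@dataclass
class DependencyEstimate:
    """The dependency index and the ingredients of its within/between contrast."""

    D: float
    within_mean: float
    between_mean: float
    K: int
    L: int
    condition: Optional[str] = None
    judgement_scope: str = "all"


def residual_matrix(
    dataset_or_matrix,
    fit: UnidimensionalFit,
    meta: Optional[Sequence[ItemMeta]] = None,
) -> np.ndarray:
    """Person x item residuals: observed 0/1 minus model probability.

    The model probability uses each person's EAP trait score.  Accepts
    either a ``ResponseDataset`` (with metadata, ordered canonically) or
    a ready persons x items matrix aligned with the fit's items.
    Missing responses yield NaN residuals.
    """
    if isinstance(dataset_or_matrix, ResponseDataset):
        if meta is None:
            raise ValueError("metadata required to lay out a ResponseDataset")
        ordered = order_items(meta)
        U, persons, item_ids = to_matrix(dataset_or_matrix, ordered)
        if item_ids != fit.items.item_ids or persons != fit.person_ids:
            raise ValueError("fit does not cover this dataset's items/persons")
    else:
        U = np.asarray(dataset_or_matrix, dtype=float)
        if U.shape != (len(fit.person_ids), len(fit.items.item_ids)):
            raise ValueError("matrix shape does not match the fit")
    p = response_probability(
        fit.theta[:, None], fit.items.beta[None, :],
        gamma=float(fit.items.gamma[0]),
    )
    return U - p  # NaN propagates for missing cells


def q3_statistic(
    residuals: np.ndarray,
    item_ids: Sequence[str],
    min_persons: int = MIN_PAIR_PERSONS,
) -> Q3Matrix:
    """Uncorrected Q3: pairwise-complete Pearson correlation of residuals.

    Pairs with fewer than ``min_persons`` jointly observed persons, or a
    zero-variance residual vector on the joint sample, are undefined
    (NaN) rather than errors; tiny subsets produce such pairs.
    """
    R = np.asarray(residuals, dtype=float)
    M = (~np.isnan(R)).astype(float)
    R0 = np.nan_to_num(R)
    n = M.T @ M                       # joint person counts
    s1 = R0.T @ M                     # s1[j,k] = sum_i R_ij over joint persons
    s2 = (R0 * R0).T @ M
    cross = R0.T @ R0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_jk = s1 / n
        var_jk = s2 / n - mean_jk**2
        cov = cross / n - mean_jk * mean_jk.T
        denom = np.sqrt(var_jk * var_jk.T)
        q3 = cov / denom
    bad = (n < min_persons) | (var_jk <= 1e-12) | (var_jk.T <= 1e-12)
    q3[bad] = np.nan
    np.fill_diagonal(q3, np.nan)
    q3 = np.clip(q3, -1.0, 1.0)
    iu = np.triu_indices(len(item_ids), k=1)
    if np.all(np.isnan(q3[iu])):
        raise ValueError("every Q3 entry is undefined")
    return Q3Matrix(values=q3, item_ids=list(item_ids), corrected=False)


def bias_correct(q3: Q3Matrix, n_items: Optional[int] = None) -> Q3Matrix:
    """Remove the -1/(I-1) expectation of Q3 under local independence.

    ``n_items`` defaults to the matrix's own item count (the number of
    items in the current fit); pass the full-design count to reuse it
    for subset analyses instead.
    """
    if q3.corrected:
        raise ValueError("Q3 matrix is already bias-corrected")
    I = q3.n_items if n_items is None else int(n_items)
    if I < 2:
        raise ValueError("bias correction needs at least 2 items")
    return Q3Matrix(
        values=q3.values + 1.0 / (I - 1),
        item_ids=list(q3.item_ids),
        corrected=True,
    )


def _pair_masks(
    q3: Q3Matrix, meta: Sequence[ItemMeta], condition: Optional[str]
) -> tuple[np.ndarray, np.ndarray]:
    lookup = {m.item_id: m for m in meta}
    missing = [i for i in q3.item_ids if i not in lookup]
    if missing:
        raise ValueError(f"metadata lacks items {missing[:5]}")
    events = np.array([lookup[i].event_id for i in q3.item_ids])
    conds = np.array([lookup[i].condition for i in q3.item_ids])
    if condition is not None and condition not in set(conds):
        raise ValueError(f"unknown condition {condition!r}")
    upper = np.triu(np.ones((q3.n_items, q3.n_items), dtype=bool), k=1)
    same_event = events[:, None] == events[None, :]
    if condition is None:
        in_scope = upper
    else:
        in_cond = conds == condition
        in_scope = upper & in_cond[:, None] & in_cond[None, :]
    return in_scope & same_event, in_scope & ~same_event


def dependency(
    q3: Q3Matrix,
    meta: Sequence[ItemMeta],
    condition: Optional[str] = None,
    judgement_scope: str = "all",
) -> DependencyEstimate:
    """Dependency index from a bias-corrected Q3 matrix.

    With ``condition`` given, only pairs whose two items both belong to
    that condition enter either mean (within- and between-event pairs
    alike).  Undefined entries drop out with the pair counts adjusted.
    """
    if not q3.corrected:
        raise ValueError("dependency requires a bias-corrected Q3 matrix")
    within_mask, between_mask = _pair_masks(q3, meta, condition)
    within = q3.values[within_mask]
    between = q3.values[between_mask]
    within = within[~np.isnan(within)]
    between = between[~np.isnan(between)]
    if len(within) == 0 or len(between) == 0:
        raise ValueError(
            f"no usable within-event (K={len(within)}) or between-event "
            f"(L={len(between)}) pairs"
        )
    wm, bm = float(within.mean()), float(between.mean())
    return DependencyEstimate(
        D=wm - bm,
        within_mean=wm,
        between_mean=bm,
        K=len(within),
        L=len(between),
        condition=condition,
        judgement_scope=judgement_scope,
    )


def dependency_from_fit(
    U: np.ndarray,
    fit: UnidimensionalFit,
    meta: Sequence[ItemMeta],
    condition: Optional[str] = None,
    min_persons: int = MIN_PAIR_PERSONS,
    n_items_bias: Optional[int] = None,
    judgement_scope: str = "all",
) -> DependencyEstimate:
    """Residuals -> Q3 -> bias correction -> D, in one call."""
    R = residual_matrix(U, fit)
    q3 = bias_correct(
        q3_statistic(R, fit.items.item_ids, min_persons=min_persons),
        n_items=n_items_bias,
    )
    return dependency(q3, meta, condition=condition, judgement_scope=judgement_scope)


def condition_dependency(
    dataset: ResponseDataset,
    fit: UnidimensionalFit,
    meta: Sequence[ItemMeta],
    condition: str,
    min_persons: int = MIN_PAIR_PERSONS,
) -> DependencyEstimate:
    """Dependency restricted to one loop condition's item pairs."""
    ordered = order_items(meta)
    U, _, _ = to_matrix(dataset, ordered)
    return dependency_from_fit(
        U, fit, ordered, condition=condition, min_persons=min_persons
    )


def subset_by_judgement(dataset: ResponseDataset, judgement: str) -> ResponseDataset:
    """Keep only responses carrying the requested recollection judgement.

    Non-matching responses become missing (their records are removed);
    the model is meant to be refit on the subset before computing D.
    """
    label = _JUDGEMENT_ALIASES.get(str(judgement).strip().lower())
    if label is None:
        raise ValueError(f"unknown judgement label {judgement!r}")
    present = set(dataset.records["judgement"])
    if label not in present:
        raise ValueError(f"judgement {label!r} absent from the data")
    kept = dataset.records.loc[dataset.records["judgement"] == label]
    return ResponseDataset(kept.reset_index(drop=True))


def q3_to_frame(q3: Q3Matrix):
    """Corrected (or raw) Q3 as a square DataFrame with item_id labels."""
    import pandas as pd

    return pd.DataFrame(q3.values, index=q3.item_ids, columns=q3.item_ids)


def dependency_to_row(est: DependencyEstimate) -> dict:
    """Flat-CSV representation of a dependency estimate."""
    return {
        "scope": "condition" if est.condition else "overall",
        "condition": est.condition or "",
        "judgement": est.judgement_scope,
        "D": est.D,
        "within_mean": est.within_mean,
        "between_mean": est.between_mean,
        "K": est.K,
        "L": est.L,
    }


__all__ = [
    "MIN_PAIR_PERSONS",
    "Q3Matrix",
    "DependencyEstimate",
    "residual_matrix",
    "q3_statistic",
    "bias_correct",
    "dependency",
    "dependency_from_fit",
    "condition_dependency",
    "subset_by_judgement",
    "q3_to_frame",
    "dependency_to_row",
]
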