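"""Experimental-design data model and tabular I/O.

The separated-encoding paradigm presents each event as a triplet of
elements (e.g. animal-object-location) whose pairwise associations are
studied one at a time.  Retrieval is probed with three cued-recognition
test trials per event, one per unordered element pair; in open-loop
conditions one association is never studied and its trial is an
*inference* trial.  This module defines the in-memory representation of
that design (events, items, binary responses with optional
remember/know/no-recognition judgements) plus CSV readers/writers and
the canonical item ordering used by all downstream analyses.

Tables are plain CSV, UTF-8, header row required, missing values as
empty fields.  The responses table has columns ``person_id, item_id,
correct[, judgement]``; the item-metadata table has ``item_id, event_id,
condition, cue_type, target_type, inference, block[, animate_first]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("eventdep")

#: Recollection-judgement labels as stored on disk.
JUDGEMENT_REMEMBER = "R"
JUDGEMENT_KNOW = "K"
JUDGEMENT_NO_RECOGNITION = "N"
JUDGEMENT_UNAVAILABLE = "unavailable"
JUDGEMENT_LABELS = (JUDGEMENT_REMEMBER, JUDGEMENT_KNOW, JUDGEMENT_NO_RECOGNITION)

_JUDGEMENT_ALIASES = {
    "r": JUDGEMENT_REMEMBER,
    "remember": JUDGEMENT_REMEMBER,
    "k": JUDGEMENT_KNOW,
    "know": JUDGEMENT_KNOW,
    "n": JUDGEMENT_NO_RECOGNITION,
    "no_recognition": JUDGEMENT_NO_RECOGNITION,
    "no recognition": JUDGEMENT_NO_RECOGNITION,
}

RESPONSE_COLUMNS = ("person_id", "item_id", "correct")
META_COLUMNS = (
    "item_id",
    "event_id",
    "condition",
    "cue_type",
    "target_type",
    "inference",
    "block",
)


class SchemaError(ValueError):
    """A table is missing required columns or carries duplicates."""


class ReferentialError(ValueError):
    """Responses reference item identifiers absent from the metadata."""


@dataclass(frozen=True)
class ElementType:
    """An element category of the event triplets (e.g. animal, location)."""

    label: str
    animate: bool = False


@dataclass(frozen=True)
class Event:
    """One study event: three elements plus its loop structure.

    ``excluded_association`` is the unordered element-type pair never
    shown at study; it is ``None`` exactly for closed-loop events.
    ``animate_first`` records whether an association involving the
    animate element was presented first (``None`` when undefined, e.g.
    for events without an animate element).
    """

    event_id: str
    condition: str
    elements: tuple[str, str, str]
    excluded_association: Optional[frozenset] = None
    animate_first: Optional[bool] = None

    def __post_init__(self) -> None:
        if len(self.elements) != 3 or len(set(self.elements)) != 3:
            raise ValueError(f"event {self.event_id}: needs 3 distinct elements")
        if self.excluded_association is not None:
            pair = frozenset(self.excluded_association)
            if len(pair) != 2 or not pair <= set(self.elements):
                raise ValueError(
                    f"event {self.event_id}: excluded association {set(pair)} "
                    f"is not a pair of the event's element types"
                )
            object.__setattr__(self, "excluded_association", pair)


@dataclass(frozen=True)
class ItemMeta:
    """One cued-recognition test trial (an IRT item)."""

    item_id: str
    event_id: str
    condition: str
    cue_type: str
    target_type: str
    inference: bool
    block: int
    animate_first: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.cue_type == self.target_type:
            raise ValueError(f"item {self.item_id}: cue_type equals target_type")

    @property
    def association(self) -> frozenset:
        return frozenset((self.cue_type, self.target_type))


@dataclass
class ResponseDataset:
    """Long-format binary responses with optional recollection judgements.

    One record per (person, item); ``correct`` is 0/1.  Missing
    responses are simply absent records (they surface as NaN cells in
    :func:`to_matrix`).
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"response table lacks columns {missing}")
        if "judgement" not in df.columns:
            df = df.assign(judgement=JUDGEMENT_UNAVAILABLE)
        df = df.loc[:, ["person_id", "item_id", "correct", "judgement"]].copy()
        df["person_id"] = df["person_id"].astype(str)
        df["item_id"] = df["item_id"].astype(str)
        dup = df.duplicated(subset=["person_id", "item_id"])
        if dup.any():
            raise SchemaError(
                f"{int(dup.sum())} duplicate (person, item) response records"
            )
        correct = pd.to_numeric(df["correct"], errors="coerce")
        bad = df.loc[correct.notna() & ~correct.isin([0, 1])]
        if len(bad):
            raise ValueError(
                f"correct must be 0 or 1; offending item_ids: "
                f"{sorted(bad['item_id'].unique())[:5]}"
            )
        # observed records only; a NaN correct is the same as an absent record
        df = df.loc[correct.notna()].copy()
        df["correct"] = correct.loc[df.index].astype(np.int8)
        df["judgement"] = _normalise_judgements(df["judgement"])
        self.records = df.reset_index(drop=True)

    # -- light accessors ------------------------------------------------
    @property
    def person_ids(self) -> list[str]:
        """Persons in first-appearance (input) order."""
        return list(dict.fromkeys(self.records["person_id"]))

    @property
    def item_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["item_id"]))

    @property
    def n_records(self) -> int:
        return len(self.records)

    def judgement_proportions(self) -> dict[str, float]:
        """Empirical R/K/N proportions among labelled responses."""
        labelled = self.records.loc[
            self.records["judgement"] != JUDGEMENT_UNAVAILABLE, "judgement"
        ]
        if labelled.empty:
            raise ValueError("dataset carries no recollection judgements")
        counts = labelled.value_counts()
        return {lab: counts.get(lab, 0) / len(labelled) for lab in JUDGEMENT_LABELS}


def _normalise_judgements(col: pd.Series) -> pd.Series:
    raw = col.fillna(JUDGEMENT_UNAVAILABLE).astype(str)
    out = raw.str.strip().str.lower().map(_JUDGEMENT_ALIASES)
    unknown = out.isna() & (raw.str.strip() != "") & (
        raw.str.lower() != JUDGEMENT_UNAVAILABLE
    )
    if unknown.any():
        logger.warning(
            "%d judgement labels outside {R, K, N} treated as unavailable",
            int(unknown.sum()),
        )
    return out.fillna(JUDGEMENT_UNAVAILABLE)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_meta(meta_path) -> list[ItemMeta]:
    """Read and validate the item-metadata CSV."""
    df = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table lacks columns {missing}")
    if df["item_id"].duplicated().any():
        raise SchemaError("duplicate item_id in metadata table")
    metas = []
    for row in df.itertuples(index=False):
        animate_first: Optional[bool] = None
        if "animate_first" in df.columns and str(row.animate_first).strip() != "":
            animate_first = _parse_bool(row.animate_first, "animate_first")
        metas.append(
            ItemMeta(
                item_id=row.item_id,
                event_id=row.event_id,
                condition=row.condition,
                cue_type=row.cue_type,
                target_type=row.target_type,
                inference=_parse_bool(row.inference, "inference"),
                block=int(row.block),
                animate_first=animate_first,
            )
        )
    validate_meta(metas)
    return metas


def _parse_bool(value, name: str) -> bool:
    text = str(value).strip().lower()
    if text in ("1", "true", "t", "yes"):
        return True
    if text in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean column {name}: {value!r}")


def validate_meta(metas: Sequence[ItemMeta]) -> None:
    """Check the per-event structure: 3 items, one per unordered pair,
    one per block, and at most one inference item (none for closed loops
    where no association was excluded)."""
    by_event: dict[str, list[ItemMeta]] = {}
    for m in metas:
        by_event.setdefault(m.event_id, []).append(m)
    for event_id, items in by_event.items():
        if len(items) != 3:
            raise SchemaError(f"event {event_id}: expected 3 items, got {len(items)}")
        if len({m.association for m in items}) != 3:
            raise SchemaError(f"event {event_id}: items repeat an element pair")
        if len({m.block for m in items}) != 3:
            raise SchemaError(f"event {event_id}: items repeat a test block")
        if len({m.condition for m in items}) != 1:
            raise SchemaError(f"event {event_id}: items disagree on condition")
        if sum(m.inference for m in items) > 1:
            raise SchemaError(f"event {event_id}: more than one inference item")
        if len({m.animate_first for m in items}) != 1:
            raise SchemaError(f"event {event_id}: items disagree on animate_first")


def read_dataset(responses_path, meta_path) -> tuple[ResponseDataset, list[ItemMeta]]:
    """Read the response and metadata tables and cross-validate them."""
    metas = read_meta(meta_path)
    df = pd.read_csv(responses_path)
    dataset = ResponseDataset(df)
    known = {m.item_id for m in metas}
    unknown = set(dataset.records["item_id"]) - known
    if unknown:
        raise ReferentialError(
            f"responses reference unknown item_ids: {sorted(unknown)[:5]}"
        )
    return dataset, metas


def write_dataset(dataset: ResponseDataset, path) -> None:
    dataset.records.to_csv(path, index=False)


def write_meta(metas: Sequence[ItemMeta], path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "item_id": m.item_id,
                "event_id": m.event_id,
                "condition": m.condition,
                "cue_type": m.cue_type,
                "target_type": m.target_type,
                "inference": m.inference,
                "block": m.block,
                "animate_first": "" if m.animate_first is None else m.animate_first,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# canonical ordering and matrix layout
# ---------------------------------------------------------------------------

def order_items(metas: Iterable[ItemMeta]) -> list[ItemMeta]:
    """Canonical item order: by condition, event, then cue type.

    A total, permutation-invariant order; item_id breaks the (by design
    unreachable) tie of two items of one event sharing a cue type.
    """
    return sorted(
        metas, key=lambda m: (m.condition, m.event_id, m.cue_type, m.item_id)
    )


def to_matrix(
    dataset: ResponseDataset, ordered_meta: Sequence[ItemMeta]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Lay responses out as a persons x items array.

    Returns ``(matrix, person_ids, item_ids)``; cells are 0.0/1.0 with
    ``nan`` marking missing responses.  Persons keep input order, items
    follow ``ordered_meta``.
    """
    item_ids = [m.item_id for m in ordered_meta]
    covered = set(item_ids)
    extra = set(dataset.records["item_id"]) - covered
    if extra:
        raise ReferentialError(f"ordered metadata does not cover items {sorted(extra)[:5]}")
    persons = dataset.person_ids
    pidx = {p: i for i, p in enumerate(persons)}
    iidx = {it: j for j, it in enumerate(item_ids)}
    mat = np.full((len(persons), len(item_ids)), np.nan)
    rec = dataset.records
    mat[
        rec["person_id"].map(pidx).to_numpy(),
        rec["item_id"].map(iidx).to_numpy(),
    ] = rec["correct"].to_numpy(dtype=float)
    return mat, persons, item_ids


def from_matrix(
    matrix: np.ndarray, person_ids: Sequence[str], item_ids: Sequence[str]
) -> ResponseDataset:
    """Inverse of :func:`to_matrix` (judgements come back unavailable)."""
    rows, cols = np.nonzero(~np.isnan(matrix))
    df = pd.DataFrame(
        {
            "person_id": [person_ids[i] for i in rows],
            "item_id": [item_ids[j] for j in cols],
            "correct": matrix[rows, cols].astype(int),
        }
    )
    return ResponseDataset(df)


def drop_unobserved_items(
    dataset: ResponseDataset, metas: Sequence[ItemMeta]
) -> list[ItemMeta]:
    """Metadata restricted to items with at least one observed response.

    Subsetting by judgement or presentation order can silence whole
    items; those cannot enter a model fit and are dropped (the Q3 bias
    correction then uses the reduced item count)."""
    observed = set(dataset.records["item_id"])
    kept = [m for m in metas if m.item_id in observed]
    if not kept:
        raise ValueError("no item retains any observed response")
    if len(kept) < len(list(metas)):
        logger.info("dropping %d items without observed responses", len(list(metas)) - len(kept))
    return kept


def meta_frame(metas: Sequence[ItemMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame (row order preserved)."""
    return pd.DataFrame(
        {
            "item_id": [m.item_id for m in metas],
            "event_id": [m.event_id for m in metas],
            "condition": [m.condition for m in metas],
            "cue_type": [m.cue_type for m in metas],
            "target_type": [m.target_type for m in metas],
            "inference": [m.inference for m in metas],
            "block": [m.block for m in metas],
            "animate_first": [m.animate_first for m in metas],
        }
    )


def subset_meta(metas: Sequence[ItemMeta], item_ids: Iterable[str]) -> list[ItemMeta]:
    wanted = set(item_ids)
    return [m for m in metas if m.item_id in wanted]


__all__ = [
    "ElementType",
    "Event",
    "ItemMeta",
    "ResponseDataset",
    "SchemaError",
    "ReferentialError",
    "JUDGEMENT_REMEMBER",
    "JUDGEMENT_KNOW",
    "JUDGEMENT_NO_RECOGNITION",
    "JUDGEMENT_UNAVAILABLE",
    "JUDGEMENT_LABELS",
    "read_dataset",
    "read_meta",
    "write_dataset",
    "write_meta",
    "validate_meta",
    "order_items",
    "to_matrix",
    "from_matrix",
    "drop_unobserved_items",
    "meta_frame",
    "subset_meta",
]
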