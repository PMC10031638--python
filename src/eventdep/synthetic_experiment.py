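"""Synthetic studies with the separated-encoding structure, and power analysis.

The generator reproduces the statistical skeleton of the three
experiments: events are triplets of typed elements randomly assigned to
loop conditions; every event yields three cued-recognition items, one
per unordered element pair, one per test block, with the cue-target
directions following one of the two rotation cycles used at test; the
excluded association of an open-loop event marks its inference item;
and each event carries a random flag for whether an association
involving the animate element was presented first.  Responses are drawn
from the bifactor model (general trait plus per-event specific traits),
optionally with multinomial remember/know/no-recognition labels.

Presentation-level details with no footprint in the response model
(primacy-buffer events, the filler phase, trial spacing, the word
stimuli themselves) are deliberately not modelled.

The power routine replays the planning logic of the experiments: for a
given design, a per-condition map of event-trait variances (the "gap"
between focal conditions is the effect size, e.g. 1.0 or 0.75), and a
focal contrast, it simulates whole studies and counts how often the
one-tailed bootstrap difference test rejects at the chosen alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .design_io import Event, ItemMeta, ResponseDataset, order_items
from .irt_core import GUESS_SIX_AFC
from .bifactor import BifactorParams, simulate_bifactor
from .inference import test_dependency_difference

logger = logging.getLogger("eventdep")

#: Loop-condition layouts: condition label -> excluded element pair
#: (None = closed loop), per element scheme.
ANIMACY_SCHEME = ("animal", "object", "location")
NON_ANIMACY_SCHEME = ("transport", "tool", "location")

ANIMACY_CONDITIONS = {
    "CL": None,
    "OL-ao": ("animal", "object"),
    "OL-al": ("animal", "location"),
    "OL-ol": ("object", "location"),
}
NON_ANIMACY_CONDITIONS = {
    "CLn": None,
    "OL-tt": ("transport", "tool"),
    "OL-tl": ("transport", "location"),
    "OL-ol2": ("tool", "location"),
}


@dataclass
class DesignSpec:
    """Blueprint of one synthetic study.

    ``conditions`` maps each loop-condition label to its excluded
    element pair (``None`` for the closed loop); ``element_scheme`` maps
    each condition to its ordered element-type triple.
    """

    conditions: dict[str, Optional[tuple[str, str]]]
    element_scheme: dict[str, tuple[str, str, str]]
    events_per_condition: int = 15
    n_persons: int = 180
    animate_labels: frozenset = frozenset({"animal"})
    judgement_proportions: Optional[dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_condition < 1:
            raise ValueError("events_per_condition must be >= 1")
        for cond, excluded in self.conditions.items():
            scheme = self.element_scheme.get(cond)
            if scheme is None or len(set(scheme)) != 3:
                raise ValueError(f"condition {cond!r}: needs a triple of element types")
            if excluded is not None and not set(excluded) <= set(scheme):
                raise ValueError(
                    f"condition {cond!r}: excluded pair {excluded} not in scheme {scheme}"
                )


def exp1_design(n_persons: int = 180, events_per_condition: int = 15,
                judgement_proportions: Optional[dict[str, float]] = None,
                seed: int = 0) -> DesignSpec:
    """Four loop conditions x 15 animal-object-location events (Experiment 1)."""
    return DesignSpec(
        conditions=dict(ANIMACY_CONDITIONS),
        element_scheme={c: ANIMACY_SCHEME for c in ANIMACY_CONDITIONS},
        events_per_condition=events_per_condition,
        n_persons=n_persons,
        judgement_proportions=judgement_proportions,
        seed=seed,
    )


def exp2_design(n_persons: int = 210, events_per_condition: int = 8,
                seed: int = 0) -> DesignSpec:
    """2 (animacy) x 4 (loop) within-subjects design, 8 events each (Experiment 2)."""
    conditions = dict(ANIMACY_CONDITIONS) | dict(NON_ANIMACY_CONDITIONS)
    scheme = {c: ANIMACY_SCHEME for c in ANIMACY_CONDITIONS} | {
        c: NON_ANIMACY_SCHEME for c in NON_ANIMACY_CONDITIONS
    }
    return DesignSpec(
        conditions=conditions,
        element_scheme=scheme,
        events_per_condition=events_per_condition,
        n_persons=n_persons,
        seed=seed,
    )


def exp3_design(animacy: bool = True, n_persons: int = 130,
                events_per_condition: int = 15, seed: int = 0) -> DesignSpec:
    """One between-subjects group of the 2 x 4 mixed design (Experiment 3)."""
    conds = ANIMACY_CONDITIONS if animacy else NON_ANIMACY_CONDITIONS
    scheme = ANIMACY_SCHEME if animacy else NON_ANIMACY_SCHEME
    return DesignSpec(
        conditions=dict(conds),
        element_scheme={c: scheme for c in conds},
        events_per_condition=events_per_condition,
        n_persons=n_persons,
        seed=seed,
    )


def generate_design(
    spec: DesignSpec, seed: Optional[int] = None
) -> tuple[list[Event], list[ItemMeta]]:
    """Draw one randomised design: events, items, blocks, and order flags.

    Per event one of the two cue-target rotation cycles over its element
    triple (x->y, y->z, z->x versus x->z, z->y, y->x) is chosen at
    random, the three items are assigned to the three test blocks in a
    random order, and events containing an animate element receive a
    random animate-first presentation flag.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    events: list[Event] = []
    metas: list[ItemMeta] = []
    for cond in spec.conditions:
        scheme = spec.element_scheme[cond]
        excluded = spec.conditions[cond]
        has_animate = any(el in spec.animate_labels for el in scheme)
        for k in range(spec.events_per_condition):
            event_id = f"{cond}-e{k:03d}"
            animate_first = bool(rng.random() < 0.5) if has_animate else None
            events.append(
                Event(
                    event_id=event_id,
                    condition=cond,
                    elements=tuple(scheme),
                    excluded_association=(
                        frozenset(excluded) if excluded is not None else None
                    ),
                    animate_first=animate_first,
                )
            )
            x, y, z = scheme
            if rng.random() < 0.5:
                pairs = [(x, y), (y, z), (z, x)]
            else:
                pairs = [(x, z), (z, y), (y, x)]
            blocks = rng.permutation([1, 2, 3])
            for (cue, target), block in zip(pairs, blocks):
                metas.append(
                    ItemMeta(
                        item_id=f"{event_id}:{cue}-{target}",
                        event_id=event_id,
                        condition=cond,
                        cue_type=cue,
                        target_type=target,
                        inference=(
                            excluded is not None
                            and frozenset((cue, target)) == frozenset(excluded)
                        ),
                        block=int(block),
                        animate_first=animate_first,
                    )
                )
    return events, metas


def default_params(
    meta: Sequence[ItemMeta],
    variance_by_condition: dict[str, float],
    general_variance: float = 1.0,
    beta_range: tuple[float, float] = (-1.0, 1.0),
    gamma: float = GUESS_SIX_AFC,
    seed: int = 0,
) -> BifactorParams:
    """Generating parameters for a design: uniform difficulties plus the
    requested per-condition event-trait variances."""
    ordered = order_items(meta)
    rng = np.random.default_rng(seed)
    item_ids = [m.item_id for m in ordered]
    conditions = {m.condition for m in ordered}
    missing = conditions - set(variance_by_condition)
    if missing:
        raise ValueError(f"variance_by_condition lacks conditions {sorted(missing)}")
    return BifactorParams(
        item_ids=item_ids,
        beta=rng.uniform(*beta_range, size=len(item_ids)),
        gamma=np.full(len(item_ids), gamma),
        general_variance=general_variance,
        event_variances={c: float(variance_by_condition[c]) for c in conditions},
    )


def generate_study(
    spec: DesignSpec,
    params: Optional[BifactorParams] = None,
    variance_by_condition: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
) -> tuple[ResponseDataset, list[ItemMeta]]:
    """One complete synthetic study: design plus simulated responses.

    Either pass explicit ``params`` (whose item_ids must come from a
    design generated with the same seed) or a ``variance_by_condition``
    map from which default parameters are drawn.
    """
    base_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    s_design, s_params, s_resp = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3)
    )
    _, metas = generate_design(spec, seed=s_design)
    if params is None:
        if variance_by_condition is None:
            variance_by_condition = {c: 0.0 for c in spec.conditions}
        params = default_params(metas, variance_by_condition, seed=s_params)
    dataset = simulate_bifactor(
        params,
        metas,
        spec.n_persons,
        seed=s_resp,
        judgement_proportions=spec.judgement_proportions,
    )
    return dataset, metas


def _design_spec_from_dict(doc: dict) -> DesignSpec:
    return DesignSpec(
        conditions={
            c: (tuple(v) if v is not None else None)
            for c, v in doc["conditions"].items()
        },
        element_scheme={c: tuple(v) for c, v in doc["element_scheme"].items()},
        events_per_condition=int(doc.get("events_per_condition", 15)),
        n_persons=int(doc.get("n_persons", 180)),
        animate_labels=frozenset(doc.get("animate_labels", ["animal"])),
        judgement_proportions=doc.get("judgement_proportions"),
        seed=int(doc.get("seed", 0)),
    )


def design_spec_from_file(path) -> DesignSpec:
    """Read a DesignSpec from a YAML (or JSON) mapping.

    Keys mirror the dataclass fields; ``conditions`` maps each condition
    label to its excluded pair (a 2-list) or null, ``element_scheme`` to
    a 3-list of element types.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("design config must be a mapping")
    return _design_spec_from_dict(doc)


def power_spec_from_file(path) -> "PowerSpec":
    """Read a PowerSpec (with an embedded or referenced design) from YAML/JSON."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    design = doc["design"]
    spec = (
        design_spec_from_file(design)
        if isinstance(design, str)
        else _design_spec_from_dict(design)
    )
    return PowerSpec(
        design=spec,
        variance_by_condition={
            c: float(v) for c, v in doc["variance_by_condition"].items()
        },
        contrast=tuple(doc["contrast"]),
        alpha=float(doc.get("alpha", 0.05)),
        replicates=int(doc.get("replicates", 200)),
        B=int(doc.get("B", 199)),
        general_variance=float(doc.get("general_variance", 1.0)),
    )


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Simulation-based power analysis of the difference test."""

    design: DesignSpec
    variance_by_condition: dict[str, float]
    contrast: tuple[str, str]
    alpha: float = 0.05
    replicates: int = 200
    B: int = 199
    general_variance: float = 1.0
    beta_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for cond in self.contrast:
            if cond not in self.design.conditions:
                raise ValueError(f"contrast condition {cond!r} not in design")


@dataclass
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_rejections: int
    n_not_tested: int
    replicates: int
    B: int
    alpha: float
    seed: int

    def to_row(self) -> dict:
        return {
            "power": self.power,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "rejections": self.n_rejections,
            "not_tested": self.n_not_tested,
            "replicates": self.replicates,
            "B": self.B,
            "alpha": self.alpha,
            "seed": self.seed,
        }


def power_simulation(
    spec: PowerSpec,
    seed: int = 0,
    bifactor_quad_nodes: tuple[int, int] = (13, 9),
    quad_nodes: int = 31,
    bootstrap_quad_nodes: int = 15,
    bifactor_tol: float = 5e-3,
    bifactor_max_iter: int = 80,
) -> PowerResult:
    """Monte-Carlo power of the one-tailed bootstrap difference test.

    Each replicate draws a fresh randomised design and fresh item
    difficulties, simulates a study at the generating variances, runs
    the difference test on the focal contrast, and scores a rejection
    when the headline p value is at or below alpha.  Replicates where
    the both-negative-D guard fires count as non-rejections.
    """
    ss = np.random.SeedSequence(seed)
    cond_a, cond_b = spec.contrast
    rejections = 0
    not_tested = 0
    for rep, child in enumerate(ss.spawn(spec.replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        dataset, metas = generate_study(
            spec.design,
            variance_by_condition=spec.variance_by_condition,
            seed=rep_seed,
        )
        res = test_dependency_difference(
            dataset,
            metas,
            cond_a,
            cond_b,
            B=spec.B,
            seed=rep_seed,
            quad_nodes=quad_nodes,
            bifactor_quad_nodes=bifactor_quad_nodes,
            bootstrap_quad_nodes=bootstrap_quad_nodes,
            bifactor_tol=bifactor_tol,
            bifactor_max_iter=bifactor_max_iter,
        )
        if res.not_tested:
            not_tested += 1
        elif res.p <= spec.alpha:
            rejections += 1
        logger.debug(
            "power replicate %d/%d: %s",
            rep + 1, spec.replicates,
            "not tested" if res.not_tested else f"p={res.p:.3f}",
        )
    power = rejections / spec.replicates
    ci_low, ci_high = proportion_confint(
        rejections, spec.replicates, alpha=0.05, method="beta"
    )
    return PowerResult(
        power=power,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_rejections=rejections,
        n_not_tested=not_tested,
        replicates=spec.replicates,
        B=spec.B,
        alpha=spec.alpha,
        seed=seed,
    )


__all__ = [
    "ANIMACY_SCHEME",
    "NON_ANIMACY_SCHEME",
    "ANIMACY_CONDITIONS",
    "NON_ANIMACY_CONDITIONS",
    "DesignSpec",
    "PowerSpec",
    "PowerResult",
    "exp1_design",
    "exp2_design",
    "exp3_design",
    "generate_design",
    "default_params",
    "design_spec_from_file",
    "power_spec_from_file",
    "generate_study",
    "power_simulation",
]
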