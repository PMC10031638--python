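import pandas as pd
import pytest

from eventdep.design_io import ItemMeta, ResponseDataset, order_items, to_matrix
from eventdep.irt_core import fit_matrix
from eventdep.synthetic_experiment import (
    DesignSpec,
    ANIMACY_CONDITIONS,
    ANIMACY_SCHEME,
    exp1_design,
    generate_design,
    generate_study,
)


@pytest.fixture
def tiny_meta() -> list[ItemMeta]:
    """One closed-loop event: three items, one per pair and block."""
    return [
        ItemMeta("i1", "e1", "CL", "animal", "object", False, 1),
        ItemMeta("i2", "e1", "CL", "object", "location", False, 2),
        ItemMeta("i3", "e1", "CL", "location", "animal", False, 3),
    ]


@pytest.fixture
def tiny_dataset() -> ResponseDataset:
    return ResponseDataset(
        pd.DataFrame(
            {
                "person_id": ["p1", "p1", "p1", "p2", "p2", "p2"],
                "item_id": ["i1", "i2", "i3", "i1", "i2", "i3"],
                "correct": [1, 0, 1, 0, 1, 0],
                "judgement": ["R", "K", "N", "R", "R", "K"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_design():
    """A compact Exp-1-shaped design: 4 loop conditions x 5 events."""
    spec = DesignSpec(
        conditions=dict(ANIMACY_CONDITIONS),
        element_scheme={c: ANIMACY_SCHEME for c in ANIMACY_CONDITIONS},
        events_per_condition=5,
        n_persons=120,
        seed=101,
    )
    events, metas = generate_design(spec)
    return spec, events, metas


@pytest.fixture(scope="session")
def li_study(small_design):
    """Responses simulated under local independence on the small design."""
    spec, _, _ = small_design
    dataset, metas = generate_study(
        spec, variance_by_condition={c: 0.0 for c in spec.conditions}, seed=202
    )
    return dataset, metas


@pytest.fixture(scope="session")
def dependent_study():
    """Exp-1-shaped study in which only the closed loop carries event variance."""
    spec = exp1_design(n_persons=150, events_per_condition=8, seed=303)
    dataset, metas = generate_study(
        spec,
        variance_by_condition={"CL": 1.0, "OL-ao": 0.0, "OL-al": 0.0, "OL-ol": 0.0},
        seed=303,
    )
    return dataset, metas


@pytest.fixture(scope="session")
def li_fit(li_study):
    dataset, metas = li_study
    ordered = order_items(metas)
    U, persons, item_ids = to_matrix(dataset, ordered)
    fit = fit_matrix(U, item_ids, persons, quad_nodes=31, tol=1e-5)
    return U, fit, ordered
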