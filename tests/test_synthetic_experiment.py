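import pytest

from eventdep.design_io import order_items, read_dataset, write_dataset, write_meta
from eventdep.synthetic_experiment import (
    ANIMACY_CONDITIONS,
    ANIMACY_SCHEME,
    DesignSpec,
    PowerSpec,
    default_params,
    design_spec_from_file,
    exp1_design,
    exp2_design,
    exp3_design,
    generate_design,
    generate_study,
    power_simulation,
    power_spec_from_file,
)


class TestGenerateDesign:
    def test_full_design_counts(self):
        spec = exp1_design(seed=1)
        events, metas = generate_design(spec)
        assert len(events) == 60
        assert len(metas) == 180
        inference = [m for m in metas if m.inference]
        assert len(inference) == 45  # one per open-loop event, none in CL
        assert all(m.condition != "CL" for m in inference)

    def test_minimal_closed_loop_design(self):
        spec = DesignSpec(
            conditions={"CL": None},
            element_scheme={"CL": ANIMACY_SCHEME},
            events_per_condition=1,
            n_persons=10,
            seed=2,
        )
        events, metas = generate_design(spec)
        assert len(metas) == 3
        assert not any(m.inference for m in metas)

    def test_same_seed_reproduces_the_design(self):
        spec = exp1_design(seed=7)
        assert generate_design(spec) == generate_design(spec)

    def test_each_event_covers_all_pairs_in_one_rotation_cycle(self):
        spec = exp1_design(seed=3)
        _, metas = generate_design(spec)
        x, y, z = ANIMACY_SCHEME
        cycles = (
            {(x, y), (y, z), (z, x)},
            {(x, z), (z, y), (y, x)},
        )
        by_event = {}
        for m in metas:
            by_event.setdefault(m.event_id, set()).add((m.cue_type, m.target_type))
        for directed in by_event.values():
            assert directed in cycles
            assert {frozenset(p) for p in directed} == {
                frozenset((x, y)), frozenset((y, z)), frozenset((x, z))
            }

    def test_blocks_cover_one_to_three_per_event(self):
        _, metas = generate_design(exp1_design(seed=4))
        by_event = {}
        for m in metas:
            by_event.setdefault(m.event_id, []).append(m.block)
        assert all(sorted(b) == [1, 2, 3] for b in by_event.values())

    def test_animate_flags_only_where_an_animate_element_exists(self):
        _, metas = generate_design(exp2_design(seed=5))
        for m in metas:
            has_animal = m.condition in ANIMACY_CONDITIONS
            assert (m.animate_first is not None) == has_animal

    def test_exp3_group_designs(self):
        _, animate = generate_design(exp3_design(animacy=True, seed=6))
        _, inanimate = generate_design(exp3_design(animacy=False, seed=6))
        assert len(animate) == len(inanimate) == 4 * 15 * 3
        assert all(m.animate_first is None for m in inanimate)

    def test_inconsistent_exclusion_is_an_error(self):
        with pytest.raises(ValueError, match="not in scheme"):
            DesignSpec(
                conditions={"OL-xx": ("animal", "tool")},
                element_scheme={"OL-xx": ANIMACY_SCHEME},
                events_per_condition=2,
                n_persons=10,
            )


class TestGenerateStudy:
    def test_tables_round_trip_through_the_io_layer(self, tmp_path):
        spec = exp1_design(n_persons=8, events_per_condition=2, seed=11,
                           judgement_proportions={"R": 0.5, "K": 0.3, "N": 0.2})
        dataset, metas = generate_study(
            spec, variance_by_condition={c: 0.5 for c in spec.conditions}
        )
        write_dataset(dataset, tmp_path / "responses.csv")
        write_meta(metas, tmp_path / "items.csv")
        back, metas_back = read_dataset(
            tmp_path / "responses.csv", tmp_path / "items.csv"
        )
        assert back.records.equals(dataset.records)
        assert order_items(metas_back) == order_items(metas)

    def test_judgement_labels_present_when_requested(self):
        spec = exp1_design(n_persons=30, events_per_condition=2, seed=12,
                           judgement_proportions={"R": 0.4, "K": 0.4, "N": 0.2})
        dataset, _ = generate_study(
            spec, variance_by_condition={c: 0.0 for c in spec.conditions}
        )
        props = dataset.judgement_proportions()
        assert sum(props.values()) == pytest.approx(1.0)

    def test_default_params_require_every_condition(self):
        _, metas = generate_design(exp1_design(seed=13))
        with pytest.raises(ValueError, match="lacks conditions"):
            default_params(metas, {"CL": 1.0})

    def test_same_seed_same_study(self):
        spec = exp1_design(n_persons=15, events_per_condition=2, seed=14)
        a, _ = generate_study(spec, variance_by_condition={c: 0.3 for c in spec.conditions})
        b, _ = generate_study(spec, variance_by_condition={c: 0.3 for c in spec.conditions})
        assert a.records.equals(b.records)


def test_specs_load_from_yaml_config(tmp_path):
    config = tmp_path / "power.yaml"
    config.write_text(
        """
design:
  conditions: {CL: null, OL-ao: [animal, object]}
  element_scheme:
    CL: [animal, object, location]
    OL-ao: [animal, object, location]
  events_per_condition: 5
  n_persons: 90
variance_by_condition: {CL: 1.0, OL-ao: 0.0}
contrast: [CL, OL-ao]
replicates: 10
B: 39
"""
    )
    spec = power_spec_from_file(config)
    assert spec.design.n_persons == 90
    assert spec.design.conditions["OL-ao"] == ("animal", "object")
    assert spec.contrast == ("CL", "OL-ao")
    assert spec.B == 39

    design_only = tmp_path / "design.yaml"
    design_only.write_text(
        """
conditions: {CL: null}
element_scheme: {CL: [animal, object, location]}
events_per_condition: 2
n_persons: 12
"""
    )
    d = design_spec_from_file(design_only)
    _, metas = generate_design(d)
    assert len(metas) == 6


class TestPower:
    @staticmethod
    def _small_power_spec(gap: float, replicates: int = 2, B: int = 19) -> PowerSpec:
        design = DesignSpec(
            conditions={"CL": None, "OL-ao": ("animal", "object")},
            element_scheme={"CL": ANIMACY_SCHEME, "OL-ao": ANIMACY_SCHEME},
            events_per_condition=5,
            n_persons=80,
            seed=21,
        )
        return PowerSpec(
            design=design,
            variance_by_condition={"CL": gap, "OL-ao": 0.0},
            contrast=("CL", "OL-ao"),
            replicates=replicates,
            B=B,
        )

    def test_power_runs_and_reproduces(self):
        spec = self._small_power_spec(gap=1.0)
        r1 = power_simulation(spec, seed=31)
        r2 = power_simulation(spec, seed=31)
        assert r1.power == r2.power
        assert 0.0 <= r1.ci_low <= r1.power <= r1.ci_high <= 1.0
        assert r1.n_rejections + r1.n_not_tested <= spec.replicates

    def test_power_is_monotone_in_gap_and_sample_size(self):
        def run(gap, n):
            design = DesignSpec(
                conditions={"CL": None, "OL-ao": ("animal", "object")},
                element_scheme={"CL": ANIMACY_SCHEME, "OL-ao": ANIMACY_SCHEME},
                events_per_condition=5,
                n_persons=n,
                seed=61,
            )
            spec = PowerSpec(
                design=design,
                variance_by_condition={"CL": gap, "OL-ao": 0.0},
                contrast=("CL", "OL-ao"),
                replicates=10,
                B=39,
            )
            return power_simulation(spec, seed=601).power

        grid = {(g, n): run(g, n) for g in (0.3, 1.5) for n in (60, 160)}
        for n in (60, 160):
            assert grid[(1.5, n)] > grid[(0.3, n)]
        for g in (0.3, 1.5):
            assert grid[(g, 160)] >= grid[(g, 60)]

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            PowerSpec(
                design=exp1_design(seed=1),
                variance_by_condition={c: 0.0 for c in ANIMACY_CONDITIONS},
                contrast=("CL", "OL-ao"),
                alpha=1.5,
            )
        with pytest.raises(ValueError, match="not in design"):
            PowerSpec(
                design=exp1_design(seed=1),
                variance_by_condition={c: 0.0 for c in ANIMACY_CONDITIONS},
                contrast=("CL", "no-such"),
            )
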