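import numpy as np
import pytest

from strokecea import ModelSpec, base_case, load_model_spec


@pytest.fixture(scope="session")
def default_spec() -> ModelSpec:
    return load_model_spec()


@pytest.fixture(scope="session")
def default_base(default_spec):
    """Base-case run of the packaged defaults, shared across tests."""
    return base_case(default_spec)


def make_random_spec(rng: np.random.Generator, base_doc: dict) -> ModelSpec:
    """A random but internally consistent parameter bundle for property tests."""
    import copy

    doc = copy.deepcopy(base_doc)
    for key in ("comparator", "intervention"):
        p = rng.dirichlet(np.full(7, 2.0))
        doc[key]["mrs_at_3mo"]["values"] = [float(v) for v in p]
        doc[key]["sich_incidence"]["value"] = float(rng.uniform(0.0, 0.1))
    u = np.sort(rng.uniform(0.05, 1.0, size=6))[::-1]
    doc["utilities"]["u_mrs"]["values"] = [float(v) for v in u] + [0.0]
    doc["utilities"]["u_recurrence"]["value"] = float(rng.uniform(0.1, 0.9))
    doc["utilities"]["d_sich"]["value"] = float(rng.uniform(0.0, 0.6))
    doc["costs"]["acute_hosp_by_mrs"]["values"] = [float(v) for v in rng.uniform(5e3, 8e4, size=7)]
    doc["costs"]["annual_care_mrs01"]["value"] = float(rng.uniform(2e3, 2e4))
    doc["costs"]["annual_care_mrs25"]["value"] = float(rng.uniform(1e4, 8e4))
    doc["costs"]["recurrent_stroke_event"]["value"] = float(rng.uniform(5e3, 6e4))
    doc["costs"]["sich_event"]["value"] = float(rng.uniform(5e3, 5e4))
    hr = np.sort(rng.uniform(1.0, 3.0, size=6))
    doc["mortality"]["hr_by_mrs"]["values"] = [float(v) for v in hr]
    doc["mortality"]["post_stroke_excess_hr"]["value"] = float(rng.uniform(1.0, 1.2))
    rec = np.sort(rng.uniform(0.0, 0.15, size=6))
    doc["recurrence"]["annual_recurrence_by_mrs"]["values"] = [float(v) for v in rec]
    doc["recurrence"]["case_fatality"]["value"] = float(rng.uniform(0.0, 0.5))
    doc["recurrence"]["p_stay_given_survive"]["value"] = float(rng.uniform(0.0, 1.0))
    doc["discount"]["annual_rate"]["value"] = float(rng.uniform(0.0, 0.08))
    return ModelSpec.from_dict(doc, strict=False)


@pytest.fixture(scope="session")
def random_spec_factory(default_spec):
    base_doc = default_spec.to_dict()

    def factory(seed: int) -> ModelSpec:
        return make_random_spec(np.random.default_rng(seed), base_doc)

    return factory
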