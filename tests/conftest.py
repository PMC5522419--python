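import numpy as np
import pytest

import sersmix as sx


def make_study(
    names=("4-MBA", "4-MPY"),
    compositions=None,
    spot_sigma=0.0,
    additive_sigma=0.0,
    spots=8,
    seed=0,
    **design_kwargs,
):
    """Build and simulate a small campaign for the given components."""
    names = list(names)
    lib = {c.name: c for c in sx.default_component_library()}
    comps = [lib[n] for n in names]
    if compositions is None:
        compositions = {
            "REF": np.ones(len(names)) / len(names),
            "M1": _simplex_point(len(names), 1),
            "M2": _simplex_point(len(names), 2),
        }
    samples = [
        (sid, sx.Composition(names, np.asarray(frac, dtype=float)))
        for sid, frac in compositions.items()
    ]
    design = sx.SimulationDesign(comps, samples, spots_per_sample=spots, **design_kwargs)
    noise = sx.NoiseModel(spot_factor_sigma=spot_sigma, additive_sigma=additive_sigma)
    return sx.simulate_study(design, noise, seed=seed)


def _simplex_point(c, i):
    rng = np.random.default_rng(100 + i)
    f = rng.dirichlet(np.ones(c) * 4)
    f = np.clip(f, 0.05, None)
    return f / f.sum()


@pytest.fixture
def binary_study():
    return make_study()


@pytest.fixture
def ternary_study():
    return make_study(("1,4-BDT", "4-MBA", "4-MPY"))


@pytest.fixture
def binary_model(binary_study):
    return sx.fit_pure_references(binary_study.pure)
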