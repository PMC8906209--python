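import numpy as np
import pytest

from duomlc import (
    Beam,
    ControlPoint,
    DualLayerPlan,
    Layer,
    build_strips,
    default_layer_specs,
    default_tip_model,
    generate_vmat_plan,
)


def make_uniform_plan(
    prox=(-20.0, 30.0),
    dist=(-20.0, 30.0),
    weights=(0.0, 1.0),
    beam_mu=100.0,
):
    """A plan whose every pair of each layer sits at the same two tips."""
    specs = default_layer_specs()
    cps = []
    for i, w in enumerate(weights):
        positions = {
            Layer.PROXIMAL: (
                np.full(specs[Layer.PROXIMAL].n_pairs, float(prox[0])),
                np.full(specs[Layer.PROXIMAL].n_pairs, float(prox[1])),
            ),
            Layer.DISTAL: (
                np.full(specs[Layer.DISTAL].n_pairs, float(dist[0])),
                np.full(specs[Layer.DISTAL].n_pairs, float(dist[1])),
            ),
        }
        cps.append(ControlPoint(i, float(w), 0.0, positions))
    beam = Beam(beam_mu=beam_mu, control_points=cps, layer_specs=specs)
    return DualLayerPlan(beams=[beam])


@pytest.fixture
def uniform_plan_factory():
    return make_uniform_plan


@pytest.fixture(scope="session")
def strips():
    specs = default_layer_specs()
    return build_strips(specs[Layer.PROXIMAL], specs[Layer.DISTAL])


@pytest.fixture(scope="session")
def tip_model():
    return default_tip_model()


@pytest.fixture(scope="session")
def small_plan():
    return generate_vmat_plan("small", seed=11)


@pytest.fixture(scope="session")
def large_plan():
    return generate_vmat_plan("large", seed=12)
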