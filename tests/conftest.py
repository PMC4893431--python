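import numpy as np
import pytest
from hypothesis import settings

from lvflow import (
    PhantomSpec,
    ReconstructionConfig,
    StructuredGrid,
    default_grid,
    exact_wall_values,
    generate_flow_series,
    project_doppler,
)
from lvflow.grid_ops import MaskedDomain

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25
)
settings.load_profile("ci")

BEAM_X = np.array([1.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def unit_grid9():
    return StructuredGrid(9, 9, 9, 0.25, origin=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def sphere_domain():
    """Spherical mask inside a 14³ grid, wall-labelled everywhere."""
    g = StructuredGrid(14, 14, 14, 1.0 / 13, origin=(-0.5, -0.5, -0.5))
    X, Y, Z = g.meshgrid()
    inside = X**2 + Y**2 + Z**2 <= 0.42**2
    return MaskedDomain.from_mask(g, inside)


@pytest.fixture(scope="session")
def hill_cycle():
    """Default drifting-Hill phantom cycle at the reference resolution,
    shared by the parameter-recovery, sweep and determinism checks."""
    spec = PhantomSpec()
    grid = default_grid(spec, 32)
    frames = generate_flow_series(spec, grid)
    series = [
        project_doppler(v, BEAM_X, frame_dt=spec.frame_dt)
        for _, v in frames
    ]
    domains = [f[0] for f in frames]
    truth = [f[1] for f in frames]
    walls = [exact_wall_values(d, v) for d, v in zip(domains, truth)]
    return {
        "spec": spec,
        "grid": grid,
        "domains": domains,
        "truth": truth,
        "series": series,
        "walls": walls,
        "config": ReconstructionConfig(),
    }
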