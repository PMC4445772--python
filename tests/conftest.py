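import dataclasses

import numpy as np
import pytest

from bgmrsi.params import AcquisitionParams
from bgmrsi.phantom import PhantomSpec, make_default_phantom
from bgmrsi.presets import get_relaxation


@pytest.fixture(scope="session")
def params() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def default_spec():
    """Default phantom subject, seed 1 (noise on)."""
    return make_default_phantom(seed=1, n_subjects=1)[0]


@pytest.fixture(scope="session")
def clean_spec(default_spec):
    """Same subject with noise, residual water and eddy currents disabled."""
    spec = dataclasses.replace(
        default_spec,
        noise_sd=0.0,
        water_residual_scale=0.0,
        eddy_terms=(),
        zero_phase=0.0,
    )
    spec._fractions = None
    return spec


def uniform_spec(tissue: str, params: AcquisitionParams, **overrides) -> PhantomSpec:
    """A phantom whose whole field of view is one pure tissue."""
    n = int(params.fov_mm)
    full = np.ones((n, n, 3))
    zero = np.zeros((n, n, 3))
    vols = {"gm": zero, "wm": zero, "csf": zero}
    vols[tissue] = full
    kwargs = dict(
        subject_id=f"pure_{tissue}",
        gm=vols["gm"], wm=vols["wm"], csf=vols["csf"],
        mask=np.ones((n, n, 3), dtype=bool),
        concentrations={"NAA": (70.0, 76.0), "Cho": (10.0, 13.0),
                        "Cre": (57.0, 44.0), "Lac": (0.5, 0.5)},
        relaxation=get_relaxation(),
        b0_map=np.zeros((params.n_phase_x, params.n_phase_y)),
        linewidth_map=np.full((params.n_phase_x, params.n_phase_y), 5.0),
        eddy_terms=(),
        zero_phase=0.0,
        water_residual_scale=0.0,
        noise_sd=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
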