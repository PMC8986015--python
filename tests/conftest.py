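import numpy as np
import pytest

from morphosex.landmark_io import LandmarkConfiguration
from morphosex.synthetic import (
    PopulationSpec,
    default_template,
    shape_modes,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def template_ref():
    """Default sacrum-like template and its reference configuration."""
    return default_template()


@pytest.fixture(scope="session")
def modes(template_ref):
    tpl, ref = template_ref
    return shape_modes(tpl, ref)


def clean_population_spec(
    template,
    reference,
    modes,
    n_half=25,
    d_shape=0.02,
    allometry_scale=0.25,
    size_log_sd=0.05,
    landmark_noise_sd=0.005,
    jitter_sd=0.0,
    seed=0,
):
    """Single-group balanced world with orthonormal sex/allometric fields,
    so variance shares are exactly computable."""
    refc = reference - reference.mean(axis=0)
    lncs0 = float(np.log(np.sqrt((refc ** 2).sum())))
    k = template.n_landmarks
    return PopulationSpec(
        template=template,
        reference=reference,
        cells={("F", "G"): n_half, ("M", "G"): n_half},
        sex_field=modes["alae_width"],
        d_shape=d_shape,
        allometric_field=modes["sag_curvature"],
        allometry_scale=allometry_scale,
        group_offsets={"G": np.zeros((k, 3))},
        size_log_mean={("F", "G"): lncs0, ("M", "G"): lncs0},
        size_log_sd=size_log_sd,
        landmark_noise_sd=landmark_noise_sd,
        semilandmark_tangential_jitter_sd=jitter_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_population(template_ref, modes):
    """24 specimens from the clean world (session-wide reuse)."""
    tpl, ref = template_ref
    spec = clean_population_spec(tpl, ref, modes, n_half=12, seed=11)
    return simulate_dataset(spec)


@pytest.fixture
def triangle_configs(template_ref):
    """Three planar triangles with stated coordinates (toy GPA input)."""
    from morphosex.landmark_io import CurveDefinition, TemplateDefinition

    tpl = TemplateDefinition(name="tri", n_fixed=3, n_semi=0, curves=())
    coords = [
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0.0, 0.1, 0.0], [1.2, 0.0, 0.0], [0.1, 0.9, 0.0]]),
        np.array([[-0.1, 0.0, 0.0], [1.0, 0.2, 0.0], [0.0, 1.1, 0.0]]),
    ]
    return [
        LandmarkConfiguration(f"t{i}", c, tpl) for i, c in enumerate(coords)
    ], tpl
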