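import numpy as np
import pytest

from connload.atlas import N_ROIS, AtlasDefinition
from connload.io import ConnectivityMatrix
from connload.synthetic import (
    GeneratorConfig,
    draw_edge_params,
    generate_controls,
    make_scaffold,
)


@pytest.fixture(scope="session")
def atlas():
    return AtlasDefinition.default()


@pytest.fixture(scope="session")
def small_config():
    """A light cohort configuration used across the unit tests."""
    return GeneratorConfig(
        n_controls=10,
        n_patients_localized=8,
        n_patients_widespread=8,
        scaffold_density=0.15,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scaffold(small_config, atlas):
    return make_scaffold(small_config, atlas)


@pytest.fixture(scope="session")
def small_params(small_config, small_scaffold):
    return draw_edge_params(small_config, small_scaffold)


@pytest.fixture(scope="session")
def small_controls(small_config, small_scaffold, small_params):
    return generate_controls(small_config, small_scaffold, small_params)


def matrix_from_edges(edges, subject_id="s", modality="FA"):
    """Build a 90x90 ConnectivityMatrix from {(i, j): weight}."""
    w = np.zeros((N_ROIS, N_ROIS))
    for (i, j), value in edges.items():
        w[i, j] = w[j, i] = value
    return ConnectivityMatrix(subject_id, modality, w)


def cohort_on_edges(edge_samples, modality="FA", prefix="s"):
    """Build a cohort from {(i, j): [w_subject0, w_subject1, ...]}."""
    n = len(next(iter(edge_samples.values())))
    return [
        matrix_from_edges(
            {e: vals[k] for e, vals in edge_samples.items()},
            subject_id=f"{prefix}{k}",
            modality=modality,
        )
        for k in range(n)
    ]
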