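import numpy as np
import pytest

import dynflex as dx
from dynflex.dfc import DynamicConnectivityStack, WindowScheme


def single_layer_stack(A: np.ndarray) -> DynamicConnectivityStack:
    """Wrap an adjacency/correlation matrix as a one-layer stack."""
    A = np.asarray(A, dtype=float)
    return DynamicConnectivityStack(
        tensor=A[:, :, None],
        region_ids=[f"R{i + 1:03d}" for i in range(A.shape[0])],
        window_starts=np.array([0]),
        scheme=WindowScheme(width=2, step=1),
    )


def stack_from_layers(layers: list[np.ndarray]) -> DynamicConnectivityStack:
    tensor = np.stack([np.asarray(a, dtype=float) for a in layers], axis=2)
    return DynamicConnectivityStack(
        tensor=tensor,
        region_ids=[f"R{i + 1:03d}" for i in range(tensor.shape[0])],
        window_starts=np.arange(tensor.shape[2]),
        scheme=WindowScheme(width=2, step=1),
    )


@pytest.fixture(scope="session")
def planted_subject():
    """One low-switch synthetic subject at an identifiable module count."""
    spec = dx.CohortSpec(n_subjects_per_group=(1, 1), n_regions=60,
                         n_timepoints=230, n_modules=4, seed=11)
    truth = dx.generate_partition_sequence(spec, 0, 101)
    ts = dx.simulate_timeseries(truth, spec, 102)
    return spec, truth, ts


@pytest.fixture(scope="session")
def toy_cohort_config():
    """Small but non-degenerate pipeline configuration for smoke tests."""
    from dynflex.pipeline import PipelineConfig
    from dynflex.stats import ComparisonSpec

    return PipelineConfig(
        cohort=dx.CohortSpec(n_subjects_per_group=(3, 3), n_regions=20,
                             n_timepoints=60, n_modules=3, epoch_length=20,
                             seed=5),
        window=dx.WindowScheme(30, 1),
        n_reps=2,
        comparison=ComparisonSpec(n_permutations=60, seed=0, covariates=()),
        include_nodal=False,
        out_dir="unused",
    )
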