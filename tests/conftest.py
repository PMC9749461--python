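import numpy as np
import pandas as pd
import pytest

import hvcpg as h


def make_dataset(values, dataset_id="toy", covariates=None, detection_p=None):
    """Build a MethylationDataset from a 2-D array or dict of rows."""
    beta = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    beta.index = [f"cg{i:05d}" for i in range(len(beta))] if beta.index.dtype != object else beta.index
    beta.columns = [f"s{j}" for j in range(beta.shape[1])] if beta.columns.dtype != object else beta.columns
    cov = covariates if covariates is not None else pd.DataFrame(index=beta.columns)
    det = None
    if detection_p is not None:
        det = pd.DataFrame(np.asarray(detection_p), index=beta.index, columns=beta.columns)
    return h.MethylationDataset(dataset_id=dataset_id, beta=beta, covariates=cov, detection_p=det)


@pytest.fixture(scope="session")
def small_study():
    """Five-cohort synthetic study with every planted category present."""
    cfg = h.SimulationConfig(
        n_datasets=5, n_samples_per_dataset=60, n_cpgs=1500,
        n_planted_shared_hv=40, n_planted_dataset_specific=10,
        n_planted_mqtl=20, n_planted_cluster=60, n_batch_components=2, seed=3,
    )
    datasets, annotation, truth = h.simulate_study(cfg)
    return cfg, datasets, annotation, truth


@pytest.fixture(scope="session")
def null_dataset():
    """A single cohort with no planted signal (background-like CpGs)."""
    cfg = h.SimulationConfig(n_datasets=1, n_samples_per_dataset=100, n_cpgs=1200, seed=11)
    (ds,), annotation, truth = h.simulate_study(cfg)
    return ds, annotation, truth
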