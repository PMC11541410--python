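import numpy as np
import pandas as pd
import pytest

from mlmcorr import ClusteredDataset, ConditionSpec, generate_dataset
from mlmcorr.lmm_core import ModelSpec, fit_lmm, fit_ols


def make_clustered(J, n, seed=0, tau0=0.5, sigma=1.0, beta_z=0.5, tau1=0.0):
    """Hand-rolled RI/RS data independent of the package generator."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(J)
    u0 = rng.standard_normal(J) * np.sqrt(tau0)
    u1 = rng.standard_normal(J) * np.sqrt(tau1)
    x = rng.standard_normal(J * n)
    e = rng.standard_normal(J * n) * sigma
    zz = np.repeat(z, n)
    y = 1.0 + beta_z * zz + np.repeat(u0, n) + np.repeat(u1, n) * x + e
    return ClusteredDataset(pd.DataFrame({
        "cluster_id": np.repeat(np.arange(J), n),
        "y": y, "x": x, "z": zz,
    }))


@pytest.fixture(scope="session")
def vp1_condition():
    return ConditionSpec(J=15, n_bar=5, icc=0.3, gamma01=0.0, gamma10=0.0,
                         balanced=True, vp_l1="VP1", vp_l2="VP1")


@pytest.fixture(scope="session")
def small_dataset(vp1_condition):
    return generate_dataset(vp1_condition, seed=42)


@pytest.fixture(scope="session")
def rs_fit(small_dataset):
    return fit_lmm(small_dataset, ModelSpec(kind="rs"))


@pytest.fixture(scope="session")
def ri_fit(small_dataset):
    return fit_lmm(small_dataset, ModelSpec(kind="ri"))


@pytest.fixture(scope="session")
def ols_fit(small_dataset):
    return fit_ols(small_dataset)
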