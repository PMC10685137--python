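import numpy as np
import pandas as pd
import pytest

from conflictsex import SimulationConfig, simulate_season
from conflictsex import selection as sel
from conflictsex.flowers import BISEXUAL, MALE, FlowerRecord


@pytest.fixture(scope="session")
def default_season():
    """One full synthetic season at the default study-like conditions."""
    return simulate_season(SimulationConfig(rng_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_bisexual(fid="F001", ind="I001", pistils=100, stamens=150,
                  opening=0, fem_len=5, male_start=None, male_len=5,
                  removal=0.0, seeds=0, tepal=25.0, stalk=20.0):
    """Hand-built bisexual flower with sensible defaults."""
    ms = opening + fem_len if male_start is None else male_start
    return FlowerRecord(
        flower_id=fid, individual_id=ind, sex_class=BISEXUAL,
        pistil_count=pistils, stamen_count_initial=stamens,
        opening_day=opening, female_interval=(opening, opening + fem_len),
        male_interval=(ms, ms + male_len), removal_fraction=removal,
        tepal_length=tepal, stalk_height=stalk, seed_count=seeds)


def make_male(fid="M001", ind="I901", stamens=150, opening=0, dur=10,
              removal=0.0, tepal=25.0, stalk=12.0):
    return FlowerRecord(
        flower_id=fid, individual_id=ind, sex_class=MALE,
        pistil_count=0, stamen_count_initial=stamens, opening_day=opening,
        male_interval=(opening, opening + dur), removal_fraction=removal,
        tepal_length=tepal, stalk_height=stalk)


def simulate_gradient_data(n, beta_F, beta_M, s2f=0.3, s2m=0.6, tau2=0.1,
                           rng=None, n_traits=5):
    """Direct draw from the bivariate selection-gradient model: standardized
    traits, female/male relative fitness with a shared flower effect and
    function-specific residual noise."""
    rng = np.random.default_rng(0) if rng is None else rng
    Z = rng.normal(size=(n, n_traits))
    z = pd.DataFrame(Z, columns=sel.TRAITS[:n_traits],
                     index=[f"F{i:04d}" for i in range(n)])
    tm = sel.standardize(z)
    zz = tm.z.to_numpy()
    u = rng.normal(0, np.sqrt(tau2), n)
    wF = 1 + zz @ np.asarray(beta_F) + u + rng.normal(0, np.sqrt(s2f), n)
    wM = 1 + zz @ np.asarray(beta_M) + u + rng.normal(0, np.sqrt(s2m), n)
    fitness = pd.DataFrame({"flower_id": z.index,
                            "relW_female": wF, "relW_male": wM})
    return tm, fitness


def dense_gls_oracle(fit, traits, fitness):
    """Independent GLS solution with the full covariance matrix built and
    inverted explicitly at the fitted variance components."""
    X, _ = sel._design(traits.z)
    n, p = X.shape[0], X.shape[2]
    Xf = X.reshape(-1, p)
    y = (fitness.set_index("flower_id").loc[traits.z.index]
         [["relW_female", "relW_male"]].to_numpy(float).reshape(-1))
    V2 = np.array([[fit.sigma2_F + fit.tau2, fit.tau2],
                   [fit.tau2, fit.sigma2_M + fit.tau2]])
    V = np.kron(np.eye(n), V2)
    Vi = np.linalg.inv(V)
    return np.linalg.solve(Xf.T @ Vi @ Xf, Xf.T @ Vi @ y)
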