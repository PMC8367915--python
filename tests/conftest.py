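import numpy as np
import pytest

from crtmiss import (
    CorrelationStructure,
    DropoutModel,
    TestSpec,
    TrialDesign,
    make_design,
)
from crtmiss.variance import build_cluster_covariance


@pytest.fixture
def corr_decay():
    """Correlation structure from the worked correlation example."""
    return CorrelationStructure(rho=0.05, r=0.9)


@pytest.fixture
def example_corr():
    """Correlation structure of the dental-practice worked example."""
    return CorrelationStructure(rho=0.05, r=0.95)


@pytest.fixture
def example_test():
    return TestSpec(d=0.2, alpha=0.05, sided="two")


@pytest.fixture
def example_dropout():
    """Per-arm dropout of the worked example: omega 0.2 control, 0.1 intervention."""
    return (DropoutModel(0.2, 2.0, 56), DropoutModel(0.1, 2.0, 56))


@pytest.fixture
def full_week():
    return make_design("Mo,Tu,We,Th,Fr,Sa,Su", 1, 5, 2)


@pytest.fixture(scope="session")
def replicated_fits():
    """2000 simulate-and-refit replications of a small complete-data trial.

    Shared session-wide: both the simulator tests and the end-to-end
    validation draw on the same Monte-Carlo run.
    """
    from crtmiss.simulate import gls_fit, simulate_trial

    design = make_design("Mo,Tu,We,Th,Fr,Sa,Su", 1, 5, 2)
    corr = CorrelationStructure(rho=0.05, r=0.9)
    theta = 0.2
    rng = np.random.default_rng(20240917)
    estimates, variances = [], []
    for _ in range(2000):
        trial = simulate_trial(design, corr, theta=theta, rng=rng)
        est, cov = gls_fit(trial)
        estimates.append(est[-1])
        variances.append(cov[-1, -1])
    return design, corr, theta, np.array(estimates), np.array(variances)


def brute_force_variance(design: TrialDesign, corr, n_obs_by_arm=None) -> float:
    """Independent oracle: explicit subject-level GLS over all 2k clusters.

    Builds the full m*h x (T+1) design matrix and m*h x m*h covariance for
    every cluster, sums X' V^-1 X, inverts, and returns the last diagonal
    element.  ``n_obs_by_arm`` gives each cluster's number of observed
    periods per arm (default: complete data).
    """
    T, m, k = design.n_periods, design.subjects, design.clusters
    if n_obs_by_arm is None:
        n_obs_by_arm = ([T] * k, [T] * k)
    info = np.zeros((T + 1, T + 1))
    for arm, h_list in enumerate(n_obs_by_arm):
        for h in h_list:
            X = np.zeros((m * h, T + 1))
            for idx in range(h):
                X[idx * m : (idx + 1) * m, idx] = 1.0
            X[:, -1] = float(arm)
            V = build_cluster_covariance(design, corr, h)
            info += X.T @ np.linalg.solve(V, X)
    return float(np.linalg.inv(info)[-1, -1])
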