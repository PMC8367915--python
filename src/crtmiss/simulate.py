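"""Monte-Carlo validation of the analytic variance engine.

Generates synthetic trial data from the same two-level model the variance
engine assumes — cluster-period random effects with calendar-day decay
correlation, independent subject residuals, discrete-Weibull cluster dropout
— and refits the fixed effects by GLS with the variance components treated
as known.  Across replications the empirical variance of the treatment
effect estimate should match the analytic value, which is the engine's core
end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignError, TrialDesign
from .dropout import DropoutModel, count_probabilities
from .variance import CorrelationStructure, _invert_information

__all__ = ["SimulatedTrial", "simulate_trial", "gls_fit"]


@dataclass
class SimulatedTrial:
    """One synthetic trial realization in tidy long format.

    ``data`` has one row per measured subject with columns
    (cluster, arm, period, day, subject, y); ``truth`` records the generating
    parameters and the realized number of observed periods per cluster.
    """

    design: TrialDesign
    corr: CorrelationStructure
    data: pd.DataFrame
    beta: np.ndarray
    theta: float
    n_periods_observed: np.ndarray  # length 2k, aligned with cluster ids

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _draw_observed_periods(
    T: int,
    p: np.ndarray | None,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Number of observed periods per cluster, drawn from the count distribution."""
    if p is None:
        return np.full(k, T)
    return rng.choice(np.arange(1, T + 1), size=k, p=p / p.sum())


def simulate_trial(
    design: TrialDesign,
    corr: CorrelationStructure,
    dropout_by_arm: tuple[DropoutModel, DropoutModel] | None = None,
    beta: np.ndarray | None = None,
    theta: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SimulatedTrial:
    """Simulate one repeated cross-sectional two-arm trial.

    Per cluster: the dropout day is drawn on the discrete measurement-day
    grid via the count distribution (inverse-CDF on the end-of-day
    convention), the cluster-period effects u are drawn jointly from
    N(0, sigma_u^2 * r^gap) over all T periods, subject residuals
    independently from N(0, sigma_e^2), and records are truncated to the
    first h observed periods (monotone missingness).
    """
    rng = np.random.default_rng(rng)
    T, m, k = design.n_periods, design.subjects, design.clusters
    if beta is None:
        beta = np.zeros(T)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (T,):
        raise DesignError(f"beta: expected length {T}, got shape {beta.shape}")

    days = np.asarray(design.calendar_days, dtype=float)
    cov_u = corr.sigma_u2 * corr.decay_matrix(days)
    sd_e = float(np.sqrt(corr.sigma_e2))

    rows = []
    n_obs = np.empty(2 * k, dtype=int)
    cluster_id = 0
    for arm in (0, 1):
        p = (
            None
            if dropout_by_arm is None
            else count_probabilities(design, dropout_by_arm[arm])
        )
        h_arm = _draw_observed_periods(T, p, k, rng)
        for j in range(k):
            h = int(h_arm[j])
            n_obs[cluster_id] = h
            if corr.sigma_u2 > 0:
                u = rng.multivariate_normal(np.zeros(T), cov_u, method="cholesky")
            else:
                u = np.zeros(T)
            for idx in range(h):
                mean = beta[idx] + arm * theta + u[idx]
                e = sd_e * rng.standard_normal(m) if sd_e > 0 else np.zeros(m)
                for i in range(m):
                    rows.append(
                        (cluster_id, arm, idx + 1, int(days[idx]), i + 1, mean + e[i])
                    )
            cluster_id += 1
    data = pd.DataFrame(
        rows, columns=["cluster", "arm", "period", "day", "subject", "y"]
    )
    return SimulatedTrial(design, corr, data, beta, theta, n_obs)


def gls_fit(trial: SimulatedTrial) -> tuple[np.ndarray, np.ndarray]:
    """GLS fit of (beta_1..beta_T, theta) with known variance components.

    Returns the estimates and their model-based covariance matrix, which for
    the realized missingness pattern equals the analytic information-matrix
    inverse.  This is design-stage validation: rho and r are inputs, not
    estimated from the data.
    """
    design, corr = trial.design, trial.corr
    T, m = design.n_periods, design.subjects
    days = np.asarray(design.calendar_days, dtype=float)
    info = np.zeros((T + 1, T + 1))
    xtvy = np.zeros(T + 1)
    for (cluster, arm), grp in trial.data.groupby(["cluster", "arm"], sort=True):
        grp = grp.sort_values(["period", "subject"])
        periods = np.sort(grp["period"].unique())
        h = len(periods)
        y = grp["y"].to_numpy()
        X = np.zeros((m * h, T + 1))
        for row_block, per in enumerate(periods):
            X[row_block * m : (row_block + 1) * m, per - 1] = 1.0
        X[:, -1] = float(arm)
        R = corr.decay_matrix(days[periods - 1])
        V = corr.sigma_u2 * np.kron(R, np.ones((m, m))) + corr.sigma_e2 * np.eye(m * h)
        Vinv_X = np.linalg.solve(V, X)
        info += X.T @ Vinv_X
        xtvy += Vinv_X.T @ y
    cov = _invert_information(info, T)
    estimates = cov @ xtvy
    return estimates, cov
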