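"""Ornstein-Uhlenbeck Gaussian prior and the MAP objective.

The absorption field is modelled a priori as a Gaussian with covariance

    Gamma_mu = sigma_mu^2 * Xi,     Xi(i, j) = exp(-||r_i - r_j|| / tau),

where r_i are element centroids (the natural coordinate of a
piecewise-constant parameterization) and tau is the characteristic
length in mm that controls spatial smoothness.  Given an assumed value
interval [min, max], the prior mean is the interval midpoint and the
marginal standard deviation sigma_mu = (max - min) / 6, so the interval
carries 99.7% (+-3 sigma) of the prior probability mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

from .forward import DataModel
from .mesh import Mesh2D

__all__ = ["PriorModel", "build_ou_prior", "objective"]


@dataclass
class PriorModel:
    """OU prior: mean, covariance, whitening and precision factors.

    ``L_mu`` satisfies ``L_mu^T L_mu = Gamma_mu^{-1}`` (it is the inverse
    of the lower Cholesky factor ``chol_lower`` of ``Gamma_mu``);
    ``precision`` is the assembled ``Gamma_mu^{-1}``.
    """

    eta_mu: np.ndarray
    sigma_mu: float
    tau: float
    Gamma_mu: np.ndarray
    L_mu: np.ndarray
    chol_lower: np.ndarray
    bounds: tuple[float, float]
    precision: np.ndarray = field(init=False)

    def __post_init__(self):
        self.precision = self.L_mu.T @ self.L_mu

    def whiten(self, deviation: np.ndarray) -> np.ndarray:
        return self.L_mu @ deviation

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw eta + C z with C the lower Cholesky factor of Gamma_mu
        (equivalently eta + L_mu^{-1} z)."""
        n = self.eta_mu.shape[0]
        if size is None:
            return self.eta_mu + self.chol_lower @ rng.standard_normal(n)
        z = rng.standard_normal((n, size))
        return (self.eta_mu[:, None] + self.chol_lower @ z).T


def build_ou_prior(
    mesh: Mesh2D, value_min: float, value_max: float, tau: float
) -> PriorModel:
    """OU prior on a mesh from an assumed coefficient interval.

    Distances are between element centroids.  If the Cholesky
    factorization fails numerically (near-duplicate centroids), a jitter
    of ``1e-10 sigma^2`` is added to the diagonal once before giving up.
    """
    if value_max <= value_min:
        raise ValueError("value_max must exceed value_min")
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = mesh.n_elements
    dists = squareform(pdist(mesh.centroids))
    sigma = (value_max - value_min) / 6.0
    eta = np.full(n, 0.5 * (value_min + value_max))
    Gamma = sigma**2 * np.exp(-dists / tau)
    try:
        C = linalg.cholesky(Gamma, lower=True)
    except linalg.LinAlgError:
        Gamma = Gamma + 1e-10 * sigma**2 * np.eye(n)
        try:
            C = linalg.cholesky(Gamma, lower=True)
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "OU covariance not SPD even after diagonal jitter"
            ) from err
    # L_mu = C^{-1}: L_mu^T L_mu = C^{-T} C^{-1} = Gamma^{-1}
    L_mu = linalg.solve_triangular(C, np.eye(n), lower=True)
    return PriorModel(
        eta_mu=eta,
        sigma_mu=sigma,
        tau=float(tau),
        Gamma_mu=Gamma,
        L_mu=L_mu,
        chol_lower=C,
        bounds=(float(value_min), float(value_max)),
    )


def objective(
    data_model: DataModel,
    prior: PriorModel,
    H_pred: np.ndarray,
    mu_a: np.ndarray,
) -> float:
    """MAP objective: half squared whitened data misfit plus half squared
    whitened prior deviation,

        u(mu_a) = 1/2 ||L_e (H_data - H(mu_a) - eta_e)||^2
                + 1/2 ||L_mu (mu_a - eta_mu)||^2.
    """
    H_pred = np.asarray(H_pred, dtype=float)
    mu_a = np.asarray(mu_a, dtype=float)
    if H_pred.shape != data_model.H_data.shape:
        raise ValueError("H_pred length does not match the data vector")
    if mu_a.shape != prior.eta_mu.shape:
        raise ValueError("mu_a length does not match the prior")
    r = data_model.whiten(data_model.H_data - H_pred - data_model.eta_e)
    d = prior.whiten(mu_a - prior.eta_mu)
    return 0.5 * float(r @ r) + 0.5 * float(d @ d)
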