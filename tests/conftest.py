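"""Shared fixtures: small meshes, a random-phantom factory, and the
bundled two-inclusion reconstruction problem used by the end-to-end
studies (built once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from asgn.forward import MonteCarloForward
from asgn.mc_transport import Illumination
from asgn.mesh import build_rectangle_mesh
from asgn.phantom_eval import default_phantom, make_dataset, relative_error
from asgn.prior_bayes import build_ou_prior


class LinearGaussianForward:
    """Stub forward H(mu) = A mu + noise with Var ~ 1/P.

    With ``sigma_h = 0`` the operator is deterministic (zero MC noise);
    otherwise each call adds fresh N(0, sigma_h^2 / P) noise to H, which
    makes the induced Gauss-Newton direction noise exactly Gaussian and
    analytically tractable.
    """

    def __init__(self, A, sigma_h=0.0, seed=0):
        self.A = np.asarray(A, dtype=float)
        self.sigma_h = float(sigma_h)
        self.rng = np.random.default_rng(seed)
        self.calls = 0

    def __call__(self, mu, P, with_jacobian=True):
        self.calls += 1
        H = self.A @ mu
        if self.sigma_h > 0:
            H = H + self.rng.normal(0.0, self.sigma_h / np.sqrt(P), size=H.shape)
        return H, self.A.copy()


def make_iid_prior(n, eta=0.0, sigma=1.0):
    """PriorModel with isotropic covariance sigma^2 I (for stub problems)."""
    from asgn.prior_bayes import PriorModel

    return PriorModel(
        eta_mu=np.full(n, float(eta)),
        sigma_mu=float(sigma),
        tau=1.0,
        Gamma_mu=sigma**2 * np.eye(n),
        L_mu=np.eye(n) / sigma,
        chol_lower=sigma * np.eye(n),
        bounds=(eta - 3 * sigma, eta + 3 * sigma),
    )


def closed_form_map(A, y, sigma_e, prior):
    """Gaussian linear-model posterior mean (the MAP oracle)."""
    precision = A.T @ A / sigma_e**2 + prior.precision
    rhs = A.T @ y / sigma_e**2 + prior.precision @ prior.eta_mu
    return np.linalg.solve(precision, rhs)


@pytest.fixture(scope="session")
def unit_square_mesh():
    return build_rectangle_mesh(1.0, 1.0, 2)


@pytest.fixture(scope="session")
def small_mesh():
    """~100-element mesh of a 5 x 4 mm domain."""
    return build_rectangle_mesh(5.0, 4.0, 100)


@pytest.fixture(scope="session")
def small_phantom_problem(small_mesh):
    """Small single-illumination phantom with prior, data and truth."""
    rng = np.random.default_rng(1234)
    mu_a = 0.01 + 0.04 * rng.random(small_mesh.n_elements)
    mu_s = np.full(small_mesh.n_elements, 2.0)
    ills = [Illumination("left")]
    from asgn.forward import add_noise, assemble_forward
    from asgn.mc_transport import OpticalFields

    clean, _ = assemble_forward(
        small_mesh, OpticalFields(mu_a, mu_s, 0.8), ills, 200_000, 9, with_jacobian=False
    )
    data_model = add_noise(clean, 0.01, 77, ills)
    prior = build_ou_prior(small_mesh, 0.01, 0.05, 1.5)
    return {
        "mesh": small_mesh,
        "mu_a": mu_a,
        "mu_s": mu_s,
        "g": 0.8,
        "illuminations": ills,
        "data_model": data_model,
        "prior": prior,
    }


@pytest.fixture(scope="session")
def bundled_problem():
    """The bundled two-inclusion phantom: data simulated with 1e6 packets
    per illumination on a ~1900-element mesh, interpolated to the ~800
    element reconstruction mesh, 1% noise, four planar illuminations."""
    spec = default_phantom()
    sim_mesh = build_rectangle_mesh(15.0, 10.0, 1900)
    rec_mesh = build_rectangle_mesh(15.0, 10.0, 832)
    ills = [Illumination(s) for s in ("left", "right", "top", "bottom")]
    data_model, truth = make_dataset(
        spec, sim_mesh, rec_mesh, ills, P_data=1_000_000, noise_fraction=0.01, seed=0
    )
    prior = build_ou_prior(rec_mesh, *spec.mu_a_range, tau=2.5)

    def truth_fn(mu):
        return relative_error(mu, truth["mu_a_sim"], sim_mesh, rec_mesh)

    def forward_factory(seed):
        return MonteCarloForward(rec_mesh, truth["mu_s_rec"], truth["g"], ills, seed)

    return {
        "spec": spec,
        "sim_mesh": sim_mesh,
        "rec_mesh": rec_mesh,
        "illuminations": ills,
        "data_model": data_model,
        "truth": truth,
        "prior": prior,
        "truth_fn": truth_fn,
        "forward_factory": forward_factory,
    }
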