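"""Synthetic optical phantoms, two-mesh data generation and evaluation.

Phantoms are piecewise-constant absorption/scattering maps: a uniform
background with geometric inclusions (discs, axis-aligned rectangles,
annuli).  Rasterization is by element centroid, preserving crisp
inclusion boundaries on a piecewise-constant triangulation.

Data generation avoids the inverse crime: the absorbed energy density is
simulated on a fine mesh, interpolated (conservatively) to the coarser
reconstruction mesh, and only then corrupted with additive Gaussian
noise.  The scattering truth is likewise interpolated to the
reconstruction mesh, where it is treated as known during inversion.

The reconstruction quality metric is the relative error in percent,
E = 100 * ||mu_hat - mu_sim|| / ||mu_sim||, with the estimate first
interpolated back to the simulation mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import add_noise, interpolate_pwc
from .mc_transport import Illumination, OpticalFields, as_seed_sequence, simulate
from .mesh import Mesh2D

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "RunStatistics",
    "default_phantom",
    "rasterize_phantom",
    "make_dataset",
    "relative_error",
    "repeat_study",
]


@dataclass
class Inclusion:
    """One geometric inclusion overriding the background coefficients.

    ``shape`` is ``"disc"`` (geometry = (cx, cy, r)), ``"rectangle"``
    (geometry = (x0, y0, x1, y1)) or ``"annulus"``
    (geometry = (cx, cy, r_in, r_out)); all lengths in mm.  ``mu_a`` /
    ``mu_s`` override the background where given (1/mm).
    """

    shape: str
    geometry: tuple
    mu_a: float | None = None
    mu_s: float | None = None

    def contains(self, points: np.ndarray) -> np.ndarray:
        x, y = points[:, 0], points[:, 1]
        if self.shape == "disc":
            cx, cy, r = self.geometry
            return (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.geometry
            return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        if self.shape == "annulus":
            cx, cy, r_in, r_out = self.geometry
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return (d2 >= r_in**2) & (d2 <= r_out**2)
        raise ValueError(f"unknown inclusion shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Domain size, background optics and inclusion list."""

    width: float = 15.0
    height: float = 10.0
    background_mu_a: float = 0.01
    background_mu_s: float = 2.0
    g: float = 0.8
    inclusions: list[Inclusion] = field(default_factory=list)

    def __post_init__(self):
        if self.background_mu_a < 0 or self.background_mu_s < 0:
            raise ValueError("background coefficients must be non-negative")

    @property
    def mu_a_range(self) -> tuple[float, float]:
        vals = [self.background_mu_a] + [
            inc.mu_a for inc in self.inclusions if inc.mu_a is not None
        ]
        return (min(vals), max(vals))


def default_phantom() -> PhantomSpec:
    """Bundled 15 x 10 mm phantom with tissue-plausible optics.

    Background mu_a = 0.01/mm, mu_s = 2/mm, g = 0.8; two absorbing
    inclusions (disc and rectangle, mu_a = 0.05/mm) and one scattering
    disc (mu_s = 4/mm).  The geometry and values are this package's own
    synthetic choices.
    """
    return PhantomSpec(
        inclusions=[
            Inclusion("disc", (4.5, 6.5, 1.6), mu_a=0.05),
            Inclusion("rectangle", (9.0, 2.0, 12.0, 4.2), mu_a=0.05),
            Inclusion("disc", (10.5, 7.0, 1.4), mu_s=4.0),
        ]
    )


def rasterize_phantom(spec: PhantomSpec, mesh: Mesh2D) -> OpticalFields:
    """Element-centroid rasterization; later inclusions override earlier."""
    c = mesh.centroids
    mu_a = np.full(mesh.n_elements, spec.background_mu_a)
    mu_s = np.full(mesh.n_elements, spec.background_mu_s)
    for inc in spec.inclusions:
        inside = inc.contains(c)
        if inc.mu_a is not None:
            mu_a[inside] = inc.mu_a
        if inc.mu_s is not None:
            mu_s[inside] = inc.mu_s
    return OpticalFields(mu_a, mu_s, spec.g)


def make_dataset(
    spec: PhantomSpec,
    sim_mesh: Mesh2D,
    rec_mesh: Mesh2D,
    illuminations: list[Illumination],
    P_data: int = 1_000_000,
    noise_fraction: float = 0.01,
    seed=0,
):
    """Two-mesh data pipeline: simulate fine, interpolate, add noise.

    Returns ``(data_model, truth)`` where ``truth`` holds the phantom
    fields on both meshes (``truth["mu_a_sim"]``, ``truth["mu_s_rec"]``,
    ...).  Noise is applied to the stacked data vector after
    interpolation to the reconstruction mesh; the clean vector is kept
    on the data model for diagnostics.
    """
    import logging

    if sim_mesh.n_elements < 2 * rec_mesh.n_elements:
        logging.getLogger("asgn").warning(
            "simulation mesh only %.1fx finer than reconstruction mesh; "
            "inverse-crime risk",
            sim_mesh.n_elements / rec_mesh.n_elements,
        )
    fields_sim = rasterize_phantom(spec, sim_mesh)
    streams = as_seed_sequence(seed).spawn(len(illuminations) + 1)
    blocks = []
    for ill, ss in zip(illuminations, streams[:-1]):
        res = simulate(sim_mesh, fields_sim, ill, P_data, ss, with_jacobian=False)
        blocks.append(interpolate_pwc(sim_mesh, res.H, rec_mesh))
    clean = np.concatenate(blocks)
    data_model = add_noise(clean, noise_fraction, streams[-1], illuminations)
    truth = {
        "mu_a_sim": fields_sim.mu_a,
        "mu_s_sim": fields_sim.mu_s,
        "mu_a_rec": interpolate_pwc(sim_mesh, fields_sim.mu_a, rec_mesh),
        "mu_s_rec": interpolate_pwc(sim_mesh, fields_sim.mu_s, rec_mesh),
        "g": spec.g,
    }
    return data_model, truth


def relative_error(
    estimate: np.ndarray,
    truth_mu_a_sim: np.ndarray,
    sim_mesh: Mesh2D,
    rec_mesh: Mesh2D,
) -> float:
    """E = 100 * ||mu_hat - mu_sim|| / ||mu_sim|| in percent, with the
    estimate interpolated from the reconstruction to the simulation
    mesh (identical meshes skip the interpolation)."""
    truth = np.asarray(truth_mu_a_sim, dtype=float)
    nrm = np.linalg.norm(truth)
    if nrm == 0.0:
        raise ValueError("relative error undefined for a zero truth field")
    if rec_mesh is sim_mesh:
        est = np.asarray(estimate, dtype=float)
    else:
        est = interpolate_pwc(rec_mesh, np.asarray(estimate, dtype=float), sim_mesh)
    return 100.0 * float(np.linalg.norm(est - truth) / nrm)


@dataclass
class RunStatistics:
    """Raw per-repeat results plus box-plot-ready summaries."""

    rel_errors: np.ndarray
    budgets: np.ndarray
    iterations: np.ndarray
    seeds: np.ndarray
    failures: list = field(default_factory=list)

    @property
    def summary(self) -> dict:
        e = self.rel_errors
        q25, q75 = np.percentile(e, [25, 75])
        iqr = q75 - q25
        outliers = e[(e < q25 - 1.5 * iqr) | (e > q75 + 1.5 * iqr)]
        return {
            "n": int(e.size),
            "mean": float(e.mean()),
            "std": float(e.std(ddof=1)) if e.size > 1 else 0.0,
            "median": float(np.median(e)),
            "q25": float(q25),
            "q75": float(q75),
            "outliers": outliers.tolist(),
            "mean_budget": float(self.budgets.mean()),
            "mean_iterations": float(self.iterations.mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": self.seeds,
                "rel_error_pct": self.rel_errors,
                "budget_packets": self.budgets,
                "iterations": self.iterations,
            }
        )


def repeat_study(run_once, n_repeats: int, base_seed: int = 0) -> RunStatistics:
    """Repeat a stochastic reconstruction with seeds base_seed+1..+n.

    ``run_once(seed)`` must return ``(rel_error_pct, booked_packets,
    n_iterations)``.  Individual failures are recorded (seed, message)
    and excluded from the summaries rather than aborting the study.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    errs, budgets, iters, seeds, failures = [], [], [], [], []
    for k in range(1, n_repeats + 1):
        seed = base_seed + k
        try:
            e, b, it = run_once(seed)
        except Exception as exc:  # noqa: BLE001 - study robustness
            failures.append((seed, repr(exc)))
            continue
        errs.append(float(e))
        budgets.append(int(b))
        iters.append(int(it))
        seeds.append(seed)
    return RunStatistics(
        rel_errors=np.asarray(errs),
        budgets=np.asarray(budgets),
        iterations=np.asarray(iters),
        seeds=np.asarray(seeds),
        failures=failures,
    )
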