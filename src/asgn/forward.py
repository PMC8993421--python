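"""Multi-illumination data assembly, mesh-to-mesh interpolation, noise.

The data vector stacks the per-illumination absorbed-energy densities in
illumination order, giving M = (number of illuminations) x (elements of
the data mesh) entries.  Additive noise is zero-mean i.i.d. Gaussian
with a scalar standard deviation set to a fraction of the maximum of the
noiseless data, applied after interpolation to the data mesh.

Interpolation between piecewise-constant triangulations is conservative:
each destination element receives the exact area-weighted mean of the
source values over its geometric overlap (polygon clipping with an
STRtree bounding-box prefilter), so the field integral is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import sparse
from shapely.strtree import STRtree

from .mc_transport import Illumination, OpticalFields, as_seed_sequence, simulate
from .mesh import SIDES, Mesh2D

__all__ = [
    "DataModel",
    "MonteCarloForward",
    "assemble_forward",
    "interpolate_pwc",
    "add_noise",
    "overlap_matrix",
]


@dataclass
class DataModel:
    """Noisy stacked data vector with its Gaussian noise model.

    The noise covariance is isotropic, ``Gamma_e = sigma_e^2 I``, so the
    whitening operator ``L_e`` (``L_e^T L_e = Gamma_e^{-1}``) is the
    scalar ``1/sigma_e`` times the identity.
    """

    H_data: np.ndarray
    sigma_e: float
    illuminations: list = field(default_factory=list)
    clean: np.ndarray | None = None
    seed: int | None = None
    eta_e: float = 0.0

    @property
    def M(self) -> int:
        return self.H_data.shape[0]

    @property
    def L_e(self) -> float:
        """Scalar whitening factor 1/sigma_e; undefined for sigma_e = 0."""
        if self.sigma_e <= 0:
            raise ValueError("degenerate noise model: sigma_e = 0 has no whitening")
        return 1.0 / self.sigma_e

    def whiten(self, residual: np.ndarray) -> np.ndarray:
        return self.L_e * residual


def assemble_forward(
    mesh: Mesh2D,
    fields: OpticalFields,
    illuminations: list[Illumination],
    P: int,
    seed,
    with_jacobian: bool = True,
):
    """Stacked (H, J) over the illumination list.

    Each illumination runs with an independent RNG stream spawned from
    ``seed`` and keyed to its side (so reordering the illumination list
    permutes the data blocks identically); blocks are concatenated in
    illumination order (J is block-stacked conformally, one (N x N)
    block per illumination).
    """
    if not illuminations:
        raise ValueError("at least one illumination is required")
    side_streams = dict(zip(SIDES, as_seed_sequence(seed).spawn(len(SIDES))))
    streams = [side_streams[ill.side] for ill in illuminations]
    Hs, Js = [], []
    for ill, ss in zip(illuminations, streams):
        res = simulate(mesh, fields, ill, P, ss, with_jacobian=with_jacobian)
        Hs.append(res.H)
        if with_jacobian:
            Js.append(res.J)
    H = np.concatenate(Hs)
    J = np.vstack(Js) if with_jacobian else None
    return H, J


class MonteCarloForward:
    """Stochastic forward operator ``(mu_a, P) -> (H, J)``.

    Wraps :func:`assemble_forward` for a fixed mesh, known scattering
    field and illumination set.  Every call consumes a fresh RNG stream
    spawned deterministically from ``base_seed``, so repeated evaluations
    are independent but an entire optimization run is a pure function of
    the seed.
    """

    def __init__(
        self,
        mesh: Mesh2D,
        mu_s: np.ndarray,
        g: float,
        illuminations: list[Illumination],
        base_seed,
    ):
        self.mesh = mesh
        self.mu_s = np.asarray(mu_s, dtype=float)
        self.g = float(g)
        self.illuminations = list(illuminations)
        self._seeds = as_seed_sequence(base_seed)
        self.n_params = mesh.n_elements

    def __call__(self, mu_a: np.ndarray, P: int, with_jacobian: bool = True):
        fields = OpticalFields(mu_a, self.mu_s, self.g)
        stream = self._seeds.spawn(1)[0]
        return assemble_forward(
            self.mesh,
            fields,
            self.illuminations,
            P,
            stream,
            with_jacobian=with_jacobian,
        )


def _mesh_polygons(mesh: Mesh2D):
    return shapely.polygons(mesh.node_coords[mesh.triangles])


_overlap_cache: dict = {}


def overlap_matrix(src_mesh: Mesh2D, dst_mesh: Mesh2D) -> sparse.csr_matrix:
    """Sparse matrix of clipped-polygon overlap areas, (n_dst x n_src)."""
    key = (id(src_mesh), id(dst_mesh))
    hit = _overlap_cache.get(key)
    if hit is not None and hit[0] is src_mesh and hit[1] is dst_mesh:
        return hit[2]
    lo_a = src_mesh.node_coords.min(axis=0)
    hi_a = src_mesh.node_coords.max(axis=0)
    lo_b = dst_mesh.node_coords.min(axis=0)
    hi_b = dst_mesh.node_coords.max(axis=0)
    if not (np.allclose(lo_a, lo_b, atol=1e-9) and np.allclose(hi_a, hi_b, atol=1e-9)):
        raise ValueError("meshes have different bounding boxes")
    src_polys = _mesh_polygons(src_mesh)
    dst_polys = _mesh_polygons(dst_mesh)
    tree = STRtree(src_polys)
    dst_idx, src_idx = tree.query(dst_polys, predicate="intersects")
    areas = shapely.area(shapely.intersection(dst_polys[dst_idx], src_polys[src_idx]))
    keep = areas > 0
    W = sparse.csr_matrix(
        (areas[keep], (dst_idx[keep], src_idx[keep])),
        shape=(dst_mesh.n_elements, src_mesh.n_elements),
    )
    _overlap_cache[key] = (src_mesh, dst_mesh, W)
    return W


def interpolate_pwc(src_mesh: Mesh2D, src_values: np.ndarray, dst_mesh: Mesh2D) -> np.ndarray:
    """Area-weighted piecewise-constant interpolation between meshes.

    Each destination element takes the exact overlap-area-weighted mean
    of the source values, so a constant field maps to itself and the
    integral sum(v * A) is conserved to rounding.
    """
    src_values = np.asarray(src_values, dtype=float)
    if src_values.shape[0] != src_mesh.n_elements:
        raise ValueError("src_values length does not match src_mesh")
    W = overlap_matrix(src_mesh, dst_mesh)
    total = np.asarray(W.sum(axis=1)).ravel()
    return (W @ src_values) / total


def add_noise(
    clean_data: np.ndarray,
    noise_fraction: float,
    seed,
    illuminations: list | None = None,
) -> DataModel:
    """Additive zero-mean Gaussian noise scaled to the data maximum.

    ``sigma_e = noise_fraction * max(clean_data)``; the same seed always
    yields the same realization.  ``noise_fraction = 0`` returns the
    clean data with a degenerate (whitening-refusing) noise model.
    """
    clean = np.asarray(clean_data, dtype=float)
    if clean.size == 0:
        raise ValueError("empty data vector")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    sigma = float(noise_fraction * clean.max())
    if sigma == 0.0:
        noisy = clean.copy()
    else:
        rng = np.random.default_rng(seed)
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
    return DataModel(
        H_data=noisy,
        sigma_e=sigma,
        illuminations=list(illuminations or []),
        clean=clean.copy(),
        seed=seed,
    )
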