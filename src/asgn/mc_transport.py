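"""Photon-packet Monte Carlo transport on triangular meshes.

Packets are launched on an illuminated side of the rectangle with a
cosine angular profile, scattered with the 2D Henyey-Greenstein phase
function, and absorbed continuously along their polygonal path following
the Beer-Lambert law ``w(s) = w0 exp(-int mu_a ds)``.  The per-element
absorbed optical energy density is tallied as

    H_j = (1 / A_j) * sum over path segments in j of (w_in - w_out),

per unit illumination energy (``w0 = 1/P``), so ``E{H}`` is independent
of the packet count ``P``.

Because packet paths depend only on ``mu_s`` and ``g`` (never on
``mu_a``), the absorbed energy at a fixed seed is a smooth closed-form
function of the absorption vector, and the Jacobian ``dH_j/dmu_a_k`` is
accumulated exactly along each path ("frozen paths", correlated
sampling): across a segment of length ``s`` in element ``j`` the
derivative of the packet weight is ``dw/dmu_a_k = -L_k(s) w(s)`` with
``L_k`` the path length already travelled in element ``k``, giving the
per-segment contributions

    dH_j/dmu_a_k += -(w_in - w_out) * L_k / A_j            (all visited k)
    dH_j/dmu_a_j += s * w_out / A_j                         (extra, k = j)

Boundaries are refractive-index matched (no reflection): packets
crossing a boundary edge exit.  Packets terminate when their weight
falls below ``1e-6 * w0``; the residual weight is booked to the energy
ledger (no Russian roulette, which would add variance to the Jacobian).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .mesh import Mesh2D, RaySegmentChain, trace_ray

__all__ = [
    "OpticalFields",
    "Illumination",
    "PacketState",
    "TransportResult",
    "Tallies",
    "sample_hg_deflection",
    "sample_scattering_distance",
    "launch_packet",
    "propagate",
    "simulate",
    "fluence_from_H",
    "PACKET_COUNTER",
]

W_MIN_FRACTION = 1e-6
MAX_SCATTER_EVENTS = 10_000_000


class PacketCounter:
    """Running count of simulated packet traces (for budget audits)."""

    def __init__(self):
        self.count = 0
        self.calls = 0

    def reset(self):
        self.count = 0
        self.calls = 0


PACKET_COUNTER = PacketCounter()


@dataclass
class OpticalFields:
    """Per-element absorption/scattering (1/mm) and global anisotropy.

    Physical fields have ``mu_a >= 0``; negative entries are tolerated
    (with a logged warning) because unconstrained MAP iterates can dip
    below zero and the frozen-path Beer-Lambert model extends smoothly
    to negative absorption.  ``mu_s`` must be non-negative since packet
    paths are sampled from it.
    """

    mu_a: np.ndarray
    mu_s: np.ndarray
    g: float

    def __post_init__(self):
        self.mu_a = np.ascontiguousarray(self.mu_a, dtype=np.float64)
        self.mu_s = np.ascontiguousarray(self.mu_s, dtype=np.float64)
        if self.mu_a.shape != self.mu_s.shape:
            raise ValueError("mu_a and mu_s must have equal length")
        if np.any(self.mu_s < 0):
            raise ValueError("mu_s must be non-negative")
        if np.any(self.mu_a < 0):
            logging.getLogger("asgn").debug(
                "%d negative mu_a entries in forward evaluation",
                int((self.mu_a < 0).sum()),
            )
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must satisfy |g| < 1")

    def validate_mesh(self, mesh: Mesh2D):
        if self.mu_a.shape[0] != mesh.n_elements:
            raise ValueError("field length does not match mesh n_elements")


@dataclass
class Illumination:
    """Planar illumination of one rectangle side: spatially uniform over
    the side, angularly cosine-weighted over inward directions."""

    side: str

    def launch_arrays(self, mesh: Mesh2D):
        cache = getattr(self, "_launch_cache", None)
        if cache is not None and cache[0] is mesh:
            return cache[1]
        edges = mesh.boundary_edges_on_side(self.side)
        if not edges:
            raise ValueError(f"no boundary edges on side {self.side!r}")
        ne = len(edges)
        elem = np.empty(ne, dtype=np.int64)
        ax = np.empty(ne)
        ay = np.empty(ne)
        bx = np.empty(ne)
        by = np.empty(ne)
        nx = np.empty(ne)
        ny = np.empty(ne)
        lens = np.empty(ne)
        for i, (j, e, outward, _side) in enumerate(edges):
            a = mesh.node_coords[mesh.triangles[j, e]]
            b = mesh.node_coords[mesh.triangles[j, (e + 1) % 3]]
            elem[i] = j
            ax[i], ay[i] = a
            bx[i], by[i] = b
            nx[i], ny[i] = -outward  # inward normal
            lens[i] = np.hypot(*(b - a))
        cum = np.cumsum(lens)
        arrays = (elem, ax, ay, bx, by, nx, ny, cum)
        self._launch_cache = (mesh, arrays)
        return arrays


@dataclass
class PacketState:
    """Transient state of one photon packet."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    element: int
    w0: float = 1.0
    path_lengths: dict = field(default_factory=dict)  # element -> mm (L_k)


@dataclass
class Tallies:
    """Accumulators shared by packets of one simulation."""

    H: np.ndarray  # absorbed energy density per element, 1/mm^2
    J: np.ndarray | None  # dH_j/dmu_a_k, 1/mm
    launched: float = 0.0
    absorbed: float = 0.0
    exited: float = 0.0
    residual: float = 0.0


@dataclass
class TransportResult:
    """Per-illumination absorbed energy density, Jacobian and ledger."""

    H: np.ndarray
    J: np.ndarray | None
    P: int
    ledger: dict
    seed: int

    def conservation_defect(self) -> float:
        led = self.ledger
        return abs(
            led["launched"] - led["absorbed"] - led["exited"] - led["residual"]
        ) / led["launched"]


def sample_hg_deflection(g: float, rng: np.random.Generator, size=None):
    """Deflection angle(s) from the 2D Henyey-Greenstein density.

    Closed-form inverse CDF of the d = 2 kernel
    ``p(theta) = (1/2pi) (1 - g^2) / (1 + g^2 - 2 g cos theta)``:
    ``theta = 2 atan(((1-g)/(1+g)) tan(pi (u - 1/2)))`` with u uniform,
    giving E{cos theta} = g.  Angles lie in (-pi, pi) with symmetric sign.
    """
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must satisfy |g| < 1")
    u = rng.random(size)
    if g == 0.0:
        return 2.0 * np.pi * (u - 0.5)
    return 2.0 * np.arctan((1.0 - g) / (1.0 + g) * np.tan(np.pi * (u - 0.5)))


def sample_scattering_distance(
    mesh: Mesh2D,
    mu_s: np.ndarray,
    start,
    direction,
    element: int,
    rng: np.random.Generator,
):
    """Draw the next scattering location along a straight leg.

    The optical depth ``T = -ln U`` is consumed element by element with
    the local ``mu_s``; the draw follows the piecewise-exponential free
    path density ``f(l) = mu_s(l) exp(-int_0^l mu_s)``.

    Returns ``(scatter_point_or_None, chain)``; the chain covers exactly
    the traversed sub-path (``None`` means the packet exits the domain).
    """
    tau = -np.log(rng.random() or np.nextafter(0, 1))
    full = trace_ray(mesh, start, direction, start_element=element)
    elements, lengths = full.elements, full.lengths
    for i, (j, ln) in enumerate(zip(elements, lengths)):
        cap = mu_s[j] * ln
        if mu_s[j] > 0.0 and tau < cap:
            s_in = tau / mu_s[j]
            pts = full.points[: i + 2].copy()
            lens = lengths[: i + 1].copy()
            lens[i] = s_in
            pts[i + 1] = pts[i] + s_in * np.asarray(direction, dtype=float)
            chain = RaySegmentChain(elements[: i + 1].copy(), pts, lens, "interior")
            return pts[i + 1], chain
        tau -= cap
    return None, full


def launch_packet(
    illumination: Illumination, mesh: Mesh2D, rng: np.random.Generator, w0: float = 1.0
) -> PacketState:
    """Sample a packet start for a planar cosine illumination.

    The position is uniform over the illuminated side (edge chosen with
    probability proportional to its length); the angle ``phi`` to the
    inward normal has density proportional to ``cos(phi)``, sampled as
    ``phi = asin(2u - 1)``.
    """
    elem, ax, ay, bx, by, nx, ny, cum = illumination.launch_arrays(mesh)
    target = rng.random() * cum[-1]
    k = int(np.searchsorted(cum, target))
    k = min(k, len(cum) - 1)
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (target - prev) / (cum[k] - prev)
    pos = np.array([ax[k] + frac * (bx[k] - ax[k]), ay[k] + frac * (by[k] - ay[k])])
    phi = np.arcsin(2.0 * rng.random() - 1.0)
    n_in = np.array([nx[k], ny[k]])
    tangent = np.array([-n_in[1], n_in[0]])
    direction = np.cos(phi) * n_in + np.sin(phi) * tangent
    return PacketState(pos, direction, w0, int(elem[k]), w0=w0)


def propagate(
    mesh: Mesh2D,
    fields: OpticalFields,
    packet: PacketState,
    rng: np.random.Generator,
    tallies: Tallies,
    w_min_fraction: float = W_MIN_FRACTION,
    max_events: int = MAX_SCATTER_EVENTS,
) -> PacketState:
    """Reference (pure Python) propagation of a single packet.

    Alternates scattering-distance and deflection draws, applies the
    Beer-Lambert weight decay per traversed segment, and accumulates the
    absorbed-energy and (if ``tallies.J`` is allocated) frozen-path
    Jacobian contributions.  The fast path for full simulations is
    :func:`simulate`, which runs the same physics in a compiled kernel.
    """
    fields.validate_mesh(mesh)
    w_min = w_min_fraction * packet.w0
    areas = mesh.element_areas
    tallies.launched += packet.weight
    events = 0
    while True:
        point, chain = sample_scattering_distance(
            mesh, fields.mu_s, packet.position, packet.direction, packet.element, rng
        )
        terminated = False
        for j, ln in zip(chain.elements, chain.lengths):
            w_out = packet.weight * np.exp(-fields.mu_a[j] * ln)
            dw = packet.weight - w_out
            tallies.H[j] += dw / areas[j]
            tallies.absorbed += dw
            if tallies.J is not None:
                for k, lk in packet.path_lengths.items():
                    tallies.J[j, k] -= dw * lk / areas[j]
                tallies.J[j, j] += ln * w_out / areas[j]
            packet.path_lengths[j] = packet.path_lengths.get(j, 0.0) + ln
            packet.weight = w_out
            if packet.weight < w_min:
                tallies.residual += packet.weight
                terminated = True
                break
        packet.position = chain.points[-1]
        packet.element = int(chain.elements[-1]) if len(chain.elements) else packet.element
        if terminated:
            return packet
        if point is None:  # boundary exit
            tallies.exited += packet.weight
            return packet
        events += 1
        if events > max_events:
            raise RuntimeError(
                "scatter-event cap exceeded; check mu_s/domain configuration"
            )
        theta = float(sample_hg_deflection(fields.g, rng))
        c, s = np.cos(theta), np.sin(theta)
        dx, dy = packet.direction
        packet.direction = np.array([c * dx - s * dy, s * dx + c * dy])


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Normalize ints / SeedSequences to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _kernel_seed(seed) -> np.uint64:
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return seed.generate_state(1, dtype=np.uint64)[0]


def simulate(
    mesh: Mesh2D,
    fields: OpticalFields,
    illumination: Illumination,
    P: int,
    seed,
    with_jacobian: bool = True,
    max_events: int = MAX_SCATTER_EVENTS,
) -> TransportResult:
    """Run P photon packets for one illumination (compiled kernel).

    Packets use independent counter-based RNG substreams derived from
    ``seed``, so the result is bit-reproducible given ``(seed, P)`` and
    ``E{H_P}`` / ``E{J_P}`` are independent of P (``w0 = 1/P``).
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    fields.validate_mesh(mesh)
    n = mesh.n_elements
    elem, ax, ay, bx, by, nx, ny, cum = illumination.launch_arrays(mesh)
    H_raw = np.zeros(n)
    J_raw = np.zeros((n, n)) if with_jacobian else np.zeros((0, 0))
    vpos = np.full(n, -1, dtype=np.int64)
    vids = np.empty(n, dtype=np.int64)
    vlens = np.empty(n)
    absorbed, exited, residual, status = _kernels.simulate_kernel(
        mesh.node_coords,
        mesh.triangles,
        mesh.element_adjacency,
        mesh.edge_origin,
        mesh.edge_normal,
        mesh.element_areas,
        fields.mu_a,
        fields.mu_s,
        float(fields.g),
        elem,
        ax,
        ay,
        bx,
        by,
        nx,
        ny,
        cum,
        int(P),
        _kernel_seed(seed),
        W_MIN_FRACTION,
        max_events,
        with_jacobian,
        H_raw,
        J_raw,
        vpos,
        vids,
        vlens,
    )
    if status == _kernels.STATUS_EVENT_CAP:
        raise RuntimeError("scatter-event cap exceeded; check mu_s/domain configuration")
    PACKET_COUNTER.count += int(P)
    PACKET_COUNTER.calls += 1
    H = H_raw / mesh.element_areas
    J = J_raw / mesh.element_areas[:, None] if with_jacobian else None
    ledger = {
        "launched": 1.0,
        "absorbed": absorbed,
        "exited": exited,
        "residual": residual,
    }
    return TransportResult(H=H, J=J, P=int(P), ledger=ledger, seed=seed)


def fluence_from_H(H: np.ndarray, mu_a: np.ndarray) -> np.ma.MaskedArray:
    """Per-element fluence ``Phi_j = H_j / mu_a_j`` (``H = mu_a Phi``).

    Entries with ``mu_a_j = 0`` are undefined and returned masked.
    """
    H = np.asarray(H, dtype=float)
    mu_a = np.asarray(mu_a, dtype=float)
    if H.shape != mu_a.shape:
        raise ValueError("H and mu_a must have equal length")
    mask = mu_a == 0.0
    phi = np.divide(H, mu_a, out=np.zeros_like(H), where=~mask)
    return np.ma.MaskedArray(phi, mask=mask)
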