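"""Photon-packet transport: samplers, propagation physics, tallies.

Statistical checks use fixed seeds and sample sizes chosen so the
Monte Carlo error sits well inside the asserted tolerance.
"""

import numpy as np
import pytest
from scipy import integrate, stats

from asgn import _kernels
from asgn.mc_transport import (
    Illumination,
    OpticalFields,
    Tallies,
    fluence_from_H,
    launch_packet,
    propagate,
    sample_hg_deflection,
    sample_scattering_distance,
    simulate,
)
from asgn.mesh import build_rectangle_mesh


def hg_density(theta, g):
    """2D Henyey-Greenstein density in the deflection angle."""
    return (1 - g**2) / (2 * np.pi * (1 + g**2 - 2 * g * np.cos(theta)))


class TestHenyeyGreensteinSampler:
    @pytest.mark.parametrize("g", [-0.5, 0.0, 0.5, 0.8])
    def test_mean_cosine_equals_anisotropy(self, g):
        rng = np.random.default_rng(42)
        theta = sample_hg_deflection(g, rng, size=1_000_000)
        assert np.cos(theta).mean() == pytest.approx(g, abs=3e-3)
        assert np.all(theta > -np.pi) and np.all(theta <= np.pi)

    def test_kernel_sampler_matches(self):
        theta = _kernels.hg_sample_batch(0.8, 123, 1_000_000)
        assert np.cos(theta).mean() == pytest.approx(0.8, abs=3e-3)

    def test_empirical_cdf_matches_quadrature(self):
        g = 0.5
        rng = np.random.default_rng(7)
        theta = np.sort(sample_hg_deflection(g, rng, size=1_000_000))
        grid = np.linspace(-np.pi, np.pi, 201)
        cdf = np.array(
            [integrate.quad(hg_density, -np.pi, t, args=(g,))[0] for t in grid]
        )
        emp = np.searchsorted(theta, grid) / theta.size
        assert np.max(np.abs(emp - cdf)) < 0.005

    def test_invalid_anisotropy_raises(self):
        with pytest.raises(ValueError):
            sample_hg_deflection(1.0, np.random.default_rng(0))


class TestScatteringDistance:
    def test_homogeneous_mean_free_path(self):
        # big domain so boundary exits are negligible
        mesh = build_rectangle_mesh(40.0, 40.0, 8)
        mu_s = np.full(mesh.n_elements, 2.0)
        rng = np.random.default_rng(3)
        start = np.array([20.0, 20.0])
        dists = []
        for _ in range(20_000):
            pt, chain = sample_scattering_distance(
                mesh, mu_s, start, (1.0, 0.0), 4, rng
            )
            assert pt is not None
            dists.append(chain.total_length)
        # exponential with mean 1/mu_s = 0.5 mm
        assert np.mean(dists) == pytest.approx(0.5, abs=1.2e-2)

    def test_two_layer_distribution_matches_piecewise_exponential(self):
        """Free-path CDF against the closed-form piecewise exponential."""
        mesh = build_rectangle_mesh(10.0, 2.0, 8)
        # layers: mu_s = 3 for x < 5, mu_s = 0.5 for x >= 5
        mu_s = np.where(mesh.centroids[:, 0] < 5.0, 3.0, 0.5)
        rng = np.random.default_rng(4)
        start = np.array([4.0, 1.0])
        draws = []
        for _ in range(5000):
            pt, chain = sample_scattering_distance(mesh, mu_s, start, (1.0, 0.0), None, rng)
            draws.append(chain.total_length if pt is not None else np.inf)
        draws = np.sort(np.asarray(draws))

        def cdf(length):
            depth = 3.0 * min(length, 1.0) + 0.5 * max(length - 1.0, 0.0)
            return 1.0 - np.exp(-depth)

        grid = np.linspace(0.01, 4.0, 60)
        emp = np.searchsorted(draws, grid) / draws.size
        ana = np.array([cdf(x) for x in grid])
        assert np.max(np.abs(emp - ana)) < 0.03

    def test_vacuum_always_exits(self, small_mesh):
        mu_s = np.zeros(small_mesh.n_elements)
        rng = np.random.default_rng(5)
        pt, chain = sample_scattering_distance(
            small_mesh, mu_s, (0.0, 2.0), (1.0, 0.0), None, rng
        )
        assert pt is None
        assert chain.terminal == "boundary"


class TestLaunch:
    def test_positions_uniform_over_side(self, small_mesh):
        rng = np.random.default_rng(6)
        ill = Illumination("bottom")
        xs = np.array(
            [launch_packet(ill, small_mesh, rng).position[0] for _ in range(10_000)]
        )
        counts, _ = np.histogram(xs, bins=10, range=(0.0, 5.0))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_cosine_angular_profile_mean(self, small_mesh):
        rng = np.random.default_rng(8)
        ill = Illumination("left")
        dots = np.array(
            [launch_packet(ill, small_mesh, rng).direction[0] for _ in range(20_000)]
        )
        # E[cos phi] under the cosine density = (pi/2) / 2 = pi/4
        assert dots.mean() == pytest.approx(np.pi / 4, abs=5e-3)

    @pytest.mark.parametrize("side,axis,sign", [("left", 0, 1), ("top", 1, -1)])
    def test_all_directions_point_inward(self, small_mesh, side, axis, sign):
        rng = np.random.default_rng(9)
        ill = Illumination(side)
        for _ in range(500):
            d = launch_packet(ill, small_mesh, rng).direction
            assert sign * d[axis] > 0  # s . n_outward < 0

    def test_missing_side_raises(self, small_mesh):
        with pytest.raises(ValueError):
            Illumination("diagonal").launch_arrays(small_mesh)


class TestPropagateReference:
    def test_zero_absorption_conserves_weight(self, small_mesh):
        fields = OpticalFields(
            np.zeros(small_mesh.n_elements),
            np.full(small_mesh.n_elements, 2.0),
            0.8,
        )
        rng = np.random.default_rng(10)
        tal = Tallies(H=np.zeros(small_mesh.n_elements), J=None)
        pkt = launch_packet(Illumination("left"), small_mesh, rng)
        propagate(small_mesh, fields, pkt, rng, tal)
        assert pkt.weight == pytest.approx(1.0, abs=1e-12)
        assert np.all(tal.H == 0)
        assert tal.exited == pytest.approx(1.0, abs=1e-12)

    def test_straight_path_beer_lambert(self, small_mesh):
        """mu_s = 0: the packet crosses straight; absorbed weight follows
        Beer-Lambert through the per-element absorption."""
        from asgn.mc_transport import PacketState
        from asgn.mesh import trace_ray

        rng = np.random.default_rng(11)
        mu_a = 0.02 + 0.08 * rng.random(small_mesh.n_elements)
        fields = OpticalFields(mu_a, np.zeros(small_mesh.n_elements), 0.0)
        start = np.array([0.0, 1.3])
        chain = trace_ray(small_mesh, start, (1.0, 0.0))
        expected_exit_w = np.exp(
            -sum(mu_a[j] * ln for j, ln in zip(chain.elements, chain.lengths))
        )
        tal = Tallies(H=np.zeros(small_mesh.n_elements), J=None)
        pkt = PacketState(start.copy(), np.array([1.0, 0.0]), 1.0, int(chain.elements[0]))
        propagate(small_mesh, fields, pkt, rng, tal)
        assert pkt.weight == pytest.approx(expected_exit_w, rel=1e-12)
        assert tal.absorbed == pytest.approx(1.0 - expected_exit_w, rel=1e-12)
        assert tal.absorbed + tal.exited == pytest.approx(1.0, abs=1e-12)

    def test_straight_path_jacobian_matches_analytic_derivative(self, small_mesh):
        """On a scatter-free path, H(mu_a) is a closed-form product of
        exponentials; the tallied Jacobian must match its derivative."""
        from asgn.mc_transport import PacketState
        from asgn.mesh import trace_ray

        rng = np.random.default_rng(12)
        mu_a = 0.05 + 0.1 * rng.random(small_mesh.n_elements)
        fields = OpticalFields(mu_a, np.zeros(small_mesh.n_elements), 0.0)
        start = np.array([0.0, 2.1])
        chain = trace_ray(small_mesh, start, (1.0, 0.0))
        elems = [int(j) for j in chain.elements]
        lens = chain.lengths

        def H_of(mu):
            """Closed-form per-element absorbed energy along the chain."""
            H = np.zeros(small_mesh.n_elements)
            w = 1.0
            for j, ln in zip(elems, lens):
                w_out = w * np.exp(-mu[j] * ln)
                H[j] += (w - w_out) / small_mesh.element_areas[j]
                w = w_out
            return H

        tal = Tallies(
            H=np.zeros(small_mesh.n_elements),
            J=np.zeros((small_mesh.n_elements, small_mesh.n_elements)),
        )
        pkt = PacketState(start.copy(), np.array([1.0, 0.0]), 1.0, elems[0])
        propagate(small_mesh, fields, pkt, rng, tal)
        step = 1e-7
        for k in set(elems):
            up, dn = mu_a.copy(), mu_a.copy()
            up[k] += step
            dn[k] -= step
            fd = (H_of(up) - H_of(dn)) / (2 * step)
            assert np.allclose(tal.J[:, k], fd, atol=1e-6)


class TestSimulate:
    def test_same_seed_bitwise_identical(self, small_mesh):
        fields = OpticalFields(
            np.full(small_mesh.n_elements, 0.02),
            np.full(small_mesh.n_elements, 2.0),
            0.8,
        )
        a = simulate(small_mesh, fields, Illumination("left"), 2000, 21)
        b = simulate(small_mesh, fields, Illumination("left"), 2000, 21)
        assert np.array_equal(a.H, b.H)
        assert np.array_equal(a.J, b.J)

    def test_energy_conservation_ledger(self, small_mesh):
        rng = np.random.default_rng(22)
        for _ in range(5):
            fields = OpticalFields(
                0.05 * rng.random(small_mesh.n_elements),
                3.0 * rng.random(small_mesh.n_elements),
                float(rng.uniform(-0.5, 0.9)),
            )
            res = simulate(small_mesh, fields, Illumination("top"), 1000, rng.integers(1 << 30))
            assert res.conservation_defect() < 1e-9
            total = (res.H * small_mesh.element_areas).sum()
            assert total + res.ledger["exited"] + res.ledger["residual"] == pytest.approx(
                1.0, abs=1e-9
            )

    def test_unbiasedness_across_packet_counts(self, small_mesh):
        """E{H_P} must not depend on P: many small runs vs one large."""
        fields = OpticalFields(
            np.full(small_mesh.n_elements, 0.03),
            np.full(small_mesh.n_elements, 2.0),
            0.8,
        )
        ill = Illumination("left")
        small_runs = np.array(
            [simulate(small_mesh, fields, ill, 1000, 1000 + s, with_jacobian=False).H
             for s in range(50)]
        )
        big = simulate(small_mesh, fields, ill, 50_000, 999, with_jacobian=False).H
        mean_small = small_runs.mean(axis=0)
        se = small_runs.std(axis=0, ddof=1) / np.sqrt(50)
        # elementwise agreement within 3 pooled standard errors, allowing
        # the expected handful of 3-sigma excursions over ~100 elements
        ok = np.abs(mean_small - big) <= 3 * se + 1e-12
        assert ok.mean() > 0.95

    def test_variance_scales_inversely_with_packets(self, small_mesh):
        fields = OpticalFields(
            np.full(small_mesh.n_elements, 0.03),
            np.full(small_mesh.n_elements, 2.0),
            0.8,
        )
        ill = Illumination("left")
        Ps = [100, 1000, 10_000]
        mean_vars = []
        for P in Ps:
            runs = np.array(
                [simulate(small_mesh, fields, ill, P, 7000 + 97 * s + P,
                          with_jacobian=False).H for s in range(20)]
            )
            mean_vars.append(runs.var(axis=0, ddof=1).mean())
        slope = np.polyfit(np.log(Ps), np.log(mean_vars), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_event_cap_raises_config_error(self):
        mesh = build_rectangle_mesh(15.0, 10.0, 50)
        fields = OpticalFields(
            np.zeros(mesh.n_elements), np.full(mesh.n_elements, 50.0), 0.0
        )
        with pytest.raises(RuntimeError, match="scatter-event cap"):
            simulate(mesh, fields, Illumination("left"), 50, 1, max_events=1)

    def test_invalid_packet_count(self, small_mesh):
        fields = OpticalFields(
            np.zeros(small_mesh.n_elements), np.zeros(small_mesh.n_elements), 0.0
        )
        with pytest.raises(ValueError):
            simulate(small_mesh, fields, Illumination("left"), 0, 1)


class TestFluence:
    def test_inverse_relation(self):
        rng = np.random.default_rng(30)
        mu_a = rng.random(40) + 0.1
        H = rng.random(40)
        phi = fluence_from_H(H, mu_a)
        assert np.allclose(phi * mu_a, H)

    def test_unit_fluence(self):
        mu_a = np.array([0.5, 1.0, 2.0])
        phi = fluence_from_H(mu_a.copy(), mu_a)
        assert np.allclose(phi, 1.0)

    def test_zero_absorption_masked(self):
        phi = fluence_from_H(np.array([0.1, 0.2]), np.array([0.5, 0.0]))
        assert not phi.mask[0] and phi.mask[1]
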