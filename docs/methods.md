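# Methods

This note documents the models, algorithms and numerical choices behind
`asgn`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the package's own design decisions lie.

## Problem setting

Quantitative photoacoustic tomography (QPAT) seeks the optical
absorption coefficient mu_a(r) from images of the absorbed optical
energy density H(r) = mu_a(r) Phi(r), where Phi is the light fluence.
The acoustic part of the problem (reconstructing H from pressure time
series) is assumed solved; the package addresses the optical inverse
problem only, with the scattering coefficient mu_s, the anisotropy g
and the illumination geometry treated as known.

The domain is a 2D rectangle (origin at the lower-left corner, x right,
y up, lengths in mm, coefficients in 1/mm) discretized by a conforming
triangulation with piecewise-constant coefficients per element.

## Forward model: photon-packet Monte Carlo

Light transport is modelled by weighted photon packets, the standard
Monte Carlo realization of the radiative transfer equation:

- **Sources.** A planar illumination covers one side of the rectangle;
  launch positions are uniform over the side and the angle phi to the
  inward normal has density proportional to cos(phi) (sampled as
  phi = asin(2u - 1)).
- **Scattering.** Free paths are drawn from the piecewise-exponential
  density f(l) = mu_s(l) exp(-int_0^l mu_s): a unit-mean optical depth
  tau = -ln U is consumed element by element along a straight ray.
  Deflection angles follow the 2D Henyey-Greenstein kernel
  p(theta) = (1 - g^2) / (2 pi (1 + g^2 - 2 g cos theta)), sampled by
  the closed-form inverse CDF
  theta = 2 atan(((1-g)/(1+g)) tan(pi(u - 1/2))); its defining moment
  is E{cos theta} = g.
- **Absorption.** Packet weight decays continuously by Beer-Lambert,
  w(s) = w0 exp(-int mu_a ds), along the polygonal path; the absorbed
  energy density tally is H_j = (1/A_j) * sum of per-segment weight
  losses in element j. With w0 = 1/P the expectation of H is
  independent of the packet count P and H is energy density per unit
  illumination energy (1/mm^2).
- **Boundaries and termination.** The boundary is refractive-index
  matched (no reflection): packets crossing it exit. Packets whose
  weight falls below 1e-6 w0 terminate, their residual weight booked to
  an energy ledger (launched = absorbed + exited + residual, exact to
  rounding). No Russian roulette is used — it would inject extra
  variance into the Jacobian. A hard cap on scattering events flags
  configuration errors (e.g. absurdly large mu_s).

### Path-length Jacobian (correlated sampling)

Because packet paths depend only on mu_s and g — never on mu_a — the
tally at a fixed seed is a smooth closed-form function of the
absorption vector, and its derivative can be accumulated exactly along
each path. With L_k(s) the path length already travelled in element k,
dw/dmu_a_k = -L_k(s) w(s), and a segment of length s in element j with
entry weight w_in and exit weight w_out contributes

    dH_j/dmu_a_k += -(w_in - w_out) L_k / A_j   for every visited k,
    dH_j/dmu_a_j += s * w_out / A_j             (additional, k = j).

These are the two closed forms obtained by differentiating the
per-segment weight loss with L_k constant across the segment for k != j
and growing linearly for k = j. The implementation is validated against
central finite differences of H under frozen paths (same seed), which
agree to ~1e-10 relative per column — far inside the 1e-5 contract.
The Jacobian is stored dense (N x N per illumination); at desk scale
(N <= ~4000) this is a few hundred MB at most and most paths touch many
elements, so sparsity is not exploitable.

The same smoothness argument is why the forward model accepts negative
mu_a entries (with a logged warning): the MAP iteration is
unconstrained and its early, noisy steps can dip below zero; Beer-
Lambert simply amplifies weight there, and the Jacobian identities
still hold. Physical phantoms always validate non-negative.

### Random numbers and reproducibility

The transport kernel uses a counter-based splitmix64 generator with one
substream per photon packet, derived from a single 64-bit seed, so a
simulation is bit-reproducible given (seed, P) and independent of
packet order. Seeds at the Python level are managed with numpy
`SeedSequence` spawning: one stream per illumination (keyed to the side
so reordering illuminations permutes data blocks identically), one
fresh stream per forward evaluation inside optimization loops. Every
entry point takes an explicit integer seed; the full pipeline is a pure
function of (configuration, seed).

### Ray traversal

Element-to-element traversal intersects the ray with the three edge
lines of the current triangle (outward-normal form) and steps across
the nearest forward-facing edge. A single absolute tolerance of 1e-12
mm governs point-on-edge tests; rays hitting a vertex (no admissible
crossing, or repeated zero-length steps) are recovered by nudging the
point 1e-9 mm forward along the ray and relocating it globally. This
sacrifices exactness on a measure-zero set of rays in exchange for
guaranteed termination.

## Observation model and inference

The data vector stacks per-illumination H fields on the data mesh
(M = #illuminations x N entries). Noise is additive zero-mean i.i.d.
Gaussian with sigma_e equal to a configured fraction (default 1%) of
the maximum of the noiseless data, applied after interpolation to the
data mesh. The absorption prior is an Ornstein-Uhlenbeck Gaussian:
covariance sigma^2 exp(-||r_i - r_j||/tau) between element centroids
(centroids because a piecewise-constant parameterization has no
canonical node), with mean and sigma derived from an assumed value
interval [min, max]: eta = midpoint, sigma = (max - min)/6, so the
interval carries 99.7% of prior mass. The characteristic length tau
(default 2.5 mm) controls spatial smoothness. A diagonal jitter of
1e-10 sigma^2 is added only if the Cholesky factorization fails.

The MAP estimate minimizes

    u(mu_a) = 1/2 ||L_e (H_data - H(mu_a))||^2
            + 1/2 ||L_mu (mu_a - eta_mu)||^2,

with whitening operators L_e = I/sigma_e and L_mu the inverse lower
Cholesky factor of the prior covariance. Gauss-Newton directions solve
the SPD system (J^T J / sigma_e^2 + Gamma_mu^{-1}) delta = rhs by dense
Cholesky; the prior precision guarantees positive definiteness, so the
normal-equations conditioning is acceptable at these scales. Steps use
alpha = 1 (no line search). The objective is logged by reusing each
iteration's simulation rather than spending an extra forward run.

Convergence is declared when the estimate differs from each of the
previous `window` = 3 estimates by less than `tol` = 10% in relative
Euclidean norm; the denominator is the current iterate's norm
(symmetric, scale-free choice).

## Adaptive packet counts: the norm test

The stochastic GN direction delta_P computed from a P-packet simulation
is a noisy version of the exact direction. Per iteration, L independent
simulations at P_i packets yield sample directions {delta^(l)}; the
elementwise means of {H^(l)} and {J^(l)} give a proxy delta_bar for the
accurate direction (it aggregates L * P_i packets). The squared
relative direction error is estimated as

    V^2 = (1/L) sum_l ||delta^(l) - delta_bar||^2 / ||delta_bar||^2,

with no finite-L bias correction: measuring spread about the sample
mean under-estimates the true second moment by the factor (1 - 1/L),
an accepted and documented bias of order 1/L. The test passes when
V^2 <= gamma^2; on failure the packet count grows by the measured
ratio, P <- ceil((V^2/gamma^2) P). If the ratio also exceeds L, even
the aggregated mean direction is deemed too noisy and one fresh
simulation at the updated P supplies the step. Packet counts are
therefore non-decreasing. Defaults: P1 = 10, L = 10, gamma = 0.6, norm
test evaluated every iteration.

Two stopping modes exist: the convergence criterion above, or a photon
budget Pb. The ledger books L * P_i per norm test and P per extra
simulation (P counts packets per illumination). In budget mode, once
the leftover budget no longer covers a norm test it is *added to the
last iteration*: the remainder is simulated at the current iterate and
pooled, packet-weighted, with that iteration's samples before the
final step. The booked total therefore never exceeds Pb and reaches it
exactly when the remainder rule fires — and the final direction never
comes from a low-packet fresh simulation, which would occasionally
wreck an already-converged estimate. A budget smaller than one norm
test degenerates to a single plain GN iteration with a warning.

## Synthetic data generation

The bundled phantom emulates a two-inclusion absorption target in a
15 x 10 mm rectangle: background mu_a = 0.01/mm, mu_s = 2/mm, g = 0.8,
a disc and a rectangle with mu_a = 0.05/mm, and one scattering disc
with mu_s = 4/mm — tissue-plausible values chosen by this package (the
phantom is synthetic; it reproduces a class of targets, not any
specific published object). Rasterization is by element centroid,
keeping inclusion boundaries crisp on the piecewise-constant mesh.

To avoid the inverse crime, data are simulated on a finer mesh
(~1900 elements) than the reconstruction mesh (~830 elements), with
structured but non-nested triangulations, then interpolated
conservatively (exact polygon-overlap area weighting, which preserves
constants and field integrals) before noise is added. The data
simulation uses 1e6 packets per illumination by default — large enough
that data noise is dominated by the configured 1% Gaussian term at
these mesh resolutions — with four planar illuminations, one per side.

What the generator does not emulate: acoustic reconstruction artefacts,
correlated or signal-dependent noise, refractive-index mismatch,
3D transport, and unknown scattering. Passing tests therefore
demonstrate correctness of the transport/inversion machinery and the
adaptive sampling logic under the stated noise model, not robustness to
those real-data effects.

## Study designs and problem sizes

The bundled studies mirror three experiment shapes: (i) convergence-
criterion mode, comparing the photon budget A-SGN needs against a
fixed-packet S-SGN; (ii) fixed-budget mode at matched budgets (S-SGN
splits Pb evenly over 10 iterations); (iii) repeated-run statistics
(box-plot summaries with 1.5 IQR outliers). The package's test suite
runs these at desk scale: one fixed dataset shared by all repeats, a
1e6-packets-per-iteration S-SGN reference computed once, 10 seeds for
the convergence-mode comparison and 20 seeds per method at budgets of
1e4 and 1e5 packets. At this scale the adaptive method reaches the
reference's relative error (~20%, dominated by the prior-smoothness
floor of the coarse reconstruction mesh) with a booked budget of a few
1e5 packets, and beats fixed-packet S-SGN at matched budgets — the
qualitative advantage expected of norm-test adaptivity.

## Known limitations

- 2D only; tetrahedral transport is out of scope.
- Derivatives with respect to mu_s (perturbation Monte Carlo) are not
  implemented; scattering must be known.
- Dense N x N Jacobians and O(N^2) prior factorizations cap practical
  mesh sizes at a few thousand elements.
- The norm-test estimator's (1 - 1/L) bias is uncorrected (by design);
  at L = 10 it under-estimates V^2 by 10%, slightly delaying packet
  growth.
- Relative-error floors are phantom- and mesh-dependent; absolute error
  values are not comparable across phantoms.
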