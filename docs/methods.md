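# Methods

`sprbayes` estimates the active analyte concentration and the kinetic rate
constants of a 1:1 surface-binding reaction from a single SPR sensorgram
recorded under partial mass-transport limitation, by Bayesian inference on
a quasi-steady-state (QSS) transport/binding ODE.

## Process model

Analyte transport from the bulk flow to the sensor surface and binding to
the immobilised ligand form a two-compartment system,

    hdiff d[As]/dt = kM_linear ([A0] − [As]) − (binding flux),
    dAB/dt         = ka [As] ([Bmax] − [AB]) − kd [AB],

with `[As]` the analyte concentration in a surface layer of height
`hdiff`.  Setting the surface balance to zero (QSS) and rewriting the
complex density in response units R (via the instrument factor
G ≈ 1000 RU·mm²/ng and the analyte molecular weight) collapses this to a
single ODE:

    dR/dt = (ka [A0] (Rmax − R) − kd R) / (1 + ka (Rmax − R)/kM),

where `kM` (RU M⁻¹ s⁻¹) is the mass-transport coefficient rescaled to
response units, `kM = kM_linear · MW · G · 1e6`.  During dissociation
`[A0] = 0` and the initial level R0 is a free parameter.  The surface
relaxation time `hdiff/kM_linear` is ≪ 1 s for realistic configurations,
which is why the QSS reduction tracks the full two-compartment solution to
better than 1% after the first second (verified against a stiff LSODA
integration of the unreduced system; the reduction's fixed point is exact
by construction).

The degree of transport limitation is summarised by the mass-transport
limit coefficient MTLC = ka·Rmax/kM.  The method's working regime is
partial limitation (MTLC ≈ 1–100): there the transport term couples the
curve shape to the absolute concentration, which is what makes `A0`
estimable without a calibration series.  Below MTLC ≈ 1 the model
approaches ideal Langmuir binding, where only the compound quantities
ka·[A0], kd and the equilibrium level are identified; above MTLC ≈ 100 the
rise carries transport information only, and ka, kd are individually lost
while KD = kd/ka survives.  The curve is exactly invariant under
(ka, A0, kM) → (c·ka, A0/c, c·kM), which the tests use as an
identifiability oracle.

## Transport physics

`kM_linear = C_kM (D² F / (h² w l))^{1/3}` with the detection-window
factor `C_kM = 1.47 (1 − (l1/l2)^{2/3})/(1 − l1/l2)` ∈ (0.98, 1.47];
`hdiff = (D h² w l / F)^{1/3}` (pure cube root, no hidden prefactor — the
only consumer is the two-compartment reference model, and the two formulas
then satisfy the identity `hdiff · kM_linear = C_kM · D`).  When the
detection-window positions are unknown (SensiQ, ProteOn) the default
l1 = 0, l2 = l gives C_kM = 1.47, which reproduces the documented SensiQ
value kM = 1.03e7 RU/(M·s) for the 201.2 Da analyte 4-CBS within ~2%.

When no diffusion coefficient is supplied it is estimated by
Stokes–Einstein, `D = kB T/(6π η r)` with
`r = (3 MW v̄ /(4π NA))^{1/3}`.  The effective specific volume defaults to
`v̄ = 1.7174e-3 m³/kg`, calibrated once so that MW = 201.2 Da gives
D = 4.76e-10 m²/s at 298.15 K in water (η = 8.9e-4 Pa·s).  This is an
effective value — roughly twice a bare protein partial specific volume —
because it absorbs hydration and shape effects; it is user-overridable,
and `D` can always be given directly.

Unit conversions happen once at the boundary
(`FlowCellGeometry.from_instrument`): mm → m and µl/min → m³/s exactly
(50 µl/min = 8.333e-10 m³/s).

## Statistical model and priors

Measurements are iid Gaussian around the model curve,
R_i = r(t_i, θ) + ε_i, ε_i ~ N(0, σ²), giving the usual Gaussian
log-likelihood over both phases.  The parameter vector is
θ = {ka, kd, A0, Rmax, R0, σ²}; the sampler works with A0 in nM.

Priors: truncated normals on the five curve parameters, inverse-gamma
(0.1, 0.1) on σ².  Defaults (location, sd, support):

| parameter | prior | support | character |
|---|---|---|---|
| ka | N(5e11, 1e12) | [1e2, 1e12] M⁻¹s⁻¹ | flat |
| kd | N(50, 10) | [1e-7, 1e2] s⁻¹ | flat below ~1 s⁻¹ |
| A0 | N(50, 10) nM | [1e-3, 1e6] nM | weakly informative |
| Rmax, R0 | N(5e4, 1e5) | (0, 1e6] RU | flat |

Two scale conventions deserve comment.  First, the conventional ka
hyperparameters (centre 5e11, second argument 1e12) are only diffuse if
the second argument is read as a standard deviation; as a variance it
would give sd 1e6 and crush the likelihood, so the sd reading is used
(likewise for Rmax and R0, where an sd of √1e5 ≈ 316 would exclude
realistic capacities of tens of RU).  Second, and in contrast, the A0 and
kd kernels use sd = 10 (the square root of the conventional 10²).  For kd
this is inconsequential.  For A0 it is deliberate and load-bearing: the
likelihood surface carries a connected ka–A0–Rmax ridge whose degenerate
end (ka → 0, A0 → ∞ with ka·A0 and Rmax compensating — an effective
pseudo-first-order model) can match noisy data as well as, occasionally
better than, the true basin.  The N(50, 10²) nM concentration prior is
what excludes that branch.  Users analysing samples far from the tens-of-nM
range must re-centre this prior; it is a genuine modelling input of the
method, not a formality.

The σ² full conditional is conjugate: InvGamma(0.1 + n/2, 0.1 + SSR/2).
(The conventional writing of this kernel carries a factor-of-two slip
relative to the stated InvGamma(0.1, 0.1) prior; the stated prior wins.)
A distributional test verifies the conjugate draw against ARMS applied
directly to the kernel.

## Sampler

A systematic-scan Gibbs cycle updates ka, kd, A0, Rmax, R0 — each by
adaptive rejection Metropolis sampling (ARMS) from its univariate full
conditional, always conditioning on the freshest values — and closes with
the exact conjugate σ² draw.  ka and kd are sampled on log10 scale (their
supports span ten decades; the Jacobian is included), the rest natural.

ARMS builds a piecewise-linear envelope of the log-conditional from
secants through evaluated points (on the interval between adjacent
abscissae i, i+1: max(chord(i,i+1), min(chord(i−1,i), chord(i+1,i+2))),
outermost chords extended to the support bounds), samples the
exponentiated envelope by inverse CDF, refines the envelope with every
rejected point, and applies a final Metropolis accept/reject against the
current value.  The correction is always applied, so the draw is exact
even where the target is not log-concave and the envelope fails to
dominate.

One correctness constraint shaped the implementation: the envelope may
depend on the conditioning coordinates but must not depend on the current
value of the coordinate being updated — seeding abscissae around (or at)
the current point makes env(x_prev) = h(x_prev), degenerates the
Metropolis ratio to always-accept, and demonstrably biases the chain
along the posterior ridge.  Envelope seeds are therefore anchored to the
run initialiser, and re-anchored exactly once, at burn-in, from the
pre-burn-in samples (adaptation frozen before any retained draw).
Statistical exactness is covered by moment tests (truncated normal,
exponential, a bimodal mixture) and, during development, by agreement
with an independent ensemble sampler on the full posterior.

Defaults: M = 5000 iterations, burn-in M/2, 5 initial abscissae, envelope
capped at 50 points.  Summaries are posterior means and central 95%
percentile intervals; KD is summarised from the per-iteration kd/ka ratio.

### Initialisation

For file-based fits the chain starts at a multi-start Nelder-Mead
posterior-mode estimate: starts spread over a log-ka grid with kd seeded
from the dissociation decay and A0 matched to the observed initial slope,
ranked by SSR, then polished on SSR/(2σ̂²) − log prior (the prior term
keeps the mode off the prior-excluded ridge end).

For scenario replication (`fit_scenario`) the default is to start at the
scenario's generating parameters.  This mirrors the original
operator-supplied-initials workflow and matters for honesty about the
low-MTLC scenarios: at 60+60 s the case-iii (MTLC = 1) profile
log-likelihood is flat to ±0.03 across A0 ∈ [25, 40] nM with ka sliding
correspondingly, so the data cannot select a ridge point and the chain
characterises the neighbourhood it starts in.  Reported recoveries in
that regime certify consistency ("the posterior retains the truth"), not
identification.

## Synthetic data

The generator adds iid N(0, sd²) noise to the forward curve.  The
standard eight-scenario design holds A0 = 30 nM, Rmax = 31.5 RU,
kM = 3.15e7 RU/(M·s) and KD = 1 nM while ka sweeps
{1e5 … 3e8} M⁻¹s⁻¹, so MTLC sweeps {0.1 … 300}; noise sd = 1.5 RU
(Proteon-class; Biacore/SensiQ are quieter).  The grid is 60 s
association + 60 s dissociation at 10 Hz (1200 points); the dissociation
clock restarts at the injection stop, and the simulated R0 is the
association endpoint so the noise-free phases join continuously.  The
10 Hz rate is an instrument-realistic acquisition rate chosen because it
supports the posterior precision this design is expected to deliver: at
1 Hz (120 points) the case-iv ka posterior spans more than a decade and
no tight recovery is possible (verified with two independent samplers).

What the generator does not emulate: baseline drift, bulk refractive
index jumps, spikes, autocorrelated or heteroscedastic noise, ligand
heterogeneity or bivalent binding, depletion of the bulk analyte.
Passing recovery tests on this generator therefore demonstrates the
estimator's behaviour under the model's own assumptions, not robustness
to real-instrument artifacts; background subtraction is assumed done
upstream.

## Numerics

The forward curve is integrated by classical fixed-step RK4 with the data
timestamps as knots (no interpolation at likelihood points) and a default
of 4 substeps per interval.  On the 10 Hz default grid a single substep
(h = 0.1 s) is accurate to < 1e-7 RU across all eight scenarios, so
scenario fits use `rk4_substeps=1`.  The kernel is numba-compiled (a fit
evaluates ~10⁵ curves).  Responses crossing Rmax by more than a 1e-9
relative tolerance make the likelihood −∞ (the proposal is rejected, not
raised); inside the integrator the transport denominator clamps
Rmax − R at zero.  Envelope masses are accumulated in log space with
expm1/log1p forms stable for near-zero chord slopes.

Problem sizes in the shipped tests and acceptance script: single fits use
M = 5000 on 1200-point sensorgrams; the regime study uses 20 replicates of
scenarios iii–vi plus the boundary scenarios at M = 2000, sizes chosen as
the smallest at which the checks are statistically meaningful.

## Known limitations

- Coordinate-wise sampling mixes slowly along the ka–A0–Rmax ridge; at
  MTLC ≲ 1 the reported credible intervals reflect local exploration
  around the chain's start (an ensemble sampler shows the flat-plateau
  width instead).  This matches the behaviour of the original
  implementation of the method; treat low-MTLC interval widths with
  caution.
- Single-sensorgram likelihood only: no joint multi-curve or
  multi-concentration fitting, no model comparison, no hierarchical
  pooling.
- The A0 prior is part of the model (see above); grossly mis-centred
  priors will bias A0 when the data are only weakly transport-limited.
- kM is treated as known from geometry and D; errors in D propagate
  directly into A0 (the product kM·A0 is what the early curve pins down).
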