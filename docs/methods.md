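# Methods

This note records the model definitions, parameter conventions, numerical
schemes and design decisions behind `critnet`, and states what the desk-scale
experiments do and do not establish.

## Spiking network

Each neuron is a conductance-based leaky integrate-and-fire unit,

    τ_m dv/dt = (v_L − v) + g_e (V_Re − v) + g_i (V_Ri − v),

with conductances in units of the leak conductance (g_L ≡ 1, so
C = τ_m g_L). Defaults: v_th = −50 mV, v_rest = v_L = −65 mV,
V_Re = 0 mV, V_Ri = −80 mV, τ_m = 20 ms, τ_syn = 5 ms for both channels.
A spike at v ≥ v_th resets the membrane to v_rest immediately; there is no
refractory period, so the model has no intrinsic single-neuron rate
ceiling (see "high-activity state" below). Each presynaptic spike of
weight w increments the matching conductance by w·g0, which then decays
exponentially with τ_syn. External drive is an independent Poisson train
per neuron delivered through the excitatory channel with weight
w_ext = 0.54.

**Weight unit.** The model fixes its weight scale by the synchronous-spike
convention: g0 is set (g0 = 0.22771…) so that exactly 14 simultaneous
excitatory spikes of weight 0.54 depolarize a resting neuron to threshold,
computed by fine-step integration of the single-neuron equation. This puts
the reference weight tables (w_EE = 0.54 or 0.74, w_EI = 1.5 or 2,
w_IE = 0.75, w_II = 2) and the "10–20 synchronous spikes reach threshold"
calibration band on one common scale; `calibrate_weights` inverts the same
computation for any target count. Both conductance increments use the same
g0; with that choice the reference table satisfies the slope-matching
condition c_EE c_II ≈ c_EI c_IE (within ~4%) at mid-interval potentials,
which is the reason the table places the network near the BT point.
Weights are log-normal with coefficient of variation 0.2.

**Wiring and desk scaling.** Every neuron of class x receives exactly
k_xy in-edges from class y. The full-scale reference is N_E = 2·10⁴,
N_I = N_E/4, k_EE = k_IE = 200, k_EI = k_II = 50. Desk-scale runs keep
the *in-degrees fixed* and reduce N (default N_E = 2000): each neuron's
input statistics — and hence the coupling coefficients k_xy·w_xy that set
the operating point — are unchanged, at the cost of a denser connection
probability (10% instead of 1%) and correspondingly stronger shared-input
correlations. Scaling the degrees with N instead (k ∝ N) weakens the
recurrent coupling tenfold and demonstrably destroys the phenomena under
study (the network becomes a shot-noise-driven Poisson ensemble with no
avalanche propagation and no high-activity state), so degree-preserving
reduction is the package's scaling rule. Consequences of the extra
density are flagged below where they matter.

**Integration.** Exponential-Euler throughout, default dt = 0.1 ms:
conductances decay by the exact factor exp(−dt/τ_syn); the membrane
relaxes exactly toward its instantaneous conductance-weighted equilibrium
V∞ = (v_L + g_e V_Re + g_i V_Ri)/(1 + g_e + g_i). The exact membrane
relaxation matters: a forward-Euler voltage step violates its stability
bound once g_tot ≳ 2τ_m/dt (routinely exceeded during bursts) and
fabricates locked firing states that the true dynamics does not have.
Threshold is checked after the update; conductance jumps from a spike are
applied at the start of the next step (zero axonal delay). Near the
critical regime the population rate retains a visible O(dt) bias through
the one-step propagation delay and threshold discretization; it converges
to ~2% only below dt ≈ 0.025 ms, which is what the convergence test uses.
Production statistics (exponents, branching ratios) were checked to be
stable between dt = 0.1 and finer steps.

**Plasticity.** STDP is pair-based and all-to-all via exponential traces:
Δw = +A₊ e^(−Δt/τ₊) for post-after-pre (Δt ≥ 0, coincident spikes
included) and −A₋ e^(Δt/τ₋) otherwise, with the kernel chosen by the
*presynaptic* population: E-type for E→E and E→I synapses, I-type for
I→E and I→I. Defaults τ± = 20 ms; E-type A₋/A₊ = 1.05 (negative kernel
integral), I-type A₋/A₊ = 0.95 (positive), the sign pattern required for
drift toward the balanced state; amplitudes are free (only the signs are
constrained by the theory) and default to A₊ = 10⁻³ per pair. Weights are
clipped to [0, 4×initial class mean]. The trace realization is exact: its
totals equal exhaustive all-pairs summation to 10⁻¹⁰ on 1 s records.
Short-term depression acts on E→E synapses only, one resource variable u
per presynaptic excitatory neuron shared by its out-edges: each spike
multiplies u by (1−q) (transmission uses the pre-spike value) and u
recovers toward 1 with τ_STP (defaults q = 0.3, τ_STP = 10·τ_syn = 50 ms).
Under Poisson firing at rate ρ the mean efficacy is
⟨u⟩ = 1/(1 + τ_STP q ρ).

**Correlation inflation at desk scale.** In the averaged weight-evolution
equations the rate-product drift (∝ kernel integral) competes with causal
pre-post correlation terms. In a degree-preserving desk network the
pairwise correlations are ~10× the full-scale ones, and with
near-symmetric kernels the correlation terms dominate: simulated STDP
drives w_IE up and w_EI down regardless of initial conditions, away from
the balance manifold (raising the kernel asymmetry to compensate
destabilizes the inhibitory pathway instead). The packaged
self-organization experiment therefore demonstrates the approach to
balance through the depression channel — the efficacy drop in
W_EE^eff = u·w_EE carries |ΔW| = |u w_EE w_II − w_EI w_IE| from its
unbalanced initial value to a low plateau within a few hundred
milliseconds — with STDP active at small amplitude. Full-scale sparse
networks, where the drift/correlation balance is the one analyzed, are
outside desk runtime; this is the main thing the passing tests do *not*
establish about the full-scale model.

## Mean-field layer

Stationary rates solve ρ_x = φ_x(z_x) with
z_x = c_xE ρ_E + c_xI ρ_I + d·ρ_ext^x, c_xy = c·k_xy·w_xy·(V_R^y − ⟨V_x⟩)
and d = g_L(v_rest − v_th)/(τ g0 (v_th − V_Re)) ≈ 0.263. The mean
potential ⟨V_x⟩ is the conductance-weighted average of v_L, V_Re, V_Ri at
the given rates — clamped at v_th, because the reset bounds the
time-averaged potential of a spiking neuron; without the clamp the
formula drives ⟨V⟩ → V_Re at high rates and spuriously extinguishes the
driving force of E→I coupling. The in-degree factors k_xy are included in
the conductance loads (the printed form of the potential average omits
them, but the total mean conductance of k inputs is k·w·ρ·τ·g0).

The gain φ is a parameterized stand-in for the single-neuron transfer
function (whose first-principles derivation is out of scope):
φ(z) = ρ_max (1 − exp(−s·softplus_β(z − z_th)/ρ_max)), zero below
threshold, slope-s linear mid-section, saturating at ρ_max = 500 Hz.
The global scale c = τ g0 /(1000 (v_th − v_rest)) makes z a rate-like
quantity. Per-population thresholds/widths are calibration constants,
fixed once so that the model's low-rate fixed point at the avalanche
reference (drive 230/150 Hz, u ≈ 0.81) matches the reference spiking
simulation's (ρ_E, ρ_I) ≈ (13, 35) Hz: gain_E (z_th 80, β 10, s 10),
gain_I (z_th 43, β 6, s 10). They are held fixed everywhere else.

Fixed points are found by seeding Newton iterations from a dense residual
grid over [0, 1.2 ρ_max]², merging duplicates within 10⁻³ Hz, classifying
by the numerically differentiated Jacobian, and labeling the regime
(Q/L/M/H) by the rate and the gain section the input falls in. BT
residuals are the slope condition c_EE c_II − c_EI c_IE and the intercept
condition ρ_ext^E − [(c_EE/c_IE)(ρ_ext^I − d) + d]; `locate_bt` minimizes
their normalized squares rather than solving exactly, since the
linearized conditions are themselves approximate.

**High-activity state.** Without depression the reference weight table at
drives 240–380 Hz has a high-rate attractor. In the spiking model this
state has no finite rate: with instant reset and no refractory period the
saturated network fires once per integration step at any step size (the
rate cap of the original statement lives in the gain function's maximal
rate). The no-depression experiment therefore reports the rate-ODE
attractor average over the reference drives (240, 280, 380 Hz); at
240 Hz the calibrated model retains only the low state (~20 Hz; the high
branch appears between 240 and 280 Hz), and the per-drive values
(20/397/461 Hz) are written alongside their mean. A short spiking run is
available as a qualitative check that the no-depression state is far
above the depression-stabilized regime.

## Fluctuation layer

The microscopic model gives each of N_E (N_I) units an active/inactive
state: deactivation at rate α = 1/τ_m per active unit, total activation
flux N_X f_X(ε, ι) with ε = n_E/N_E, ι = n_I/N_I, so the deterministic
limit is exactly dε/dt = f_E − αε. Gillespie simulation is statistically
exact (compiled path for affine f; arbitrary callables in Python). The
linear-noise stationary covariance solves the Lyapunov equation
A Σ + Σ Aᵀ + B = 0 with B = 2α·diag(ρ_E, ρ_I), because at stationarity
the birth and death fluxes are each α·ρ. Row-reduced this is the 3×3
system with right-hand side −α(ρ_E, ρ_I, 0) — note the prefactor −α, not
−α/2: the decoupled limit must be Poisson (Var(ε) = ρ_E for
A offdiagonals zero and A₁₁ = −α), which the exact birth–death law and
the Gillespie tests confirm; the −α/2 variant would give half-Poisson
variance. The closed form is

    Var(ε) = c[(det A + A₂₂²) ρ_E + A₁₂² ρ_I],  c = −α/((tr A)(det A)),

and cyclic analogues; variances are linear in the rates and diverge as
trace → 0 or det → 0 — the fluctuation signature of the BT neighborhood.
Singular systems raise a near-criticality diagnostic rather than divide.

## Field layer

Linear stability of the reaction–diffusion system is read from the
eigenvalues of (L − k²D). The excitatory field obeys the DP Langevin
equation ∂_t E = γE + DΔE − uE² + ψ with ⟨ψψ'⟩ = (2σ²/N)Eδδ and u > 0
(the saturating sign; the rescaling E = λS with λ = σ/√(uN) maps the
noise to the standard DP form 2u'S with u' = uλ, leaving γ and D
unchanged, so γ = 0 is the critical point in either variable).

The square-root multiplicative noise is *not* integrated by
Euler–Maruyama with truncation: clipping negative excursions at zero
injects mass exactly where extinction should happen, and at the study's
noise scales the critical field then never reaches the absorbing state
(measured: every seeded avalanche survived to the step cap). Instead the
linear-drift-plus-noise part is propagated through its exact transition
density — E' = Gamma(Poisson(λ E e^(γdt)))/λ with
λ = γ/(s(e^(γdt) − 1)), s the per-site noise scale — which preserves the
absorbing state exactly and reproduces the square-root diffusion's mean
and variance to closed form; diffusion, saturation and drive follow by an
Euler step (operator splitting, O(γ·dt) bias at the deterministic fixed
point). Avalanches are seeded point perturbations integrated until the
lattice-summed activity falls below 10⁻⁶; size is the space–time integral
of activity. With weak saturation the summed field is the critical
branching diffusion, and the measured size exponent is 1.47 ± 0.01
(mean-field DP value 3/2). The depression-coupled field replaces γ by
(−α + Ω)/τ_m with dΩ/dt = (Ω₀ − Ω)/τ_STP − qΩE; its homogeneous
stationary state is the intersection of Ω = Ω₀/(1 + qτ_STP E) with
uE = Ω − α, and with Ω₀ close to α the stationary linear coefficient
−α + Ω_st is a small fraction of Ω₀ − α: self-organized proximity to the
critical line. Long-run simulated means match the intersection to the
Monte-Carlo error.

## Avalanche statistics

Detection bins the merged spike train on an absolute grid and extracts
maximal runs of non-empty bins; every spike belongs to exactly one
avalanche. The default bin is the mean inter-event interval, never finer
than the simulation step (same-step spikes are simultaneous by
construction). The avalanche *experiment* uses a 0.5 ms bin — the
measured median monosynaptic descendant latency of this model (pre→post
spike lag within a τ_syn window), i.e. one causal generation per bin;
exponents were checked across bins 0.1–1 ms.

Power-law fitting: (i) linear regression of the log CCDF over distinct
sizes between x_min and the 99th percentile (exponent = slope + 1,
bootstrap standard errors) — note the exact discrete law is curved below
x ≈ 10, so generator-recovery checks regress above that region; (ii)
discrete maximum likelihood with Hurwitz-zeta normalization and KS-minimal
x_min selection, the preferred estimator. Both recover generator
exponents {1.3, 1.5, 2.0} at n = 10⁵ within three standard errors.

Branching ratio: the bin-ratio estimator averages n(t+1)/n(t) over
within-avalanche consecutive bins *including the terminating transition
to zero* — conditioning on non-empty successors inflates the mean (for a
Galton–Watson process the inclusive estimator is unbiased: it recovers
m = 0.8 and m = 1 fixtures exactly). The causal-descendant estimator
attributes each postsynaptic spike fractionally (by synaptic weight)
among its presynaptic drivers within a τ_syn window and averages the
credit per spike; it implements the "set to fire by the presynaptic
input" definition and reads 0.994 ± 0.002 in the avalanche regime.
Shape collapse rescales mean per-duration profiles as t/T and T^(1−g),
minimizing the normalized spread over g; size–duration scaling is the
log-log regression slope of ⟨S⟩ against T (critical value 2; durations
below ~8 generations carry a visible finite-size transient).

## Synthetic generators

Poisson trains, Galton–Watson avalanche records (Poisson or geometric
offspring; one generation per 5 ms bin, 3-bin gaps so detection recovers
the truth exactly; note E[size] equals the generation cap at m = 1, so
caps are kept modest), and discrete power-law samples via exact
inverse-transform through the zeta CDF (continuous-tail fallback above
10⁶). These fix the ground truth for every estimator without any
simulation. They emulate the *counting statistics* of critical activity,
not membrane dynamics, synapses or refractoriness — estimator tests on
them validate the statistics pipeline, not the network model.

## Experiment scales

The packaged experiments (also used by `scripts/acceptance.py`) run at:
avalanche regime N_E = 2000, ≥ 12 000 avalanches (~60 s biological time);
STDP convergence N_E = 500, 3 × 60 s at 150/150 Hz drive; self-organization
N_E = 2000, 20 s with 4 s epochs; no-depression state from the rate ODE
(4 s integrations per drive); DP field 2500 seeded trials on 64 sites.
One full acceptance run takes ~70 s on one CPU; the test suite ~6 minutes.

## Known limitations

- Desk-scale density inflates pairwise correlations ~10×; STDP-driven
  convergence to balance (as opposed to depression-driven) is not
  reproduced at this scale (see above).
- The spiking model has no single-neuron rate cap, so the saturated
  no-depression state is bounded only by the integration step; the
  mean-field gain carries the cap instead.
- The gain function is a calibrated phenomenological form; regime
  *labels* (Q/L/M/H multiplicities) are faithful, exact bifurcation
  curves are not.
- Avalanche exponents at desk scale depend mildly on the detection bin
  (CCDF 1.35–1.47, MLE 1.47–1.64 across 0.1–1 ms); both straddle 3/2
  with the causal-generation bin.
- The ring of populations is implemented and exercised qualitatively
  (synchronized avalanche epochs); quantitative spatial statistics of
  the coupled system are not studied.
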