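# Methods

This note documents the models, numerical choices and limitations behind
`pfvkit`, in the order the pipeline runs.

## Surface-confined CV simulation

The simulator treats a monolayer of adsorbed one-couple redox sites
(diffusionless regime). The oxidized fraction x obeys the two-rate site
balance dx/dt = k_ox(1 − x) − k_red·x with Butler–Volmer rates
k_ox = k_s·e^{(1−α)f(E−E°′)}, k_red = k_s·e^{−αf(E−E°′)}, f = F/RT, under a
triangular potential program. The faradaic current is i = nFAΓ_T·dx/dt
(IUPAC sign convention: anodic positive; the cathodic peak is the current
minimum). A capacitive term C_dl·A·(dE/dt) and additive i.i.d. Gaussian
noise (seeded `numpy` Generator) complete the current.

**Integrator.** The kinetics ODE is stiff in the reversible limit
(k_ox + k_red → ∞), so the update is exponential: rates are frozen at the
midpoint potential of each step and

    x_{k+1} = x_inf + (x_k − x_inf)·exp[−(k_ox + k_red)Δt],
    x_inf = k_ox/(k_ox + k_red),

which is exact for frozen rates and unconditionally stable — k_s from 0 to
10⁹ s⁻¹ integrates without step-size restrictions. Internal sub-stepping
caps the potential change per update at 0.1 mV regardless of the output
resolution (`potential_step`, default 0.1 mV). Exponent arguments are
clipped at ±700 to avoid overflow; a residual non-finite state raises a
stiffness error advising a smaller step. The current is recovered from the
propagated x by finite differences (`np.gradient`), not from the
instantaneous rate expression — in the Nernstian limit x tracks its
equilibrium value and the net-rate formula would evaluate to ~0 while the
true current is Γ_T·dx_eq/dt.

The initial condition is the Nernst-equilibrium oxidized fraction at the
start potential, which avoids a relaxation transient at the sweep edge.
Verified closed forms (tests): reversible ΔE_p < 1 mV, FWHM within 0.5 mV
of 3.53RT/nF, peak current within 0.5% of n²F²νAΓ_T/4RT, faradaic charge
equal to nFAΓ_T within 0.1%, and self-convergence of E_p to < 0.2 mV under
step halving.

**Ground truth.** Every synthetic dataset carries its generating
configuration plus the reversible-limit peak current and FWHM; a flag marks
sweep windows that fail to bracket E°′ by 150 mV on both sides (peaks then
sit too close to the edges for reliable baselines).

## Peak processing

Each sweep segment gets a linear baseline through its two flank windows
(default flank fraction 0.1 of the segment, least squares); the corrected
extremum is the peak. A warning is raised when the extremum sits inside a
flank window.

**Sub-grid refinement.** The peak potential is the vertex of a
least-squares parabola fitted over the contiguous top of the peak (points
above 90% of the maximum). On a 0.1 mV grid the classical three-point
parabola is numerically meaningless in the presence of noise — the
curvature signal over one grid step is orders of magnitude below realistic
current noise — while the windowed parabola degenerates to the same
estimator on clean data and stays stable on noisy data. When the flank
noise (1.4826·MAD) exceeds 0.2% of the peak height, the segment is
Savitzky–Golay pre-smoothed (second order, window ~2.5% of the segment)
before peak location; charges are always integrated from the unsmoothed
corrected current. For a symmetric-kinetics couple (α = 0.5) the residual
shape bias of the parabola cancels between the anodic and cathodic peaks,
leaving the midpoint unbiased (recovered within 2 mV in the tests; the
noise floor for declaring "no peak" is 3 flank-MADs).

**Charges and coverage.** Peak support runs between the zero-crossings of
the corrected current around the peak, falling back to a ±150 mV window;
trapezoidal integration over potential divided by the scan rate gives the
charge. The coverage estimator uses the cathodic charge,
Γ_0 = Q_c/(nFA) — the anodic charge is retained for the Q_a/Q_c ≈ 1
diagnostic of a well-behaved film.

**Reference scales.** SCE→SHE conversion uses a fixed +0.2412 V offset;
the temperature dependence of the reference is deliberately ignored because
the non-isothermal protocol keeps the reference electrode thermostatted.

## Reduction thermodynamics

ΔS°′_rc = nF·(slope of E°′ vs T) by ordinary least squares, assuming
ΔS°′_rc constant over the 278–318 K range; ΔH°′_rc = −nF·(slope of E°′/T
vs 1/T) per Gibbs–Helmholtz; ΔG°′_rc = ΔH°′_rc − T_ref·ΔS°′_rc, which for
noiseless linear data equals −nFE°′(T_ref) to machine precision (tested to
1 J mol⁻¹). Standard errors propagate from the regression slopes. A
Wald–Wolfowitz runs test on the residual signs (5% level, ≥ 8 points)
warns about systematic curvature. Temperatures are kelvin internally;
Celsius columns are accepted at I/O behind an explicit flag/header key.
Reported units follow convention: entropies in J mol⁻¹ K⁻¹, enthalpies and
free energies in kJ mol⁻¹.

**Compensation analysis.** ΔH°′_rc is regressed on ΔS°′_rc across
conditions. Outliers are flagged *sequentially* by externally studentized
residuals (threshold 2.5): the worst point above threshold is set aside,
the line refitted, and the test repeated while at least four points remain.
The one-shot rule fails by masking when two outliers inflate the residual
variance together; the sequential form is the standard remedy and reduces
to the one-shot rule for a single outlier. The full-sample fit is always
reported; the refit on unflagged points is reported alongside.

## pH titration

E°′(pH) = E°′_lowpH + c·Σᵢ log₁₀[(K_red,i + [H⁺])/(K_ox,i + [H⁺])], 1–3
equilibria, with pKa_red,i > pKa_ox,i. The ratio orientation is chosen so
that E°′ is non-increasing in pH and equals E°′_lowpH in the acid limit —
with pKa_red > pKa_ox the opposite orientation would make E°′ *rise* with
pH, contradicting reduction-coupled proton uptake. The acid→alkaline span
is exactly c·Σ(pKa_red,i − pKa_ox,i). The Nernst coefficient defaults to
the conventional 0.059 V per decade and can be set to 2.303RT/F at the
working temperature (0.0582 V at 293 K).

Local slope uses the closed form −c·Σ(f_red,i − f_ox,i) with
f = [H⁺]/(K_a + [H⁺]) (protonated fraction); apparent proton uptake is
−slope/c, bounded by the number of equilibria. The analytic slope is
property-tested against central differences to 10⁻⁹ V/pH.

**Fitting.** Bounded nonlinear least squares (`scipy.optimize.least_squares`,
TRF) with 50 seeded multi-starts; pKa_ox starts uniform in [3, 12]
(sorted), and the ordering constraint is built into the parameterization
pKa_red = pKa_ox + e^δ. pKa bounds are [2, 13]; points are weighted
equally; ties between equally good optima break toward the lower first
pKa_ox. Standard errors come from the Jacobian (delta method for pKa_red);
a residual-resampling bootstrap (`bootstrap_ph_fit`) is available because
overlapping equilibria leave individual alkaline pKa's weakly identified —
the bootstrap reports that honestly instead of hiding it. Parameters
landing on bounds raise a warning and are listed in the fit result.

**Pair labeling.** The fitted model is invariant under permutation of its
equilibria, so reported pairs are sorted by their mean pKa,
(pKa_ox + pKa_red)/2. Sorting by pKa_ox alone is unstable when two
oxidized-state pKa's nearly coincide (exactly the overlapping-alkaline
situation); the mean-pKa order is stable there and agrees with the
pKa_ox order whenever the pairs are well separated.

**Model-size selection** fits all three sizes and compares small-sample
AICc; with strongly overlapping equilibria the criterion may prefer two
equilibria over the generating three — that is a statement about
identifiability at the given noise, not a defect.

## ET kinetics

**Working curve.** The dimensionless trumpet relation —
ΔE_p·nF/RT as a function of m⁻¹ = (F/RT)(ν/k_s) at fixed α — is generated
numerically from the package's own simulator (noiseless, capacitance-free
CVs on a 56-point logarithmic m⁻¹ grid from 0.05 to 200), memoized
in-process, optionally persisted to CSV. The curve is strictly increasing,
→ 0 in the reversible limit, and its large-m⁻¹ slope versus ln m⁻¹
approaches 1/α + 1/(1−α) (the Laviron irreversible closed form), which the
tests verify. Because the same peak-picking path produces both the curve
and the measurements, small shape biases cancel in the inversion;
regenerating the curve at half the integration step moves inverted k_s by
< 2%.

**k_s extraction.** Default: per-row inversion of the working curve
(log-log interpolation) and geometric-mean aggregation, SE from the spread
of the per-row logarithms; rows with ΔE_p below 5 mV (quasi-Nernstian,
ill-conditioned inversion) are skipped, and an all-reversible dataset
yields a flagged lower bound instead of a point estimate. α is taken as
0.5 in this mode. The alternative irreversible-branch method fits the
linear E_p vs ln ν branches (rows with ΔE_p > 200/n mV, ≥ 3 required),
reads α from the two slopes and k_s from the scan rate at which each branch
extrapolates to E°′. The two routes agree within 20% on simulated data for
k_s ∈ [0.5, 5] s⁻¹ (tested); the `auto` mode cross-checks them and warns
above 25% disagreement.

**Arrhenius and Marcus.** ΔH‡ = −R·(slope of ln k_s vs 1/T), identifying
the Arrhenius slope with the activation enthalpy directly — the
E_a = ΔH‡ + RT correction is *not* applied, consistent with treating the
activation entropy as negligible. λ = 4ΔH‡ exactly. Tunneling distances
come from ln k_s = ln ν₀ − β(r − r₀) − ΔH‡/RT with defaults ν₀ = kT/h at
the measurement temperature, β = 1 Å⁻¹, r₀ ∈ [0, 3] Å and a
through-monolayer distance of 19 Å (all overridable); the surface-to-center
interval is (r − r₀) − d_SAM shifted by the r₀ range, floored at zero with
a warning when the geometry turns unphysical.

## Synthetic-data conditions

The generators default to the regime the analysis targets: k_s ≈ 1 s⁻¹,
α = 0.5, Γ_T = 5×10⁻¹¹ mol cm⁻² on 0.02 cm² (a ~10⁻⁸ C film), scan rates
0.02–0.5 V s⁻¹, temperatures 278–318 K, titration constants
(5.1, 7.5), (8.4, 10.9), (8.9, 11.3), potential noise ~1–2 mV, current
noise ~1% of peak. What they deliberately do **not** emulate: uncompensated
cell resistance (iR drop), coverage dispersion and intersite interactions
(non-ideal peak widths), film loss over cycling, catalytic O₂-reduction
currents, and drifting baselines beyond a linear capacitive term. Passing
tests therefore demonstrate correctness of the estimators under ideal-film
assumptions, not robustness to every experimental artifact.

Problem sizes used by the tests and the acceptance script — 0.1 mV
simulation grids, 33-point titrations, 6–8-rate trumpets, 9-point
temperature series, 200–1000-replicate Monte-Carlo checks — keep every run
in the seconds-to-a-minute range while leaving the statistical checks
well-powered.

## Known limitations

- The Laviron working curve assumes an ideal Langmuir film with a single
  k_s; dispersion in real films broadens peaks and biases k_s downward.
- The irreversible-branch method needs genuinely irreversible rows; at the
  45–95 mV separations typical of k_s ≈ 1 s⁻¹ films below 0.5 V s⁻¹ only
  the working-curve route applies.
- SCE→SHE conversion ignores the reference temperature coefficient
  (appropriate only for thermostatted-reference protocols).
- The overlapping alkaline equilibria are weakly identified at 2 mV noise;
  their pair *sum* is well determined, the individual constants carry
  bootstrap SEs of several tenths of a pKa unit.
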