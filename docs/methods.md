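# Methods

## Model

The consortium model tracks five states: population densities x₁, x₂ (OD600
units) of a tryptophan and a tyrosine auxotroph, shared glucose s⁻ (g/L),
and the two cross-fed amino acids s₁⁺ (tryptophan) and s₂⁺ (tyrosine),
both in mg/L. Growth of species i follows double Monod kinetics,
μᵢ = μᵢᵐᵃˣ · sᵢ⁺/(Kᵢ⁺+sᵢ⁺) · s⁻/(Kᵢ⁻+s⁻), and the balances are

    dxᵢ/dt  = (μᵢ − k_d,i) xᵢ
    ds⁻/dt  = −Y_{s⁻/x₁} μ₁x₁ − Y_{s⁻/x₂} μ₂x₂ + q(t)
    dsᵢ⁺/dt = −Y_{sᵢ⁺/xᵢ} μᵢxᵢ + Y_{sᵢ⁺/xⱼ} μⱼxⱼ

where q(t) is a piecewise-constant glucose supply. Slow-release feed beads
are modeled as a constant rate switched on at the addition time and held to
the end of the horizon; no bead-depletion kinetics. Units deliberately stay
mixed (g/L for glucose, mg/L for amino acids, OD for biomass) so the
default parameter values can be used verbatim; nothing in the code converts
units.

Default parameters (the fitted set for the ΔtrpC/ΔtyrA pair): μ₁ᵐᵃˣ =
0.2961 h⁻¹, μ₂ᵐᵃˣ = 0.1658 h⁻¹; K₁⁺ = 3.30·10⁻³, K₂⁺ = 3.881·10⁻⁴ mg/L;
K₁⁻ = 3.091·10⁻⁴, K₂⁻ = 3.923·10⁻⁴ g/L; k_d,1 = 1.206·10⁻⁴, k_d,2 =
4.024·10⁻⁷ h⁻¹; glucose yields 1.372 / 1.773 g/OD; own-amino-acid yields
1.550 / 2.994 mg/OD; secretion yields 1.365 (tyrosine per OD of species 1)
and 2.961 (tryptophan per OD of species 2) mg/OD; bead rates 5.580·10⁻²
(three beads) and 9.300·10⁻² g/L/h (five beads).

## Interaction coefficients

With μᵢ an explicit function of (sᵢ⁺, s⁻), the gLV coefficient is obtained
by the chain rule, aᵢⱼ = ∂μᵢ/∂xⱼ = (∂μᵢ/∂sᵢ⁺)(∂sᵢ⁺/∂xⱼ) +
(∂μᵢ/∂s⁻)(∂s⁻/∂xⱼ). The stoichiometric sensitivities are fixed by the
growth reaction: partner growth releases the focal species' amino acid
(∂sᵢ⁺/∂xⱼ = +Y_{sᵢ⁺/xⱼ}) and consumes glucose (∂s⁻/∂xⱼ = −Y_{s⁻/xⱼ}).
This yields a promotive channel aᵢⱼ⁺ ≥ 0 and an inhibitive channel
aᵢⱼ⁻ ≤ 0 in closed form for double Monod kinetics, a normalized balance
γᵢⱼ = (aᵢⱼ⁺+aᵢⱼ⁻)/(aᵢⱼ⁺−aᵢⱼ⁻) ∈ [−1, 1], and intraspecific aᵢᵢ ≤ 0 through
species i's own consumption of both substrates.

Design choices:

- Coefficients are derived from the kinetic growth rate only; the death
  rate k_d enters the dynamics but not the interaction definition.
- The basal (density-independent) growth-rate offset of the underlying
  Taylor expansion has no computable closed form in this framework and is
  not represented.
- Degenerate γ (both channels exactly zero, e.g. every substrate exhausted)
  is reported as value 0 with `defined = False` rather than NaN, so
  downstream summaries can exclude those points explicitly.
- `coefficients_from_growth_model` accepts an arbitrary growth-rate
  function with optional analytic partial derivatives (internal central
  differences otherwise), so kinetic forms beyond double Monod can be
  plugged in; the closed forms are the default fast path.
- The independent verification oracle perturbs a virtual partner density
  and differences μᵢ centrally, with a default step of 10⁻⁶ of the local
  (K + s) scale — small enough that truncation error is negligible, large
  enough that round-off does not dominate for K values down to 10⁻⁴. A step
  that would drive a concentration negative is a domain error; oracle
  agreement is therefore asserted at strictly positive concentrations.

## Numerical integration

`solve_ivp` with LSODA, rtol 10⁻⁸ / atol 10⁻⁹ by default; the small
half-saturation constants (~10⁻⁴) make the system moderately stiff near
substrate depletion. Integration restarts at every feed-event time so each
segment has a continuous right-hand side. Negative concentrations from
solver overshoot are clamped to zero inside the RHS; output states are
clamped at zero and the run aborts if any state dips below 10× the
absolute tolerance (that indicates solver failure, not round-off). Batch
runs with k_d = 0 conserve the glucose and amino-acid stoichiometric
balances to better than 10⁻⁶ relative, which the test suite enforces.

Default output: 30 h horizon on a 0.05 h grid (the longest window the
semi-batch analyses discuss); both are conventions, overridable everywhere.

## Scenario library

Co-culture scenarios start at 0.02 OD per strain (total 0.04, equal
ratio). Batch conditions: 2 g/L glucose with 1 mg/L of each amino acid
(`fig3A`, the reference), 0.5 g/L with 1 mg/L (`fig3B`), 0.5 g/L with
4 mg/L (`fig3C`); each also exists as a semi-batch variant with three
beads added at 7.5 h (`fig4A/B/C`) plus a five-bead variant
(`fig4B_5fb`). Axenic controls run at 4.5 g/L glucose with the strain's
amino acid supplemented at 20 mg/L — the midpoint of the 10–40 mg/L range
the axenic experiments spanned, since per-panel values are not available —
and `coculture_batch` is a binary batch at 4.5 g/L glucose used for
fitting exercises. Sampling defaults to hourly.

## Synthetic observations

The generator simulates a scenario exactly (the truth trajectory is kept on
the observation set for testing) and then emulates the measurement chain:
total OD and glucose receive mean-one multiplicative log-normal noise with
configurable CV (default 2%, triplicate); the species-1 fraction receives a
symmetric Beta perturbation with concentration κ (default 500) emulating
qPCR compositional error; per-species OD is reconstructed as
fraction × total, as in the real workflow. Amino-acid observations are off
by default because exchanged metabolite levels typically sit near detection
limits; when enabled they carry a 0.05 mg/L detection floor with explicit
censoring flags. Not emulated: instrument drift, sampling-volume effects,
plate-position effects, OD nonlinearity at high density, and qPCR primer
chemistry — so passing recovery tests demonstrate statistical, not
instrumental, robustness.

## Parameter fitting

The objective is a weighted sum of squared residuals over per-species OD,
total OD and glucose (amino-acid series join automatically when present in
the data); weights default to the inverse squared mean of each observable
so OD (~0.1–1) and glucose (~0.5–4.5) contribute comparably. Optimization
uses bounded trust-region least squares with a finite-difference Jacobian,
multistarted (default 8) from a seeded Latin-hypercube design;
half-saturation constants are searched in log10 space for conditioning.
Candidate simulations that fail return a large finite penalty residual so
a start is never lost to one bad region. Identical configuration and seed
give identical results.

The auxotrophy constraint is applied as a hard feasibility filter on
candidate optima, not as a penalty: (a) each strain alone without its
amino acid must show no net growth over 30 h; (b) the pair together with
glucose must achieve net growth from trace amino-acid carryover. Clause
(b) cannot use literally zero initial amino acids — zero is an absorbing
state of the deterministic model, so no parameter set could ever pass —
and instead seeds 1 µg/L of each amino acid (three orders of magnitude
below experimental supplementation), representing inoculum carryover, and
requires final growth to exceed twice what the trace alone could support.
Inside these feasibility simulations half-saturation constants are floored
at 10⁻⁶: a zero K makes the kinetics discontinuous at zero substrate and
stalls the integrator, while the floor changes growth predictions
negligibly.

Identifiability is flagged, not formally analyzed: estimates within 1% of
a bound are reported as near-bound, and parameters whose ±20% perturbation
moves the objective by less than 10⁻³ relative are reported as flat
directions (e.g. the amino-acid half-saturation of a species absent from
every dataset).

Problem sizes used by the shipped tests — three synthetic datasets
(two axenic, one binary batch) at 2% noise in triplicate, four free
parameters, four starts — recover growth-rate and glucose-yield parameters
well within 15% relative error.

## Known limitations

- Two species only; extending to more members requires growth kinetics in
  which partner effects are identifiable, which is the hard part in real
  communities.
- The gLV linearization drops higher-order terms; coefficients are exact
  sensitivities of μ, not guarantees of gLV trajectory equivalence.
- Feed beads as ideal constant sources; no depletion, no pH or temperature
  effects, no chemostat mode.
- γ sign-change summaries use linear interpolation between grid points and
  a |γ| deadband of 10⁻³ to suppress numerical chatter near zero.
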