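# Methods

## The model

`porespace` simulates how biological activity reshapes the pore system of
a soil layer. The layer is a set of partial volumes over a nominal
cross-section A_xs: mineral and organic solids (V_s(m), V_s(o)), a static
*textural* pore volume V_p(t) inherent to the closest packing of the
mineral particles, and dynamic *structural* pore volumes in three size
classes bounded at equivalent cylindrical diameters of 30 and 100 μm
(micropores, mesopores, macropores; heads −100 cm and −30 cm under the
capillary rule d·|ψ| = 3000 μm·cm). Micropores and mesopores form the
soil *matrix*; all macropores are structural. Volumes are the canonical
state; porosities, bulk density γ_b = γ_s(1−φ) and layer thickness
Δz = V_t/A_xs are always derived, so the additivity identities

    φ = φ_mat + φ_mac = φ_t + φ_s,   φ_mat = φ_mic + φ_mes

hold to machine precision by construction. The textural constants come
from a user-defined minimum matrix porosity φ_min and minimum thickness
Δz_min: V_p(t) = φ_min·Δz_min·A_xs, V_s(m) = V_p(t)(1/φ_min − 1). The
textural pore space is split a priori into micropore and mesopore shares
by f_t(mic).

### Water retention

The matrix retention curve is the van Genuchten form with zero residual
water content,

    θ(ψ) = φ_mat [1 + (α|ψ|)^n]^(1/n − 1).

`n` is texture-controlled and held constant; `α` is the dynamic shape
parameter and follows the pore pools in closed form from the requirement
θ(ψ_mic/mes) = φ_mic:

    α = [ (φ_mic/φ_mat)^(−n/(n−1)) − 1 ]^(1/n) / |ψ_mic/mes|.

Macropores lie outside the unimodal curve and are tracked volumetrically
only. Measured curves from several samples are fitted jointly with one
shared `n` (fixed or free) and per-curve (φ_mat, α), by nonlinear least
squares on concatenated residuals (scipy `least_squares`, TRF, bounds
φ_mat ∈ (10⁻³, 0.999), α ∈ (10⁻⁶, 10) on a log scale, n ∈ (1.001, 10)),
with ten multi-starts log-spaced in α because the fit surface is
multimodal in α. Points at listed pressure heads (default −2.5 cm, the
free-drainage measurement, which carries macropore storage the matrix
curve cannot represent) are excluded before fitting. Replicates can be
combined by point pooling (default: every replicate point carries its own
residual) or by replicate means; both are exposed through `pool_curves`.

A known conditioning limit: for soils with `n` close to 1 (the silt-loam
rotation fits use n = 1.08) the curve is still far from saturation at the
wettest retained head, so φ_mat is an extrapolation and trades off
against α under noise. The parameter-recovery test for noisy data
therefore uses a mid-range loam parameterization (n = 1.4); for flat
curves, recovering φ_mat to better than ~0.02 at σ_θ = 0.01 should not
be expected from this measurement design.

### Pore-change factors

Every structure-forming agent couples to the structural pore classes
linearly: dV_p(s,i)/dt = Σ_j f_ij dV_s(j)/dt, with pore-change factors
f_ij in m³ pores per m³ solids. A process whose three factors sum to −1
conserves total soil volume. The built-in table:

| process        | f_mac        | f_mes               | f_mic          |
|----------------|--------------|---------------------|----------------|
| root growth    | 0            | −s_mes              | −s_mic         |
| root decay     | −f_r(c)      | f_r(c) − 1          | 0              |
| worm casting   | −(1+ε_casts) | (1−f_casts(mic))ε_casts | f_casts(mic)ε_casts |
| worm ingestion | −(1+ε)       | s_mes·ε             | s_mic·ε        |

where ε = φ_mat/(1−φ) is the matrix void ratio, ε_casts the cast void
ratio, f_r(c) the coarse-root fraction, and s_mes, s_mic the structural
matrix shares φ_s(i)/(φ_s(mes)+φ_s(mic)). Root growth into macropores is
neglected. The macropore casting/ingestion factors are −(1+ε_casts) and
−(1+ε): only with the parenthesis does each column sum to −1 and does
the macropore balance produce the (ε − ε_casts) exchange term. Microbial
OM turnover enters through the same mechanism with a user factor
(aggregation typically 2 < f < 4), and swell/shrink as
dV_mat = f·dV_w with f ∈ [0, 1] the slope of the shrinkage
characteristic (no crack-geometry factor; matrix volume only).

When the structural matrix pools are exhausted
(φ_s(mes)+φ_s(mic) < 10⁻¹²) the ingestion shares fall back to the
textural split (f_t(mic), 1−f_t(mic)): the structural shares are 0/0
there, and textural pores are what remains to be ingested.

### Steady-flux regime and closed-form equilibrium

With casting and root biomass at steady state (E_c = E_i, R_g = R_d) the
total porosity is constant and the class porosities obey, with
A = B_r τ_r / γ_r and W = γ_b τ_s / γ_s,

    dφ_mac/dt    = f_r(c)·A + (ε − ε_casts)·W
    dφ_s(mes)/dt = (1 − f_r(c) − s_mes)·A + ((1−f_casts(mic))ε_casts − s_mes ε)·W
    dφ_s(mic)/dt = −s_mic·A + (f_casts(mic))ε_casts − s_mic ε)·W

whose rates sum to zero. Setting them to zero gives the closed form
implemented in `steady_state` (derived here directly from the rate
equations, and validated against 500-year integrations rather than
against any printed formula):

    ε*        = ε_casts − f_r(c)·A/W
    φ_mat*    = ε*(1−φ),  φ_mac* = φ − φ_mat*
    φ_s(mic)* = (φ_mat* − φ_min)·f_casts(mic)·ε_casts·W / (A + W ε*)
    φ_mic*    = φ_s(mic)* + f_t(mic)·φ_min,  φ_mes* = φ_mat* − φ_mic*

On bare soil (B_r = 0) the equilibrium matrix void ratio equals ε_casts
exactly — the matrix is eventually all cast material. The closed form can
imply φ_mat* ≤ 0 (extreme root macropore production) or φ_mat* > φ
(ε_casts exceeding φ/(1−φ)); both raise an explicit infeasibility error.

### Surface casting and compaction recovery

On bare compacted soil a fraction f_surf = max(0, 1 − φ_mac/φ_mac(c)) of
the egested casts is deposited at the soil surface: worms cast on the
surface when the soil is too compact to cast into. The factor sum then
exceeds −1 and the layer grows. With the solid ingestion flux
Q = V_t·I_r·E_bio/γ_s (cm³ solids/yr; τ_s = I_r E_bio/γ_b):

    dV_mac/dt    = Q [ε − ε_casts + f_surf(1+ε_casts)]
    dV_ps,mes/dt = Q [(1−f_casts(mic))ε_casts − s_mes ε]
    dV_ps,mic/dt = Q [f_casts(mic)ε_casts − s_mic ε]
    dV_t/dt      = Q f_surf (1+ε_casts)

Surface-cast pore volume enters the meso/micro pools with full weight
(the bioturbated layer is treated as uniform, surface casts included).
Total worm biomass is conserved as the layer grows — E_bio is a
concentration, so V_t·E_bio and hence Q are constant in time. φ_mac(c)
and ε_casts set the equilibrium macroporosity and matrix porosity;
f_casts(mic), φ_min and f_t(mic) set the micropore/mesopore split.

### Numerical integration

`integrate` uses adaptive RK45 (scipy `solve_ivp`) with a 0.05-yr step
cap and tolerances rtol = 10⁻¹⁰, atol = 10⁻¹² on the three dynamic
volumes; states at output times are rebuilt from volumes so every
porosity identity holds along the trajectory. Negative volumes within
10⁻⁹·V_t of zero are clamped (ODE round-off); larger ones raise. A
discrete parcel-moving bookkeeping simulator (excavate (1+ε)v of matrix,
leave a macropore, deposit (1+ε_casts)v of casts split by f_casts(mic)
and f_surf) lives in the test suite as an independent oracle and agrees
with the ODE rates to better than 10⁻³ relative when Euler-stepped at
dt = 10⁻⁴ yr.

The calibration objective uses a fixed-step classical RK4 fast path
(dt = 0.005 yr in the generator and tests, 0.01–0.02 yr inside the
optimizer) on the same right-hand side; it agrees with the adaptive
integrator to ~10⁻⁹ on the 4-year problem and costs ~2 ms per forward
run, which is what makes 100 optimizer restarts practical.

### Calibration

Four parameters are estimated from a compacted-plot observation series:
I_r (g soil g⁻¹ biomass day⁻¹, converted internally at 365 day/yr),
ε_casts, f_casts(mic) and φ_mac(c). Fixed quantities follow the bare-plot
configuration: φ_min = 0.35, f_t(mic) = 0.966 (the post-compaction
mesoporosity is assumed purely textural), γ_s estimated from measured
bulk density and porosity, E_bio from areal biomass (655 kg/ha over
0–30 cm ↔ 2.1833·10⁻⁴ g/cm³). Observables: γ_b, φ, θ(−30 cm) = φ_mat
(macropores drained) and θ(−100 cm) = φ_mic (only micropores filled).
Compacted values are first normalized per variable by
v_ctrl(0)/v_ctrl(t) from the nearest-in-time control observation
(tolerance 0.05 yr) to strip trends unrelated to recovery; the
operation is idempotent only for a constant control. The initial state
is read from the first observation row, with class porosities raised to
their textural floor when noise puts them below it.

The loss is a sum of squared residuals standardized per variable by the
observed standard deviation (or range when no std is supplied) —
without standardization bulk density (~1.5) would dominate porosity
residuals (~0.05). Minimization uses Powell's derivative-free
conjugate-direction method (the forward model is only piecewise smooth
through the max() in the casting rule) under bounds
I_r ∈ (0, 10], ε_casts ∈ (0, 2], f_casts(mic) ∈ [0, 1],
φ_mac(c) ∈ (0, 0.2], restarted from seeded uniform-random starts; the
full restart table is returned and its spread is the uniqueness
diagnostic. Infeasible forward runs return a large finite penalty.

## Synthetic data

`gen_retention` evaluates the retention curve of each group at a ladder
of measurement heads (default −2.5, −10, −30, −60, −100, −300, −1000,
−15000 cm, overridable), replicates it (default 12), adds independent
Gaussian noise truncated to [0, 1] (default σ = 0.01 cm³/cm³, the
magnitude of replicate-mean error bars on such data), and can add a
saturation excess at the wettest head to emulate macropore water that
the exclusion rule must discard. `gen_recovery` forward-simulates the
surface-casting model over 4 years (half-yearly sampling) from a
compacted initial state (φ_mic = 0.345, φ_mes = 0.012 ≈ the textural
mesoporosity under f_t(mic) = 0.966, φ_mac = 0.005), with generating
parameters defaulting to the calibrated field values (I_r = 2.79
g g⁻¹ day⁻¹, ε_casts = 0.714, f_casts(mic) = 0.845, φ_mac(c) = 0.057),
adds truncated Gaussian noise re-clipped to the physical ordering
θ₁₀₀ ≤ θ₃₀ ≤ φ, and emits a control series with an optional
multiplicative drift to exercise the normalization.

What the generators do not emulate: spatial heterogeneity within the
layer, seasonal swell/shrink cycles, correlated measurement errors, and
sampling-occasion effects beyond a smooth multiplicative control drift.
Passing the recovery tests therefore shows that the inverse problem is
well posed for this model and observation design — not that the model is
structurally correct for any particular field soil.

## Design choices and limitations

- Volumes are canonical because the solid-balance and casting equations
  are volume rates and V_t itself changes under surface casting.
- γ_s is the particle density throughout (it pairs with γ_b = γ_s(1−φ));
  organic solids default to zero volume but the slot exists so OM volume
  change can act as a pore-change agent.
- Layer states are homogeneous; multiple layers are multiple states.
  There is no feedback of structure on worm or root activity, no dual
  (bimodal) retention function, and no crack-geometry factor for
  swell/shrink.
- The steady-flux conservation of φ, the factor-sum theorem, scale
  invariance of porosities, and the bare-soil void-ratio identity are
  enforced as property tests (hypothesis, seeded).
- Long-horizon consistency checks integrate 500 years without the step
  cap (the system is smooth and slow; the capped and uncapped solutions
  agree to the stated tolerances, which the step-halving test verifies).
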