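# Methods

This note documents the model formulation, the rationale for every default
parameter, the numerical scheme, and the limitations of the package. Units
throughout: chlorophyll mg m⁻³, macronutrients µmol kg⁻¹, iron nmol kg⁻¹,
irradiance mol photons m⁻² d⁻¹, rates d⁻¹, depths m.

## 1. Model formulation

### State

A single mixed-layer box of depth *H(t)* carries chlorophyll biomass *Pᵢ* for
six phytoplankton functional types (diatoms, coccolithophores, chlorophytes,
dinoflagellates, cyanobacteria, phaeocystis) and four dissolved pools:
nitrate, ammonium, silicate, and iron. Total chlorophyll is the plain sum
Chl_tot = Σᵢ Pᵢ.

### Growth

µᵢ = µ_max,ᵢ · min(f_Nut,ᵢ, f_E,ᵢ) · R(T), with R(T) = 1.066^(T−20).

- Nutrient limitation is a Liebig minimum of Monod terms X/(k+X): dissolved
  nitrogen (NO₃+NH₄) and iron for every group, silicate additionally for
  diatoms. Exact ties between limitation terms resolve in the fixed order
  N, Fe, Si, so the reported "binding nutrient" label is deterministic.
- Light limitation is Monod in the mixed-layer mean PAR,
  Ē = E₀ (1 − e^(−K_PAR·H)) / (K_PAR·H), the exact depth average of
  Beer–Lambert decay. Attenuation follows the Morel relations
  K₄₉₀ = 0.0166 + 0.0773 Chl^0.6715 and
  K_PAR = 0.0864 + 0.884 K₄₉₀ − 0.00137/K₄₉₀, evaluated on total
  chlorophyll (self-shading couples the groups through light).

### Losses

- Sinking: w = w₀ (0.451 + 0.0178 T), the seawater-viscosity correction to a
  reference speed specified at 31 °C (the multiplier is ≈1 there; at 0 °C it
  is 0.451). Sinking acts as a dilution loss w/H.
- Grazing: a community-wide Ivlev specific rate
  γ = γ_m (0.06 e^(0.1T) + 0.7)(1 − e^(−Λ Chl_tot)), applied uniformly to all
  groups. Because it is one specific rate, grazing is exactly
  composition-neutral: it changes total biomass but never relative shares.

### Nutrient budgets

dPᵢ/dt = (µᵢ − γ − wᵢ/H) Pᵢ

dNO₃/dt = κ (NO₃_deep − NO₃) − φ_NO₃ Σᵢ µᵢ Pᵢ r_N
dNH₄/dt = ε γ Σᵢ Pᵢ r_N − φ_NH₄ Σᵢ µᵢ Pᵢ r_N
dSi/dt  = κ (Si_deep − Si) − µ_diat P_diat r_Si
dFe/dt  = κ (Fe_deep − Fe) − Σᵢ µᵢ Pᵢ r_Fe + ε γ Σᵢ Pᵢ r_Fe

where r_N, r_Si, r_Fe are fixed nutrient-to-chlorophyll uptake ratios,
φ_NO₃ = NO₃/(NO₃+NH₄) splits nitrogen uptake in proportion to pool sizes
(φ_NH₄ = 1 − φ_NO₃), and ε is the recycled fraction of grazed nitrogen and
iron (one shared constant for both — one fewer free parameter with the same
budget-closure property). Ammonium is a purely biological pool with no deep
exchange. With ε = 1, w₀ = 0, and κ = 0, total nitrogen
NO₃ + NH₄ + Σᵢ Pᵢ r_N is conserved exactly; the integrator preserves this to
machine precision (see §3).

Optionally (`entrainment_dilution=True`) mixed-layer deepening dilutes biomass
and entrains deep nutrients at rate (dH/dt)/H; by default the box exchanges
only through κ so that budget analyses stay simple.

## 2. Parameters: values and rationale

Group-resolved physiological constants of this class of model are not fully
constrained by any single source; the defaults below are the package's own
declared choices. They satisfy the standard ordering constraints for these
six groups — diatoms have the largest maximum growth rate and half-saturations
and the fastest sinking; dinoflagellates grow at 90 % of the diatom rate with
the same nitrate/iron half-saturations but no silicate requirement;
cyanobacteria are the slowest-growing, most oligotrophic-adapted (lowest k's),
and effectively non-sinking; coccolithophores saturate at low light — with
magnitudes typical of mixed-layer NPZD-class models.

| group | µ_max | k_NO₃ | k_Fe | k_Si | k_E | w₀ | r_N | r_Si | r_Fe |
|---|---|---|---|---|---|---|---|---|---|
| diatoms | 1.80 | 1.00 | 0.90 | 1.20 | 5.0 | 0.75 | 0.63 | 0.63 | 0.012 |
| coccolithophores | 1.10 | 0.50 | 0.50 | – | 4.0 | 0.60 | 0.63 | – | 0.005 |
| chlorophytes | 1.30 | 0.75 | 0.65 | – | 7.0 | 0.25 | 0.63 | – | 0.005 |
| dinoflagellates | 1.62 | 1.00 | 0.90 | – | 6.0 | 0.10 | 0.63 | – | 0.005 |
| cyanobacteria | 0.80 | 0.30 | 0.15 | – | 14.0 | 0.01 | 0.63 | – | 0.002 |
| phaeocystis | 1.20 | 0.60 | 0.55 | – | 7.0 | 0.30 | 0.63 | – | 0.005 |

Community constants: γ_m = 0.5 d⁻¹, Λ = 1.0 (mg Chl m⁻³)⁻¹, ε = 0.4.

Points worth flagging:

- **Diatom iron quota (r_Fe twice the other groups).** Diatoms are the
  dominant iron consumers in bloom regimes; this is what lets a diatom crash
  leave an iron *surplus* behind (the HNLC signature of the Blob experiments).
- **Si:N quota 1:1 for diatoms** (r_Si = r_N = 0.63), the canonical Brzezinski
  ratio for healthy diatoms.
- **γ_m = 0.5 d⁻¹.** A zero-dimensional Liebig box with weak grazing falls
  into unphysical boom–bust cycles (total chlorophyll excursions above
  20 mg m⁻³ in the tropical profile at γ_m = 0.25); 0.5 d⁻¹ keeps the
  community in a forced, damped regime.
- **ε = 0.4**, a typical mixed-layer regeneration efficiency; larger values
  accumulate implausible ammonium stocks.
- **k_E ordering.** Only the coccolithophore low-light affinity is a strong
  prior; the remaining values were chosen so that no single group wins the
  light competition everywhere (a 0-D box exhibits competitive exclusion, so
  coexistence must come from the seasonal cycle and from different groups
  winning different seasons).

### Region profiles and deep reservoirs

The seasonal generator (sinusoidal annual cycle + seeded AR(1) red noise,
365-day years starting 2000-01-01) bundles two profiles:

| | subarctic | equatorial |
|---|---|---|
| SST (mean ± amp, peak DOY) | 9 ± 4 °C, 227 | 27 ± 1 °C, 105 |
| PAR₀ | 26 ± 20, 172 | 40 ± 4, 105 |
| MLD | 60 ± 45 m, 60 | 45 ± 8 m, 60 |
| κ | 0.030 ± 0.018 d⁻¹ | 0.060 ± 0.012 d⁻¹ |
| deep NO₃ / Si / Fe | 20 / 12 / 1.0 | 12 / 16 / 1.2 |

The deep reservoirs place the subarctic box in an iron/silicate co-limited
regime — baseline silicate supply (κ·Si_deep ≈ 0.36 µmol kg⁻¹ d⁻¹) just
exceeds the demand of a diatom-dominated community, so halving it starves
diatoms specifically — and the equatorial box in a nitrate-controlled,
diatom-dominated upwelling regime where cutting nitrate supply collapses the
whole community with diatoms hit hardest. The equatorial κ carries
larger-amplitude red noise, standing in for high-frequency variability of
tropical upwelling. Per-variable child random streams
(`default_rng([seed, index])`) make each variable's noise independent of the
others and make an n-year series extend a shorter one bit-for-bit.

## 3. Numerics

`run()` integrates with the classic fourth-order Runge–Kutta step on the full
state (six biomasses + four nutrients), with forcing linearly interpolated to
sub-step midpoints and states clipped at zero after each step. Two properties
drove this choice over simpler explicit schemes:

- **Accuracy at a daily step.** The package's accuracy oracle demands that a
  dt = 1 d run track a dt = 0.05 d reference within 1 % pointwise over a
  year. Forward Euler misses by a factor of ~50 (peak bloom error 47 %), and
  an exponential integrating-factor Euler still drifts in phase through bloom
  transients (9 % subarctic). RK4 meets the oracle with margin (< 0.4 %
  across seeds on the default subarctic profile).
- **Exact budget closure.** Total nitrogen under full recycling is a *linear*
  invariant of the tendencies, and every Runge–Kutta method preserves linear
  invariants exactly: closure holds to ~10⁻¹⁶ relative drift per year.

The equatorial profile sits in a stiffer, internally oscillatory regime where
dt = 1 d is marginal (≈20 % peak discrepancy, converging as ~dt⁴); the
package default dt = 0.25 d is well converged there (< 1 %). The fine-step
run remains the accuracy oracle of record.

Assimilation enters the integrator through an `intervene` callback evaluated
at step starts: the sequential driver nudges total chlorophyll a fraction
`weight` toward the nearest observation within half a cadence of each tick,
rescales every group by the same factor (composition-preserving by
construction), and optionally decrements the nutrient pools by the
chlorophyll increment times the uptake ratios.

Ekman vertical velocity w_E = ∂x(τ_y/ρ₀f) − ∂y(τ_x/ρ₀f) uses second-order
centered differences on the sphere (one-sided second order at grid edges) and
masks |lat| < 5° where f vanishes; the analytic sinusoidal-curl wind field
provides a closed-form oracle with a known truncation bound
(1 − sin(kh)/kh ≤ (kh)²/6 interior).

Climatologies require a baseline of at least two full years with every
calendar month represented; percent anomalies are undefined (NaN) where the
climatological mean is zero. Limitation anomalies transform concentrations
through the diatom Monod term *first* and deseasonalize *second* — Monod is
concave, so the order matters (Jensen), and transform-first is the choice that
makes the anomaly a statement about growth limitation rather than about
concentration.

NetCDF wind-grid io uses xarray's scipy backend (NETCDF3), avoiding a
dependency on the netCDF4 C stack.

## 4. Experiment design

`run_experiment` pairs a baseline and a scenario run over identical seeded
forcing and initial conditions, so every in-window difference is attributable
to the scenario. Scenarios are trapezoid-windowed (one-month ramps by
default) perturbations of SST (additive), deep reservoir concentrations
(multiplicative supply factors acting through κ·X_deep), and mixed-layer
depth. Anomalies of the scenario run are measured against the *baseline
run's* monthly climatology — a clean counterfactual. Default problem sizes
(6-year runs at dt = 0.25 d with the event in year 4) are the package's own
choice: long enough for a ≥ 2-year pre-event climatology and a converged
seasonal attractor, small enough to run in seconds.

The two bundled scenarios mirror the two canonical marine-heatwave regimes:
`blob_scenario()` (8 months, +2.5 °C, silicate supply halved, subarctic) and
`elnino_scenario()` (5 months, +4 °C, nitrate supply cut to 20 %,
equatorial). Note that the Blob's diagnostic iron surplus is cleanest when
the silicate cut is applied alone; the +2.5 °C warming in the convenience
default stimulates growth enough to partly mask it.

## 5. Limitations

- Zero-dimensional: no horizontal transport, no explicit vertical structure
  beyond the mixed-layer mean; entrainment is optional and one-directional.
- A single implicit herbivore with fixed temperature response; no explicit
  zooplankton state, so grazing cannot lag blooms.
- Fixed stoichiometry (no photoacclimation or variable Chl:C), chlorophyll as
  the only biomass currency.
- The parameter table is a declared, internally consistent choice — order
  relations are grounded, magnitudes are plausible but not calibrated to any
  specific ocean region; quantitative outputs (e.g., percent anomalies) are
  regime properties, not predictions.
- Synthetic forcing is sinusoid + AR(1); it has no trends, no ENSO-like
  low-frequency memory, and no covariance between variables.
- The equatorial profile's internal oscillation makes daily-step integration
  marginal there; use the default dt = 0.25 d (or finer) for that profile.
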