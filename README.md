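# pft-heatwave

A mixed-layer ecosystem model of six phytoplankton functional types (PFTs),
with sequential chlorophyll assimilation and a marine-heatwave anomaly
analysis toolkit. The package is built to study, at desk scale, how warm
anomalies such as the northeast-Pacific "Blob" and equatorial El Niño warm
phases reorganize phytoplankton community composition: reduced silicate supply
switching subarctic communities from diatoms to dinoflagellates, and collapsed
nitrate supply driving a near-total diatom crash and a large chlorophyll
decline in the tropics.

## The model

Six PFTs — diatoms, coccolithophores, chlorophytes, dinoflagellates,
cyanobacteria, and phaeocystis — compete in a single mixed-layer box of depth
*H* that exchanges with a deep nutrient reservoir at rate κ. Biomass is
carried as chlorophyll (mg m⁻³); nutrients are dissolved nitrogen
(nitrate + ammonium), iron, and — for diatoms only — silicate.

Growth for PFT *i* is

&nbsp;&nbsp;&nbsp;&nbsp;µᵢ = µ_max,ᵢ · min(f_Nut,ᵢ, f_E,ᵢ) · 1.066^(T−20)

with Monod limitation terms f = X/(k + X) and a Liebig minimum across
nutrients (N, Fe, and Si for diatoms). Light limitation uses the mixed-layer
mean PAR from the Morel attenuation relations

&nbsp;&nbsp;&nbsp;&nbsp;K_d(490) = 0.0166 + 0.0773 · Chl^0.6715,
&nbsp;&nbsp;&nbsp;&nbsp;K_d(PAR) = 0.0864 + 0.884 · K_d(490) − 0.00137 / K_d(490),

averaged exactly over the layer: Ē = E₀ (1 − e^(−K·H)) / (K·H). Losses are
temperature-dependent Stokes sinking w = w₀ (0.451 + 0.0178 T) and an Ivlev
grazing term γ = γ_m (0.06 e^(0.1T) + 0.7)(1 − e^(−Λ·ΣP)) applied as a single
community-wide specific rate, so grazing never alters relative composition.
Grazed nitrogen and iron are partially recycled to the ammonium and iron
pools; nutrient pools relax toward deep reservoir values and pay the
stoichiometric cost of growth through fixed nutrient-to-chlorophyll ratios.

Around the core model the package provides:

- **`forcing`** — seeded synthetic seasonal forcing (SST, PAR, mixed-layer
  depth, vertical exchange, deep reservoirs) for a subarctic and an equatorial
  profile; trapezoid-windowed heatwave scenarios; noisy/gappy satellite-like
  chlorophyll observations; analytic wind-stress grids.
- **`lightfield`** — the Morel attenuation chain and mixed-layer mean light.
- **`dynamics`** — rate laws, tendencies, and the RK4 time integrator.
- **`assimilation`** — fraction-preserving chlorophyll nudging with
  stoichiometric nutrient adjustment.
- **`anomalies`** — monthly climatologies, deseasonalized absolute/percent
  anomalies, nutrient-limitation anomalies, Ekman vertical velocity from wind
  stress curl, and dominant-PFT classification.
- **`validation`** — median percent-error skill metrics and PFT composition
  bias.
- **`pipeline`** — paired baseline/scenario experiments with event-window
  summaries, and a `pft-heatwave` command-line interface.

## Worked example

A Blob-style experiment: halve the silicate supply to the subarctic profile
for eight months and compare against the paired baseline run (same seed, same
initial state), summarizing the event window.

```python
import pft_heatwave as ph
from pft_heatwave.forcing import ScenarioSpec

params = ph.default_params()
scenario = ScenarioSpec(kind="blob", duration_months=8.0,
                        supply_factor_si=0.5, ramp_months=1.0)
report = ph.run_experiment(scenario, "subarctic", params, seed=3)

print(f"window: {report.window[0].date()} .. {report.window[1].date()}")
print(f"mean chlorophyll anomaly: {report.mean_chl_percent_anomaly:+.1f} %")
print(f"mean iron anomaly: {report.fe_anomaly_mean:+.4f} nmol kg^-1")
for name, change in sorted(report.fraction_change_points.items()):
    print(f"  {name:<18s} {change:+6.1f} points")
```

Output:

```text
window: 2002-12-31 .. 2003-08-31
mean chlorophyll anomaly: +9.8 %
mean iron anomaly: +0.0085 nmol kg^-1
  chlorophytes         +0.0 points
  coccolithophores     +0.0 points
  cyanobacteria        +0.0 points
  diatoms             -11.9 points
  dinoflagellates     +11.9 points
  phaeocystis          +0.0 points
```

The silicate cut takes the diatom share down by ~12 percentage points and
hands it to dinoflagellates, while iron — which the dominant diatoms would
otherwise have drawn down — accumulates as a small positive anomaly. The
equivalent El Niño experiment (`kind="elnino"`, nitrate supply cut to 20 %
with +4 °C on the equatorial profile) produces a −52.6 % in-window
chlorophyll anomaly with the diatom fraction change (−39.1 points) by far the
most negative of the six groups.

The same experiment from the command line:

```sh
pft-heatwave experiment --scenario blob --profile subarctic --seed 3 \
    --out blob_summary.csv
```

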