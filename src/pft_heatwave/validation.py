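"""Median-based skill metrics for model-versus-observation comparison.

The percent error PE = 100 (med(model) - med(obs)) / med(obs) uses medians
because chlorophyll is close to log-normally distributed, which makes the
median a distribution-robust bias measure. Fields are compared only where both
sides are present (co-location masking).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percent_error", "annual_pe", "pft_fraction_bias"]


def percent_error(model_field, obs_field) -> float:
    """Median percent error over co-located (jointly non-missing) entries."""
    model = np.asarray(model_field, dtype=float).ravel()
    obs = np.asarray(obs_field, dtype=float).ravel()
    if model.shape != obs.shape:
        raise ValueError("model and observation fields must have the same shape")
    mask = ~(np.isnan(model) | np.isnan(obs))
    if not mask.any():
        raise ValueError("no co-located data")
    med_model = np.median(model[mask])
    med_obs = np.median(obs[mask])
    if med_obs == 0:
        raise ValueError("observed median is zero; percent error undefined")
    return float(100.0 * (med_model - med_obs) / med_obs)


def annual_pe(monthly_pe) -> float:
    """Annual percent error: the arithmetic mean of 12 monthly PE values."""
    vals = np.asarray(monthly_pe, dtype=float)
    if vals.shape != (12,) or np.any(np.isnan(vals)):
        raise ValueError("annual PE needs all 12 monthly values")
    return float(vals.mean())


def pe_report(model: pd.Series, obs: pd.Series, region: str = "") -> pd.DataFrame:
    """Monthly PE over one year of co-located series, plus the annual mean."""
    months = sorted(set(model.index.month))
    rows = []
    for m in months:
        rows.append(
            {
                "region": region,
                "month": m,
                "pe_percent": percent_error(
                    model[model.index.month == m].to_numpy(),
                    obs[obs.index.month == m].to_numpy(),
                ),
            }
        )
    out = pd.DataFrame(rows)
    if len(months) == 12:
        out = pd.concat(
            [out, pd.DataFrame([{
                "region": region, "month": "annual",
                "pe_percent": annual_pe(out["pe_percent"].to_numpy()),
            }])],
            ignore_index=True,
        )
    return out


def pft_fraction_bias(model_frac: dict[str, float],
                      obs_frac: dict[str, float]) -> dict[str, float]:
    """Per-PFT relative-abundance bias, model% minus observed%.

    Both compositions must cover the same PFT set and each sum to ~100%;
    the biases then sum to ~0 by construction.
    """
    if set(model_frac) != set(obs_frac):
        raise ValueError("model and observed compositions cover different PFT sets")
    for label, comp in (("model", model_frac), ("observed", obs_frac)):
        total = sum(comp.values())
        if abs(total - 100.0) > 1.0:
            raise ValueError(f"{label} composition sums to {total:.2f}%, not 100%")
    return {k: model_frac[k] - obs_frac[k] for k in sorted(model_frac)}
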