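"""Mixed-layer light reconstruction and the light growth-limiting term.

Surface chlorophyll sets the diffuse attenuation coefficient at 490 nm via the
Morel case-1 relation, Kd490 maps empirically to a broadband PAR attenuation
coefficient, the mixed-layer mean PAR is the exact depth average of
Beer-Lambert decay over [0, H], and growth limitation by light is a Monod
(saturating) function of that mean PAR. The composition is monotone decreasing
in chlorophyll for fixed surface PAR and mixed-layer depth: more biomass means
more self-shading.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kd490_from_chl",
    "kdpar_from_kd490",
    "mixed_layer_mean_par",
    "light_limitation",
]


def kd490_from_chl(chl):
    """Diffuse attenuation at 490 nm (m^-1) from chlorophyll (mg m^-3).

    Kd490 = 0.0166 + 0.0773 * Chl^0.6715; the pure-water floor 0.0166 m^-1 is
    returned at zero chlorophyll.
    """
    chl = np.asarray(chl, dtype=float)
    if np.any(chl < 0):
        raise ValueError("chlorophyll must be non-negative")
    out = 0.0166 + 0.0773 * chl**0.6715
    return out if out.ndim else float(out)


def kdpar_from_kd490(kd490):
    """Broadband PAR attenuation (m^-1) from Kd490 (m^-1).

    KdPAR = 0.0864 + 0.884 Kd490 - 0.00137 / Kd490. The reciprocal term
    diverges at zero, so kd490 must be strictly positive.
    """
    kd490 = np.asarray(kd490, dtype=float)
    if np.any(kd490 <= 0):
        raise ValueError("kd490 must be strictly positive")
    out = 0.0864 + 0.884 * kd490 - 0.00137 / kd490
    return out if out.ndim else float(out)


def mixed_layer_mean_par(par0, kd_par, mld):
    """Depth-mean PAR over the mixed layer [0, H].

    The exact average of Beer-Lambert decay:
    E = par0 * (1 - exp(-kd_par * H)) / (kd_par * H).
    """
    par0 = np.asarray(par0, dtype=float)
    kd_par = np.asarray(kd_par, dtype=float)
    mld = np.asarray(mld, dtype=float)
    if np.any(par0 <= 0) or np.any(kd_par <= 0) or np.any(mld <= 0):
        raise ValueError("par0, kd_par and mld must all be strictly positive")
    tau = kd_par * mld  # optical thickness of the layer
    out = par0 * -np.expm1(-tau) / tau
    return out if out.ndim else float(out)


def light_limitation(e_ml, k_e):
    """Monod light-limitation term E / (k_E + E), in [0, 1)."""
    e_ml = np.asarray(e_ml, dtype=float)
    k_e = np.asarray(k_e, dtype=float)
    if np.any(e_ml < 0):
        raise ValueError("e_ml must be non-negative")
    if np.any(k_e <= 0):
        raise ValueError("k_e must be strictly positive")
    out = e_ml / (k_e + e_ml)
    return out if out.ndim else float(out)


def mixed_layer_light(chl_tot, par0, mld):
    """Convenience composition chl -> Kd490 -> KdPAR -> mean mixed-layer PAR."""
    return mixed_layer_mean_par(par0, kdpar_from_kd490(kd490_from_chl(chl_tot)), mld)
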