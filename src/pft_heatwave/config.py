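"""Physical constants, default parameters, and YAML config io.

All irradiance values are mixed-layer PAR in mol photons m^-2 d^-1;
macronutrients in umol kg^-1, iron in nmol kg^-1, chlorophyll in mg m^-3.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

# -- Physical constants (standard oceanographic values) -----------------------

RHO0 = 1025.0  # reference seawater density, kg m^-3
OMEGA = 7.2921e-5  # Earth's angular velocity, s^-1
EARTH_RADIUS = 6.371e6  # m
EQUATOR_MASK_LAT = 5.0  # |lat| below which the Coriolis parameter is masked, degrees

PFT_NAMES = (
    "diatoms",
    "coccolithophores",
    "chlorophytes",
    "dinoflagellates",
    "cyanobacteria",
    "phaeocystis",
)

# -- Default physiological parameter table ------------------------------------
#
# Per-group constants are declared here, not derived elsewhere. The ordering
# constraints they satisfy: diatoms have the largest maximum growth rate and the
# largest half-saturations; dinoflagellates grow at 90% of the diatom rate with
# identical nitrate and iron half-saturations but no silicate requirement;
# cyanobacteria have the lowest maximum growth rate and the lowest nutrient
# half-saturations; coccolithophores have a low light-saturation constant and
# low nutrient half-saturations. Magnitudes are typical of mixed-layer
# NPZD-class models.
#
# Fields per group:
#   mu_max   d^-1          maximum growth rate at 20 degC
#   k_no3    umol kg^-1    half-saturation for dissolved N (NO3 + NH4)
#   k_fe     nmol kg^-1    half-saturation for dissolved Fe
#   k_si     umol kg^-1    half-saturation for silicate (diatoms only)
#   k_e      mol photons m^-2 d^-1   half-saturation mixed-layer PAR
#   w0       m d^-1        sinking speed at the 31 degC viscosity reference
#   r_n_chl  umol N per mg Chl m^-3  (N:Chl uptake ratio)
#   r_si_chl umol Si per mg Chl m^-3 (diatoms only)
#   r_fe_chl nmol Fe per mg Chl m^-3

DEFAULT_PFT_TABLE: dict[str, dict] = {
    "diatoms": dict(
        mu_max=1.80, k_no3=1.00, k_fe=0.90, k_si=1.20, k_e=5.0,
        w0=0.75, r_n_chl=0.63, r_si_chl=0.63, r_fe_chl=0.012,
    ),
    "coccolithophores": dict(
        mu_max=1.10, k_no3=0.50, k_fe=0.50, k_si=None, k_e=4.0,
        w0=0.60, r_n_chl=0.63, r_si_chl=None, r_fe_chl=0.005,
    ),
    "chlorophytes": dict(
        mu_max=1.30, k_no3=0.75, k_fe=0.65, k_si=None, k_e=7.0,
        w0=0.25, r_n_chl=0.63, r_si_chl=None, r_fe_chl=0.005,
    ),
    "dinoflagellates": dict(
        mu_max=1.62, k_no3=1.00, k_fe=0.90, k_si=None, k_e=6.0,
        w0=0.10, r_n_chl=0.63, r_si_chl=None, r_fe_chl=0.005,
    ),
    "cyanobacteria": dict(
        mu_max=0.80, k_no3=0.30, k_fe=0.15, k_si=None, k_e=14.0,
        w0=0.01, r_n_chl=0.63, r_si_chl=None, r_fe_chl=0.002,
    ),
    "phaeocystis": dict(
        mu_max=1.20, k_no3=0.60, k_fe=0.55, k_si=None, k_e=7.0,
        w0=0.30, r_n_chl=0.63, r_si_chl=None, r_fe_chl=0.005,
    ),
}

DEFAULT_COMMUNITY = dict(
    gamma_m=0.50,        # d^-1, maximum grazing rate at 20 degC
    ivlev_lambda=1.0,    # (mg Chl m^-3)^-1
    recycle_frac=0.4,    # fraction of grazed N and Fe regenerated to NH4 / Fe pools
)

# Background composition used only to reseed a fully collapsed community before
# an assimilation increment (equal shares).
DEFAULT_BACKGROUND_FRACTIONS = {name: 1.0 / 6.0 for name in PFT_NAMES}


def default_params():
    """Build the default :class:`~pft_heatwave.dynamics.CommunityParams`."""
    from .dynamics import CommunityParams, PFTParams

    pfts = [PFTParams(name=n, **DEFAULT_PFT_TABLE[n]) for n in PFT_NAMES]
    return CommunityParams(pfts=pfts, **DEFAULT_COMMUNITY)


def save_params(params, path: str | Path) -> None:
    """Write a CommunityParams to a YAML file mirroring the field names."""
    doc = {
        "community": {
            "gamma_m": params.gamma_m,
            "ivlev_lambda": params.ivlev_lambda,
            "recycle_frac": params.recycle_frac,
        },
        "pfts": {
            p.name: {
                k: v
                for k, v in dataclasses.asdict(p).items()
                if k != "name" and v is not None
            }
            for p in params.pfts
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path: str | Path):
    """Read a CommunityParams from YAML written by :func:`save_params`."""
    from .dynamics import CommunityParams, PFTParams

    doc = yaml.safe_load(Path(path).read_text())
    pfts = [
        PFTParams(name=name, **{"k_si": None, "r_si_chl": None, **fields})
        for name, fields in doc["pfts"].items()
    ]
    return CommunityParams(pfts=pfts, **doc["community"])
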