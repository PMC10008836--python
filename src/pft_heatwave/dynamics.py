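"""Six-group phytoplankton mixed-layer box model.

Chlorophyll-based biomass of six phytoplankton functional types (PFTs) competes
for dissolved nitrogen (nitrate + ammonium), iron, and — for diatoms only —
silicate, in a mixed layer of depth H exchanging with a deep nutrient
reservoir at rate kappa. Growth is the product of a maximum rate, the Liebig
minimum of nutrient- and light-limitation Monod terms, and an exponential
temperature factor normalised to 20 degC. Losses are temperature-dependent
sinking and an Ivlev grazing term applied as a uniform specific rate, which by
construction does not alter community composition. Grazed nitrogen and iron
are partially recycled to the ammonium and iron pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lightfield import light_limitation, mixed_layer_light

NUTRIENT_ORDER = ("N", "Fe", "Si")  # tie-break order for the Liebig minimum

# ---------------------------------------------------------------------------
# Parameter and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PFTParams:
    """Physiological constants for one phytoplankton functional type.

    Units: mu_max d^-1; k_no3, k_si umol kg^-1; k_fe nmol kg^-1;
    k_e mol photons m^-2 d^-1; w0 m d^-1 (sinking speed at the 31 degC
    viscosity reference); r_n_chl umol N per mg Chl m^-3; r_si_chl umol Si per
    mg Chl m^-3 (diatoms only); r_fe_chl nmol Fe per mg Chl m^-3.
    """

    name: str
    mu_max: float
    k_no3: float
    k_fe: float
    k_e: float
    w0: float
    r_n_chl: float
    r_fe_chl: float
    k_si: float | None = None
    r_si_chl: float | None = None

    def __post_init__(self):
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        for nm in ("k_no3", "k_fe", "k_e"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.w0 < 0:
            raise ValueError("w0 must be non-negative")
        if self.r_n_chl <= 0 or self.r_fe_chl <= 0:
            raise ValueError("nutrient:chlorophyll ratios must be positive")
        is_diatom = self.name == "diatoms"
        if is_diatom and (self.k_si is None or self.r_si_chl is None):
            raise ValueError("diatoms require k_si and r_si_chl")
        if not is_diatom and (self.k_si is not None or self.r_si_chl is not None):
            raise ValueError("only diatoms take k_si / r_si_chl")


@dataclass(frozen=True)
class CommunityParams:
    """The six PFT parameter sets plus community-level grazing constants."""

    pfts: tuple[PFTParams, ...]
    gamma_m: float  # d^-1, maximum grazing rate at 20 degC
    ivlev_lambda: float  # (mg Chl m^-3)^-1
    recycle_frac: float = 0.75  # grazed N/Fe share returned to NH4 / Fe pools

    def __post_init__(self):
        object.__setattr__(self, "pfts", tuple(self.pfts))
        names = [p.name for p in self.pfts]
        if len(names) != 6 or len(set(names)) != 6:
            raise ValueError("exactly six uniquely named PFTs are required")
        if self.gamma_m < 0:
            raise ValueError("gamma_m must be non-negative")
        if self.ivlev_lambda <= 0:
            raise ValueError("ivlev_lambda must be positive")
        if not 0.0 <= self.recycle_frac <= 1.0:
            raise ValueError("recycle_frac must lie in [0, 1]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pfts)

    def __getitem__(self, name: str) -> PFTParams:
        for p in self.pfts:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass
class ModelState:
    """Mixed-layer state at one instant.

    chl: per-PFT chlorophyll, mg m^-3, ordered as CommunityParams.pfts;
    no3, nh4, si: umol kg^-1; fe: nmol kg^-1.
    """

    time: pd.Timestamp
    chl: np.ndarray
    no3: float
    nh4: float
    si: float
    fe: float

    def __post_init__(self):
        self.time = pd.Timestamp(self.time)
        self.chl = np.asarray(self.chl, dtype=float)
        if self.chl.shape != (6,):
            raise ValueError("chl must hold six values")
        if np.any(self.chl < 0) or min(self.no3, self.nh4, self.si, self.fe) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def chl_tot(self) -> float:
        return float(self.chl.sum())


@dataclass
class Trajectory:
    """Time-ordered model states plus per-step diagnostics.

    ``data`` is indexed by time with per-PFT columns suffixed by the PFT name
    (chl_*, mu_*, f_nut_*, f_e_*, w_*, binding_*) and scalar columns (no3, nh4,
    si, fe, chl_tot, gamma, temp_factor, kd490, kd_par, e_ml, assimilated).
    """

    data: pd.DataFrame
    pft_names: tuple[str, ...]

    @property
    def time(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)

    @property
    def chl(self) -> pd.DataFrame:
        """Per-PFT chlorophyll, columns named by PFT."""
        cols = {f"chl_{n}": n for n in self.pft_names}
        return self.data[list(cols)].rename(columns=cols)

    @property
    def chl_tot(self) -> pd.Series:
        return self.data["chl_tot"]

    def fractions(self) -> pd.DataFrame:
        return biomass_fractions(self)

    def state_at(self, i: int) -> ModelState:
        row = self.data.iloc[i]
        return ModelState(
            time=self.data.index[i],
            chl=np.array([row[f"chl_{n}"] for n in self.pft_names]),
            no3=row["no3"], nh4=row["nh4"], si=row["si"], fe=row["fe"],
        )

    def to_tidy_csv(self, path) -> None:
        """Tidy export: one row per (time, pft) plus a scalar table appended."""
        per_pft = []
        for n in self.pft_names:
            sub = pd.DataFrame(
                {
                    "time": self.data.index,
                    "pft": n,
                    "chl_mg_m3": self.data[f"chl_{n}"].to_numpy(),
                    "mu_per_d": self.data[f"mu_{n}"].to_numpy(),
                    "f_nut": self.data[f"f_nut_{n}"].to_numpy(),
                    "f_e": self.data[f"f_e_{n}"].to_numpy(),
                    "w_m_d": self.data[f"w_{n}"].to_numpy(),
                    "binding": self.data[f"binding_{n}"].to_numpy(),
                }
            )
            per_pft.append(sub)
        pd.concat(per_pft, ignore_index=True).to_csv(path, index=False)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="time", date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path, pft_names=None) -> "Trajectory":
        df = pd.read_csv(path, index_col="time", parse_dates=True)
        if pft_names is None:
            pft_names = tuple(
                c[len("chl_"):] for c in df.columns
                if c.startswith("chl_") and c != "chl_tot"
            )
        return cls(data=df, pft_names=tuple(pft_names))


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def temperature_factor(t):
    """Exponential growth-temperature factor 1.066^(T - 20), equal to 1 at 20 degC."""
    return 1.066 ** (np.asarray(t, dtype=float) - 20.0)


def monod(conc, k):
    """Saturating uptake term conc / (k + conc) with half-saturation k > 0."""
    conc = np.asarray(conc, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("half-saturation k must be strictly positive")
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    out = conc / (k + conc)
    return out if out.ndim else float(out)


def nutrient_limitation(state: ModelState, pft: PFTParams):
    """Liebig-minimum nutrient limitation for one PFT.

    Returns ``(f_nut, binding)`` where binding is the nutrient label ("N",
    "Fe", or "Si") attaining the minimum; exact ties are broken in that fixed
    order. Dissolved nitrogen is the NO3 + NH4 sum; only diatoms see silicate.
    """
    terms = {
        "N": monod(state.no3 + state.nh4, pft.k_no3),
        "Fe": monod(state.fe, pft.k_fe),
    }
    if pft.k_si is not None:
        terms["Si"] = monod(state.si, pft.k_si)
    binding = min(NUTRIENT_ORDER.index(k) for k, v in terms.items()
                  if v == min(terms.values()))
    label = NUTRIENT_ORDER[binding]
    return terms[label], label


def growth_rate(pft: PFTParams, state: ModelState, e_ml: float, t: float) -> float:
    """Realised growth rate mu = mu_max * min(f_nut, f_E) * R(T), d^-1."""
    f_nut, _ = nutrient_limitation(state, pft)
    f_e = light_limitation(e_ml, pft.k_e)
    return pft.mu_max * min(f_nut, f_e) * float(temperature_factor(t))


def sinking_rate(w0, t):
    """Stokes sinking speed w0 * (0.451 + 0.0178 T), m d^-1.

    The temperature polynomial is the seawater-viscosity correction to a
    reference speed specified at 31 degC (where the multiplier is ~1).
    """
    w0 = np.asarray(w0, dtype=float)
    if np.any(w0 < 0):
        raise ValueError("w0 must be non-negative")
    out = w0 * (0.451 + 0.0178 * np.asarray(t, dtype=float))
    return out if out.ndim else float(out)


def grazing_temperature_factor(t):
    """Herbivore temperature dependence Rh = 0.06 exp(0.1 T) + 0.7."""
    return 0.06 * np.exp(0.1 * np.asarray(t, dtype=float)) + 0.7


def grazing_rate(total_chl, t, params: CommunityParams):
    """Ivlev specific grazing loss gamma = gamma_m Rh(T) (1 - exp(-Lambda P)), d^-1.

    Applied uniformly to every PFT, so grazing removes biomass in proportion to
    relative abundance and leaves community composition unchanged.
    """
    total_chl = np.asarray(total_chl, dtype=float)
    if np.any(total_chl < 0):
        raise ValueError("total_chl must be non-negative")
    out = (
        params.gamma_m
        * grazing_temperature_factor(t)
        * -np.expm1(-params.ivlev_lambda * total_chl)
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Budget assembly and time integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForcingSample:
    """Forcing interpolated to one instant."""

    sst: float
    par0: float
    mld: float
    kappa: float
    deep_no3: float
    deep_si: float
    deep_fe: float


class _ParamArrays:
    """Per-PFT parameters unpacked to aligned numpy vectors for fast stepping."""

    def __init__(self, params: CommunityParams):
        p = params.pfts
        self.names = params.names
        self.mu_max = np.array([q.mu_max for q in p])
        self.k_no3 = np.array([q.k_no3 for q in p])
        self.k_fe = np.array([q.k_fe for q in p])
        self.k_e = np.array([q.k_e for q in p])
        self.w0 = np.array([q.w0 for q in p])
        self.r_n = np.array([q.r_n_chl for q in p])
        self.r_fe = np.array([q.r_fe_chl for q in p])
        self.is_diatom = np.array([q.k_si is not None for q in p])
        diat = [q for q in p if q.k_si is not None]
        self.k_si = diat[0].k_si if diat else np.inf
        self.r_si = diat[0].r_si_chl if diat else 0.0


def _step_rates(P, no3, nh4, si, fe, f: ForcingSample, params: CommunityParams,
                pa: _ParamArrays):
    """All instantaneous rates and diagnostics at one state/forcing sample."""
    if f.mld <= 0:
        raise ValueError("mixed-layer depth must be positive")
    chl_tot = P.sum()
    from .lightfield import kd490_from_chl, kdpar_from_kd490, mixed_layer_mean_par

    kd490 = kd490_from_chl(chl_tot)
    kd_par = kdpar_from_kd490(kd490)
    e_ml = mixed_layer_mean_par(f.par0, kd_par, f.mld)

    n_sum = no3 + nh4
    f_n = n_sum / (pa.k_no3 + n_sum)
    f_fe = fe / (pa.k_fe + fe)
    f_si = np.where(pa.is_diatom, si / (pa.k_si + si), np.inf)
    terms = np.stack([f_n, f_fe, f_si])  # ordered N, Fe, Si for tie-breaking
    idx = np.argmin(terms, axis=0)  # argmin takes the first minimum
    f_nut = terms[idx, np.arange(6)]
    f_e = e_ml / (pa.k_e + e_ml)
    r_t = float(temperature_factor(f.sst))
    mu = pa.mu_max * np.minimum(f_nut, f_e) * r_t

    gamma = grazing_rate(chl_tot, f.sst, params)
    w = sinking_rate(pa.w0, f.sst)

    dP = (mu - gamma - w / f.mld) * P

    uptake_n = mu * P * pa.r_n  # umol N kg^-1 d^-1 per PFT
    phi_no3 = no3 / n_sum if n_sum > 0 else 0.0
    recycled_n = params.recycle_frac * gamma * np.sum(P * pa.r_n)
    dno3 = f.kappa * (f.deep_no3 - no3) - phi_no3 * uptake_n.sum()
    dnh4 = recycled_n - (1.0 - phi_no3) * uptake_n.sum()
    dsi = f.kappa * (f.deep_si - si) - np.sum(mu * P * pa.r_si * pa.is_diatom)
    dfe = (
        f.kappa * (f.deep_fe - fe)
        - np.sum(mu * P * pa.r_fe)
        + params.recycle_frac * gamma * np.sum(P * pa.r_fe)
    )

    diag = dict(
        mu=mu, f_nut=f_nut, f_e=f_e, binding_idx=idx, gamma=gamma,
        temp_factor=r_t, w=w, kd490=kd490, kd_par=kd_par, e_ml=e_ml,
        chl_tot=chl_tot,
    )
    return (dP, dno3, dnh4, dsi, dfe), diag


def tendencies(state: ModelState, forcing_at_t: ForcingSample,
               params: CommunityParams):
    """Time derivatives of every state field at one instant.

    Returns a dict with ``chl`` (per-PFT, mg m^-3 d^-1) and scalars ``no3``,
    ``nh4``, ``si``, ``fe``. Phytoplankton: dP_i/dt = (mu_i - gamma - w_i/H) P_i.
    Nutrients: vertical-exchange relaxation toward the deep reservoir minus
    stoichiometric uptake, with grazed N (Fe) partially recycled to ammonium
    (iron); NO3/NH4 uptake splits in proportion to pool sizes.
    """
    pa = _ParamArrays(params)
    (dP, dno3, dnh4, dsi, dfe), _ = _step_rates(
        state.chl, state.no3, state.nh4, state.si, state.fe,
        forcing_at_t, params, pa,
    )
    return {"chl": dP, "no3": dno3, "nh4": dnh4, "si": dsi, "fe": dfe}


def default_init(forcing, params: CommunityParams,
                 chl0: float = 0.5, nh4_0: float = 0.5) -> ModelState:
    """Standard initial state: 0.5 mg Chl m^-3 per group, ammonium 0.5 umol kg^-1,
    nitrate/silicate/iron at the deep reservoir values at the first time."""
    return ModelState(
        time=forcing.time[0],
        chl=np.full(6, chl0),
        no3=float(forcing.deep_no3[0]),
        nh4=nh4_0,
        si=float(forcing.deep_si[0]),
        fe=float(forcing.deep_fe[0]),
    )


def _interp_forcing(forcing, t_days: np.ndarray) -> dict[str, np.ndarray]:
    """Linear interpolation of each forcing field to the integration times."""
    src = (forcing.time - forcing.time[0]) / pd.Timedelta(days=1)
    src = np.asarray(src, dtype=float)
    out = {}
    for name in ("sst", "par0", "mld", "kappa", "deep_no3", "deep_si", "deep_fe"):
        y = getattr(forcing, name)
        if np.any(np.isnan(y)):
            bad = forcing.time[int(np.flatnonzero(np.isnan(y))[0])]
            raise ValueError(f"NaN in forcing field {name!r} at {bad}")
        out[name] = np.interp(t_days, src, y)
    return out


def run(forcing, params: CommunityParams, init: ModelState | None = None,
        dt: float = 0.25, entrainment_dilution: bool = False,
        intervene=None) -> Trajectory:
    """Integrate the box model over the forcing span with explicit RK4 steps.

    The classic fourth-order Runge-Kutta step keeps a coarse daily step on the
    same solution as a fine-step reference even through bloom transients, and,
    being a Runge-Kutta method, preserves the linear total-nitrogen invariant
    exactly (budget closure to machine precision when recycling is total and
    exports vanish). States are clipped at zero after each step. ``dt`` (days)
    must not exceed the forcing step. With ``entrainment_dilution`` on,
    mixed-layer deepening dilutes phytoplankton and entrains deep nutrients; by
    default the box only exchanges through kappa.

    ``intervene``, if given, is called at the start of every step as
    ``intervene(time, P, no3, nh4, si, fe)`` and may return a corrected state
    tuple (or None to leave the state alone); corrected steps are flagged in
    the ``assimilated`` column. This is the hook the sequential assimilation
    driver uses.
    """
    if init is None:
        init = default_init(forcing, params)
    step = forcing.step_days
    if dt > step + 1e-12:
        raise ValueError("dt must not exceed the forcing time step")
    pa = _ParamArrays(params)
    total_days = float((forcing.time[-1] - forcing.time[0]) / pd.Timedelta(days=1))
    n_steps = int(round(total_days / dt))
    t_days = np.arange(n_steps + 1) * dt
    fc = _interp_forcing(forcing, t_days)
    fc_mid = _interp_forcing(forcing, t_days[:-1] + 0.5 * dt) if n_steps else None

    P = init.chl.copy()
    no3, nh4, si, fe = init.no3, init.nh4, init.si, init.fe

    names = pa.names
    cols: dict[str, list] = {c: [] for c in (
        [f"chl_{n}" for n in names] + ["no3", "nh4", "si", "fe", "chl_tot"]
        + [f"mu_{n}" for n in names] + [f"f_nut_{n}" for n in names]
        + [f"f_e_{n}" for n in names] + [f"w_{n}" for n in names]
        + [f"binding_{n}" for n in names]
        + ["gamma", "temp_factor", "kd490", "kd_par", "e_ml",
           "sst", "par0", "mld", "kappa", "assimilated"]
    )}

    def record(diag, f: ForcingSample, corrected: bool):
        for j, n in enumerate(names):
            cols[f"chl_{n}"].append(P[j])
            cols[f"mu_{n}"].append(diag["mu"][j])
            cols[f"f_nut_{n}"].append(diag["f_nut"][j])
            cols[f"f_e_{n}"].append(diag["f_e"][j])
            cols[f"w_{n}"].append(diag["w"][j])
            cols[f"binding_{n}"].append(NUTRIENT_ORDER[diag["binding_idx"][j]])
        cols["no3"].append(no3); cols["nh4"].append(nh4)
        cols["si"].append(si); cols["fe"].append(fe)
        cols["chl_tot"].append(diag["chl_tot"])
        cols["gamma"].append(diag["gamma"])
        cols["temp_factor"].append(diag["temp_factor"])
        cols["kd490"].append(diag["kd490"]); cols["kd_par"].append(diag["kd_par"])
        cols["e_ml"].append(diag["e_ml"])
        cols["sst"].append(f.sst); cols["par0"].append(f.par0)
        cols["mld"].append(f.mld); cols["kappa"].append(f.kappa)
        cols["assimilated"].append(corrected)

    times = forcing.time[0] + pd.to_timedelta(t_days, unit="D")
    mld_prev = fc["mld"][0]
    for i in range(n_steps + 1):
        corrected = False
        if intervene is not None:
            new = intervene(times[i], P, no3, nh4, si, fe)
            if new is not None:
                P, no3, nh4, si, fe = new
                P = np.asarray(P, dtype=float)
                corrected = True
        f = ForcingSample(
            sst=fc["sst"][i], par0=fc["par0"][i], mld=fc["mld"][i],
            kappa=fc["kappa"][i], deep_no3=fc["deep_no3"][i],
            deep_si=fc["deep_si"][i], deep_fe=fc["deep_fe"][i],
        )
        (dP, dno3, dnh4, dsi, dfe), diag = _step_rates(
            P, no3, nh4, si, fe, f, params, pa
        )
        record(diag, f, corrected)
        if i == n_steps:
            break
        ent_rate = 0.0
        if entrainment_dilution:
            dh = (fc["mld"][i + 1] - mld_prev) / dt
            if dh > 0:
                ent_rate = dh / f.mld
            mld_prev = fc["mld"][i + 1]

        f_mid = ForcingSample(
            sst=fc_mid["sst"][i], par0=fc_mid["par0"][i], mld=fc_mid["mld"][i],
            kappa=fc_mid["kappa"][i], deep_no3=fc_mid["deep_no3"][i],
            deep_si=fc_mid["deep_si"][i], deep_fe=fc_mid["deep_fe"][i],
        )
        f_next = ForcingSample(
            sst=fc["sst"][i + 1], par0=fc["par0"][i + 1], mld=fc["mld"][i + 1],
            kappa=fc["kappa"][i + 1], deep_no3=fc["deep_no3"][i + 1],
            deep_si=fc["deep_si"][i + 1], deep_fe=fc["deep_fe"][i + 1],
        )

        def rhs(y, fs):
            Pk = np.maximum(y[:6], 0.0)
            no3k, nh4k, sik, fek = (max(v, 0.0) for v in y[6:])
            (dPk, dno3k, dnh4k, dsik, dfek), _ = _step_rates(
                Pk, no3k, nh4k, sik, fek, fs, params, pa
            )
            if ent_rate:
                dPk = dPk - ent_rate * Pk
                dno3k += ent_rate * (fs.deep_no3 - no3k)
                dnh4k -= ent_rate * nh4k
                dsik += ent_rate * (fs.deep_si - sik)
                dfek += ent_rate * (fs.deep_fe - fek)
            return np.concatenate([dPk, [dno3k, dnh4k, dsik, dfek]])

        y0 = np.concatenate([P, [no3, nh4, si, fe]])
        k1 = np.concatenate([dP, [dno3, dnh4, dsi, dfe]])
        if ent_rate:
            k1 = k1 + np.concatenate([
                -ent_rate * P,
                [ent_rate * (f.deep_no3 - no3), -ent_rate * nh4,
                 ent_rate * (f.deep_si - si), ent_rate * (f.deep_fe - fe)],
            ])
        k2 = rhs(y0 + 0.5 * dt * k1, f_mid)
        k3 = rhs(y0 + 0.5 * dt * k2, f_mid)
        k4 = rhs(y0 + dt * k3, f_next)
        y1 = np.maximum(y0 + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4), 0.0)
        P = y1[:6]
        no3, nh4, si, fe = (float(v) for v in y1[6:])

    data = pd.DataFrame(cols, index=pd.Index(times, name="time"))
    return Trajectory(data=data, pft_names=names)


def biomass_fractions(traj: Trajectory) -> pd.DataFrame:
    """Per-PFT share of total chlorophyll; NaN wherever total chlorophyll is 0."""
    chl = traj.chl
    tot = chl.sum(axis=1)
    frac = chl.div(tot, axis=0)
    frac[tot == 0] = np.nan
    return frac
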