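"""Sequential chlorophyll assimilation by composition-preserving nudging.

At each assimilation tick the total chlorophyll is relaxed a fraction
``weight`` of the way toward the observation and every PFT is rescaled by the
same factor, so relative community composition is preserved exactly. When
nutrient adjustment is enabled, each dissolved pool is decremented by the
chlorophyll increment times the model's nutrient-to-chlorophyll uptake ratios
(and incremented when chlorophyll is removed), with the nitrogen change split
between nitrate and ammonium in proportion to their pool sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import DEFAULT_BACKGROUND_FRACTIONS
from .dynamics import (
    CommunityParams,
    ModelState,
    Trajectory,
    _ParamArrays,
    default_init,
    run,
)
from .forcing import ForcingSeries, ObsSeries


@dataclass(frozen=True)
class AssimConfig:
    """weight: fraction of the model-observation misfit removed per tick, in
    [0, 1]; cadence: days between ticks; adjust_nutrients: propagate the
    chlorophyll increment into the nutrient pools."""

    weight: float = 0.5
    cadence: float = 1.0
    adjust_nutrients: bool = True

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")


def assimilate_step(state: ModelState, obs_chl: float, cfg: AssimConfig,
                    params: CommunityParams,
                    background_fractions: dict[str, float] | None = None,
                    ) -> ModelState:
    """One nudging increment toward an observed total chlorophyll.

    Fractions are untouched; if the community has fully collapsed while the
    observation is positive, PFTs are first reseeded from configurable
    background fractions so the scaling is defined.
    """
    if obs_chl < 0:
        raise ValueError("obs_chl must be non-negative")
    pa = _ParamArrays(params)
    chl = state.chl.copy()
    tot = chl.sum()
    if tot == 0.0:
        if obs_chl == 0.0:
            return replace(state)
        bg = background_fractions or DEFAULT_BACKGROUND_FRACTIONS
        chl = np.array([bg[n] for n in params.names], dtype=float)
        chl = chl / chl.sum() * 1e-6  # seed a tiny community, then scale
        tot = chl.sum()
    new_tot = tot + cfg.weight * (obs_chl - tot)
    dchl = chl * (new_tot / tot - 1.0)

    no3, nh4, si, fe = state.no3, state.nh4, state.si, state.fe
    if cfg.adjust_nutrients:
        dn = float(np.sum(dchl * pa.r_n))
        n_sum = no3 + nh4
        phi_no3 = no3 / n_sum if n_sum > 0 else 1.0
        no3 = max(no3 - phi_no3 * dn, 0.0)
        nh4 = max(nh4 - (1.0 - phi_no3) * dn, 0.0)
        si = max(si - float(np.sum(dchl * pa.r_si * pa.is_diatom)), 0.0)
        fe = max(fe - float(np.sum(dchl * pa.r_fe)), 0.0)

    return ModelState(time=state.time, chl=chl + dchl, no3=no3, nh4=nh4,
                      si=si, fe=fe)


def run_assimilated(forcing: ForcingSeries, obs: ObsSeries,
                    params: CommunityParams, cfg: AssimConfig,
                    init: ModelState | None = None, dt: float = 0.25,
                    background_fractions: dict[str, float] | None = None,
                    ) -> Trajectory:
    """Forward run with a nudging increment at each cadence tick with data.

    An observation is used at a tick when one lies within half a cadence of
    it; gaps (NaN observations) are skipped, leaving the free model running.
    The trajectory's ``assimilated`` column flags corrected steps.
    """
    if init is None:
        init = default_init(forcing, params)
    if len(obs.time) and (obs.time[0] < forcing.time[0]
                          or obs.time[-1] > forcing.time[-1]):
        raise ValueError("observation times must lie within the forcing span")

    obs_s = pd.Series(obs.chl_obs, index=pd.DatetimeIndex(obs.time)).dropna()
    half = pd.Timedelta(days=cfg.cadence / 2)
    t0 = forcing.time[0]
    cadence = pd.Timedelta(days=cfg.cadence)
    next_tick = {"t": t0}

    def intervene(time, P, no3, nh4, si, fe):
        if time < next_tick["t"]:
            return None
        next_tick["t"] = time + cadence
        if len(obs_s) == 0:
            return None
        pos = obs_s.index.get_indexer([time], method="nearest")[0]
        if abs(obs_s.index[pos] - time) > half:
            return None
        state = ModelState(time=time, chl=P, no3=no3, nh4=nh4, si=si, fe=fe)
        new = assimilate_step(state, float(obs_s.iloc[pos]), cfg, params,
                              background_fractions)
        return new.chl, new.no3, new.nh4, new.si, new.fe

    return run(forcing, params, init=init, dt=dt, intervene=intervene)
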