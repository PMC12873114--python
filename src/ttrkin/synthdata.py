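"""Seeded synthetic-data generators for every input the pipeline consumes.

Real calibration data for this model are digitised clinical PK profiles
and plasma subunit-exchange measurements, neither of which is deposited in
machine-readable form.  These generators produce statistically analogous
tables — a multi-dose oral PK profile, (concentration, kd) exchange
measurements, and serum TTR time courses — from the model itself plus a
configurable noise model, so the whole estimation pipeline can be
exercised and validated by parameter recovery.

Defaults encode the study conditions: 61 mg once daily, V = 3000 mL,
M_drug = 308.11 g/mol, interval-average plasma level ≈ 25 μM, exchange
truth (kd0 = 0.0024 h⁻¹, λ = 0.112 μM⁻¹), and 10% multiplicative
lognormal measurement noise (a typical bioanalytical CV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import TTRParameters, TTRState, simulate_ttr
from .errors import DomainError
from .pd_link import StabiliserRelation, kd_of_concentration
from .pk import DoseRegimen, PKParameters, simulate_pk

__all__ = [
    "NoiseModel",
    "clinical_sampling_times",
    "gen_pk_profile",
    "gen_exchange_measurements",
    "gen_ttr_timecourse",
]


def clinical_sampling_times(n_days: int = 7) -> np.ndarray:
    """A realistic sparse PK sampling design over a multi-dose course.

    Rich sampling after the first dose (absorption + distribution), one
    post-dose sample on each subsequent day (accumulation), and a dense
    final-day profile — 24 samples for the default 7-day course, the kind
    of schedule bioequivalence studies use.
    """
    if n_days < 2:
        raise DomainError("design needs at least 2 dosing days")
    day1 = np.array([0.5, 1, 2, 3, 4, 6, 8, 12, 16, 20, 23.0])
    daily = 24.0 * np.arange(1, n_days) + 2.0
    last = 24.0 * (n_days - 1) + np.array([4, 8, 12, 16, 20, 23, 23.9])
    return np.sort(np.concatenate([day1, daily, last]))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise specification.

    ``multiplicative_lognormal`` multiplies by exp(σZ), Z ~ N(0,1) — the
    median equals the noiseless value; ``additive_gaussian`` adds σZ.
    """

    kind: str = "multiplicative_lognormal"
    sigma: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise DomainError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        rng = rng or self.rng()
        z = rng.standard_normal(values.shape)
        if self.kind == "multiplicative_lognormal":
            return values * np.exp(self.sigma * z)
        return values + self.sigma * z


def gen_pk_profile(params: PKParameters, regimen: DoseRegimen,
                   sample_times: Sequence[float],
                   noise: NoiseModel = NoiseModel()) -> pd.DataFrame:
    """Noisy plasma concentration–time table, ``time_h, c1_ug_per_mL``.

    Emulates a sparse clinical profile (e.g. day-7 sampling under daily
    dosing) in the units such profiles are reported in.
    """
    prof = simulate_pk(params, regimen, sample_times)
    c1_ug = prof["c1_mg_per_mL"].to_numpy() * 1000.0
    return pd.DataFrame({"time_h": prof["time_h"],
                         "c1_ug_per_mL": noise.apply(c1_ug)})


def gen_exchange_measurements(rel: StabiliserRelation,
                              concentrations: Sequence[float],
                              noise: NoiseModel = NoiseModel()) -> pd.DataFrame:
    """Noisy (stabiliser concentration, measured kd) table,
    ``c1_uM, kd_per_h``."""
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise DomainError("concentration list must not be empty")
    kd = kd_of_concentration(rel, c)
    return pd.DataFrame({"c1_uM": c, "kd_per_h": noise.apply(kd)})


def gen_ttr_timecourse(params: TTRParameters, init: TTRState,
                       sample_times: Sequence[float],
                       noise: NoiseModel = NoiseModel(),
                       report: str = "tetramer") -> pd.DataFrame:
    """Noisy serum TTR series, ``time_h, TTR_uM``.

    ``report='tetramer'`` gives T only (the convention for interpreting
    clinical totals); ``report='total'`` gives 4·T + M in monomer-
    equivalent μM, mimicking assays that cannot distinguish the species.
    The two differ by well under 1% at the physiological steady state.
    """
    if report not in ("tetramer", "total"):
        raise DomainError("report must be 'tetramer' or 'total'")
    traj = simulate_ttr(params, init, sample_times)
    obs = 4.0 * traj.T + traj.M if report == "total" else traj.T
    return pd.DataFrame({"time_h": traj.times, "TTR_uM": noise.apply(obs)})
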