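"""Regime-resolved steady-state analysis of the TTR turnover model.

Two fluxes compete for free monomers at steady state: reassociation into
tetramers (4·ka·Mst⁴) and first-order elimination (krem_M·Mst).  Which one
dominates decides the closed-form steady state, how the synthesis rate r
and the monomer removal rate krem_M can be back-calculated from observable
quantities, and how much a kinetic stabiliser can raise the tetramer level
at all:

* reassociation-dominated — Tst = r/krem_T, Mst = (kd·Tst/ka)^(1/4);
  Tst does not depend on kd, so stabilisation gains nothing.
* degradation-dominated — Tst = r/(krem_T + kd), Mst = 4·kd·Tst/krem_M;
  abolishing dissociation (kd → 0) raises Tst by at most kd/krem_T.
* intermediate (fluxes comparable, split 50/50 here) —
  Tst = r/(krem_T + 0.5·kd); the maximal gain is halved.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Optional

from .core import TTRParameters, TTRState
from .errors import DomainError

__all__ = [
    "Regime",
    "RegimeDiagnostics",
    "steady_state_closed_form",
    "classify_regime",
    "stabilisation_gain",
    "infer_rates",
    "RateInference",
    "regime_report",
]

#: Default dominance margin for classification: one flux must exceed the
#: other by a decade before a limiting closed form is trusted.
DEFAULT_THRESHOLD = 10.0


class Regime(enum.Enum):
    """Monomer-fate regime at steady state."""

    REASSOCIATION_DOMINATED = "reassociation_dominated"
    DEGRADATION_DOMINATED = "degradation_dominated"
    INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class RegimeDiagnostics:
    """Monomer-removal fluxes at a (steady) state.

    ``flux_ratio`` = reassociation/removal; ``inf`` when removal is zero.
    ``degenerate`` marks the M = 0, krem_M = 0 corner where both fluxes
    vanish and the ratio is undefined.
    """

    reassociation_flux: float
    removal_flux: float
    flux_ratio: float
    degenerate: bool = False


def steady_state_closed_form(params: TTRParameters, regime: Regime) -> TTRState:
    """Closed-form steady state under the stated regime's approximation."""
    p = params
    if p.kd == 0:
        if p.krem_T == 0:
            raise DomainError("krem_T = 0 with kd = 0: tetramers have no sink")
        return TTRState(T=p.r / p.krem_T, M=0.0)
    if regime is Regime.REASSOCIATION_DOMINATED:
        if p.krem_T == 0:
            raise DomainError("krem_T must be > 0 in the reassociation branch")
        if p.ka == 0:
            raise DomainError("ka must be > 0 in the reassociation branch")
        Tst = p.r / p.krem_T
        Mst = (p.kd * Tst / p.ka) ** 0.25
    elif regime is Regime.DEGRADATION_DOMINATED:
        if p.krem_M == 0:
            raise DomainError("krem_M must be > 0 in the degradation branch")
        Tst = p.r / (p.krem_T + p.kd)
        Mst = 4.0 * p.kd * Tst / p.krem_M
    elif regime is Regime.INTERMEDIATE:
        if p.ka == 0:
            raise DomainError("ka must be > 0 in the intermediate branch")
        Tst = p.r / (p.krem_T + 0.5 * p.kd)
        Mst = (0.5 * p.kd * Tst / p.ka) ** 0.25
    else:  # pragma: no cover
        raise ValueError(f"unknown regime {regime}")
    return TTRState(T=Tst, M=Mst)


def classify_regime(params: TTRParameters, state: TTRState,
                    threshold: float = DEFAULT_THRESHOLD
                    ) -> tuple[Regime, RegimeDiagnostics]:
    """Classify the monomer-fate regime from the flux balance at ``state``.

    ``state`` should be a steady state (caller's responsibility).  A flux
    ratio above ``threshold`` (default one decade) is reassociation-
    dominated, below 1/threshold degradation-dominated, else intermediate.
    """
    if threshold < 1:
        raise DomainError(f"threshold must be >= 1, got {threshold}")
    p = params
    reassoc = 4.0 * p.ka * state.M ** 4
    removal = p.krem_M * state.M
    if removal == 0.0 and reassoc == 0.0:
        # no monomers / no sinks at all: report the branch whose formulas
        # stay valid (reassociation: Tst = r/krem_T holds when M ~ 0)
        diag = RegimeDiagnostics(reassoc, removal, math.inf, degenerate=True)
        return Regime.REASSOCIATION_DOMINATED, diag
    ratio = math.inf if removal == 0.0 else reassoc / removal
    diag = RegimeDiagnostics(reassoc, removal, ratio)
    if ratio > threshold:
        return Regime.REASSOCIATION_DOMINATED, diag
    if ratio < 1.0 / threshold:
        return Regime.DEGRADATION_DOMINATED, diag
    return Regime.INTERMEDIATE, diag


def stabilisation_gain(kd: float, krem_T: float, regime: Regime) -> float:
    """Maximal relative rise in Tst from perfect stabilisation (kd → 0).

    The bound is (Tst[kd=0] − Tst[kd])/Tst[kd]: kd/krem_T in the
    degradation-dominated regime, half that in the intermediate regime, and
    exactly 0 in the reassociation-dominated regime where Tst is
    independent of kd.  Independent of the synthesis rate r in all cases.
    """
    if krem_T <= 0:
        raise DomainError(f"krem_T must be > 0, got {krem_T}")
    if kd < 0:
        raise DomainError(f"kd must be >= 0, got {kd}")
    if regime is Regime.DEGRADATION_DOMINATED:
        return kd / krem_T
    if regime is Regime.INTERMEDIATE:
        return 0.5 * kd / krem_T
    return 0.0


@dataclass(frozen=True)
class RateInference:
    """Back-calculated synthesis and monomer-removal rates.

    ``krem_M`` is ``None`` in the reassociation branch, where monomer
    elimination is by definition negligible rather than zero.
    """

    regime: Regime
    r: float
    krem_M: Optional[float]


def infer_rates(regime: Regime, Tst: float, krem_T: float, kd: float,
                Mst: Optional[float] = None, ka: Optional[float] = None
                ) -> RateInference:
    """Invert the regime steady-state formulas for r and krem_M.

    Given the observables — steady-state tetramer level Tst, tetramer
    removal rate krem_T (tracer data), dissociation rate kd (subunit
    exchange) — each regime's closed form determines the synthesis rate r.
    The monomer balance additionally yields krem_M, but only against a
    monomer measurement: with ``Mst=None`` the returned ``krem_M`` is None
    (r alone is still well defined).  A supplied Mst must be > 0.
    """
    if Tst <= 0:
        raise DomainError(f"Tst must be > 0, got {Tst}")
    if krem_T < 0 or kd < 0:
        raise DomainError("rates must be >= 0")
    if Mst is not None and Mst <= 0:
        raise DomainError(f"Mst must be > 0 if supplied, got {Mst}")
    if regime is Regime.REASSOCIATION_DOMINATED:
        if krem_T == 0:
            raise DomainError("krem_T must be > 0 in the reassociation branch")
        return RateInference(regime, r=krem_T * Tst, krem_M=None)
    if regime is Regime.DEGRADATION_DOMINATED:
        r = Tst * (krem_T + kd)
        krem_M = None if Mst is None else 4.0 * kd * Tst / Mst
    else:  # intermediate: each monomer sink carries ~2·kd·Tst
        r = Tst * (krem_T + 0.5 * kd)
        krem_M = None if Mst is None else 2.0 * kd * Tst / Mst
    return RateInference(regime, r=r, krem_M=krem_M)


_FORMULAS = {
    Regime.REASSOCIATION_DOMINATED: {
        "Tst": "r/krem_T", "Mst": "(kd*Tst/ka)^(1/4)", "gain": "0"},
    Regime.DEGRADATION_DOMINATED: {
        "Tst": "r/(krem_T + kd)", "Mst": "4*kd*Tst/krem_M", "gain": "kd/krem_T"},
    Regime.INTERMEDIATE: {
        "Tst": "r/(krem_T + 0.5*kd)", "Mst": "(0.5*kd*Tst/ka)^(1/4)",
        "gain": "0.5*kd/krem_T"},
}


def regime_report(Tst: float, krem_T: float, kd: float,
                  Mst: Optional[float] = None, ka: Optional[float] = None,
                  as_json: bool = False):
    """Full three-branch analysis report from the observable quantities.

    For each regime: the formulas used, the inferred r (and krem_M where
    determined) and the perfect-stabilisation gain bound.
    """
    report = {}
    for regime in Regime:
        entry = {"formulas": dict(_FORMULAS[regime]),
                 "gain_bound": stabilisation_gain(kd, krem_T, regime)}
        try:
            inf = infer_rates(regime, Tst, krem_T, kd, Mst=Mst, ka=ka)
            entry["r"] = inf.r
            entry["krem_M"] = inf.krem_M
        except DomainError as exc:
            entry["r"] = None
            entry["krem_M"] = None
            entry["note"] = str(exc)
        report[regime.value] = entry
    if as_json:
        return json.dumps(report, indent=2)
    return report
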