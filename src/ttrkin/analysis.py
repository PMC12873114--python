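"""End-to-end analysis: parameterisation → regime inference → gain bounds
→ therapy simulation → comparison with the clinical TTR rise.

``run_analysis`` wires the modules together the way the scientific
argument runs: starting from the observable quantities (steady-state serum
TTR, tracer-derived tetramer clearance, exchange-derived kd and ka), it
back-calculates the unobservable synthesis and monomer-removal rates under
each monomer-fate regime, evaluates the perfect-stabilisation bound for
each, simulates a stabiliser course, and checks every bound against the
≥ 30% TTR rise seen clinically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .core import TTRParameters
from .errors import DomainError
from .pd_link import StabiliserRelation
from .pk import DoseRegimen, PKParameters, average_steady_state_c1
from .regimes import Regime, infer_rates, regime_report
from .therapy import (CLINICAL_INCREASE, relative_increase_bound_report,
                      simulate_therapy)

__all__ = ["AnalysisConfig", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Resolved configuration for the full analysis pipeline."""

    ttr: TTRParameters
    pk: PKParameters
    relation: StabiliserRelation
    regimen: DoseRegimen
    Tst_observed: float = 6.44
    Mst_observed: Optional[float] = None
    constant_c1: Optional[float] = None   # bypass PK with a fixed μM level
    therapy_duration: float = 24.0 * 60
    regime_threshold: float = 10.0
    #: monomer removal rate used for the degradation-dominated therapy
    #: scenario when no monomer measurement pins it down; 100 h⁻¹ is the
    #: rapid-clearance assumption (proteins of comparable size), deep in
    #: the regime.
    krem_M_degradation: float = 100.0
    seed: int = 0

    @classmethod
    def default(cls) -> "AnalysisConfig":
        return cls(ttr=TTRParameters.reference(),
                   pk=PKParameters.reference(),
                   relation=StabiliserRelation.reference(),
                   regimen=DoseRegimen.daily(61.0, n_days=60))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        base = cls.default()
        try:
            ttr = TTRParameters(**d["ttr"]) if "ttr" in d else base.ttr
            pk = PKParameters(**d["pk"]) if "pk" in d else base.pk
            relation = (StabiliserRelation(**d["relation"])
                        if "relation" in d else base.relation)
            if "regimen" in d:
                r = d["regimen"]
                regimen = DoseRegimen.daily(r.get("dose_mass", 61.0),
                                            n_days=r.get("n_doses", 60),
                                            interval=r.get("interval", 24.0))
            else:
                regimen = base.regimen
        except TypeError as exc:
            raise DomainError(f"malformed config block: {exc}") from exc
        obs = d.get("observables", {})
        return cls(ttr=ttr, pk=pk, relation=relation, regimen=regimen,
                   Tst_observed=obs.get("Tst", 6.44),
                   Mst_observed=obs.get("Mst"),
                   constant_c1=d.get("constant_c1"),
                   therapy_duration=d.get("therapy_duration", 24.0 * 60),
                   regime_threshold=d.get("regime_threshold", 10.0),
                   krem_M_degradation=d.get("krem_M_degradation", 100.0),
                   seed=d.get("seed", 0))

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved(self) -> dict:
        return {
            "ttr": self.ttr.to_dict(),
            "pk": self.pk.to_dict(),
            "relation": {"kd0": self.relation.kd0, "lam": self.relation.lam},
            "regimen": {"dose_mass": self.regimen.dose_mass,
                        "times_of_doses": list(self.regimen.times_of_doses),
                        "duration": self.regimen.duration},
            "observables": {"Tst": self.Tst_observed, "Mst": self.Mst_observed},
            "constant_c1": self.constant_c1,
            "therapy_duration": self.therapy_duration,
            "regime_threshold": self.regime_threshold,
            "krem_M_degradation": self.krem_M_degradation,
            "seed": self.seed,
        }


def run_analysis(config: Optional[AnalysisConfig] = None) -> dict:
    """Run the full analysis arc and return a structured report."""
    cfg = config or AnalysisConfig.default()
    ttr, rel = cfg.ttr, cfg.relation
    Tst = cfg.Tst_observed
    Mst = cfg.Mst_observed
    mst_source = "observed" if Mst is not None else "not measured"

    # krem_M inversion only makes sense against a real monomer measurement
    inference = regime_report(Tst, ttr.krem_T, ttr.kd, Mst=Mst, ka=ttr.ka)

    # stabiliser exposure: fixed c1 if configured, else PK interval average
    if cfg.constant_c1 is not None:
        c1 = cfg.constant_c1
        exposure = {"mode": "constant_c1", "c1_uM": c1}
    else:
        c1 = average_steady_state_c1(cfg.pk, cfg.regimen)
        exposure = {"mode": "pk_average", "c1_uM": c1}

    bounds = {}
    for regime in Regime:
        bounds[regime.value] = relative_increase_bound_report(
            ttr, regime, rel=rel, c1=c1)

    # Therapy simulation in the degradation-dominated parameterisation, the
    # regime in which stabilisation acts at all.  r follows from the Tst
    # observation; krem_M from the measured Mst when there is one, else the
    # configured rapid-clearance value (deep in the regime).
    deg = infer_rates(Regime.DEGRADATION_DOMINATED, Tst, ttr.krem_T, ttr.kd,
                      Mst=Mst)
    r_deg = deg.r
    krem_M = deg.krem_M if deg.krem_M is not None else cfg.krem_M_degradation
    ttr_deg = ttr.replace(r=r_deg, krem_M=krem_M)
    sim = simulate_therapy(ttr_deg, cfg.pk, rel,
                           regimen=cfg.regimen if cfg.constant_c1 is None else None,
                           duration=cfg.therapy_duration,
                           constant_c1=cfg.constant_c1)

    return {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.resolved(),
        "observables": {"Tst_uM": Tst, "Mst_uM": Mst, "Mst_source": mst_source},
        "rate_inference": inference,
        "exposure": exposure,
        "gain_bounds": bounds,
        "therapy": {
            "parameterisation": "degradation_dominated",
            "r": r_deg,
            "krem_M": krem_M,
            "baseline_Tst_uM": sim.baseline.T,
            "treated_Tst_uM": sim.treated_T_ss,
            "relative_increase": sim.relative_increase,
            "converged": sim.converged,
        },
        "clinical_comparison": {
            "observed_increase": CLINICAL_INCREASE,
            "max_model_bound": max(b["bound"] for b in bounds.values()),
            "model_explains_observation": any(
                not b["additional_mechanisms_required"] for b in bounds.values()),
        },
    }
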