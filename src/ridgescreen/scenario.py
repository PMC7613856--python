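"""Scenario files: YAML description of simulation grids for `evaluate`."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .evaluate import PROCEDURES, estimate_operating_characteristics
from .simulate import CorrelationStructure, EffectSpec, SimulationConfig

__all__ = ["Scenario", "EvaluationPlan", "load_plan", "run_plan"]


@dataclass
class Scenario:
    name: str
    sample_sizes: list[int]
    structure: CorrelationStructure
    effects: EffectSpec
    allocation: float = 0.5


@dataclass
class EvaluationPlan:
    scenarios: list[Scenario]
    procedures: list[str]
    replicates: int
    alpha: float
    alpha1: float
    B: int
    seed: int
    error_level: str = "cluster"


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValidationError(f"missing key {key!r} in {context}")
    return mapping[key]


def _parse_effects(raw: dict, context: str) -> EffectSpec:
    def int_keys(d: dict) -> dict[int, float]:
        try:
            return {int(k): float(v) for k, v in (d or {}).items()}
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"effect maps in {context} need integer keys: {exc}") from exc

    return EffectSpec(
        intercept=float(raw.get("intercept", 0.0)),
        treatment_effect=float(raw.get("treatment", 0.0)),
        main=int_keys(raw.get("main")),
        interaction=int_keys(raw.get("interaction")),
        noise_sd=float(_require(raw, "noise_sd", context)),
    )


def load_plan(path: str | Path) -> EvaluationPlan:
    """Parse and validate an evaluation-plan YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("scenario file must be a mapping at the top level")
    procedures = list(raw.get("procedures", PROCEDURES))
    unknown = [p for p in procedures if p not in PROCEDURES]
    if unknown:
        raise ValidationError(f"unknown procedure(s) {unknown}; expected one of {PROCEDURES}")
    scen_raw = _require(raw, "scenarios", "plan")
    if not isinstance(scen_raw, list) or not scen_raw:
        raise ValidationError("'scenarios' must be a non-empty list")
    scenarios = []
    for i, s in enumerate(scen_raw):
        ctx = f"scenario #{i + 1}"
        name = str(s.get("name", f"scenario{i + 1}"))
        n = _require(s, "n", ctx)
        sample_sizes = [int(v) for v in (n if isinstance(n, list) else [n])]
        structure = CorrelationStructure(
            m=int(_require(s, "m", ctx)),
            cluster_size=int(s.get("cluster_size", 20)),
            rho=float(s.get("rho", 0.0)),
        )
        effects = _parse_effects(_require(s, "effects", ctx), ctx)
        effects.validate_indices(structure.m)
        scenarios.append(
            Scenario(
                name=name,
                sample_sizes=sample_sizes,
                structure=structure,
                effects=effects,
                allocation=float(s.get("allocation", 0.5)),
            )
        )
    return EvaluationPlan(
        scenarios=scenarios,
        procedures=procedures,
        replicates=int(raw.get("replicates", 100)),
        alpha=float(raw.get("alpha", 0.05)),
        alpha1=float(raw.get("alpha1", 0.05)),
        B=int(raw.get("B", 5)),
        seed=int(raw.get("seed", 0)),
        error_level=str(raw.get("error_level", "cluster")),
    )


def run_plan(plan: EvaluationPlan) -> pd.DataFrame:
    """Run every scenario x sample size x procedure; tidy long-format result."""
    rows = []
    for scen in plan.scenarios:
        for n in scen.sample_sizes:
            config = SimulationConfig(
                n=n,
                effects=scen.effects,
                structure=scen.structure,
                allocation=scen.allocation,
                seed=plan.seed,
            )
            results = estimate_operating_characteristics(
                config,
                plan.procedures,
                R=plan.replicates,
                seed=plan.seed,
                alpha=plan.alpha,
                alpha1=plan.alpha1,
                B=plan.B,
                error_level=plan.error_level,
            )
            for proc, oc in results.items():
                for metric, value, se in (
                    ("power", oc.power, oc.power_se),
                    ("fwer", oc.fwer, oc.fwer_se),
                ):
                    if value is None:
                        continue
                    rows.append(
                        {
                            "scenario": scen.name,
                            "n": n,
                            "procedure": proc,
                            "metric": metric,
                            "estimate": value,
                            "mc_se": se,
                            "replicates": oc.replicates,
                        }
                    )
    return pd.DataFrame(rows)
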