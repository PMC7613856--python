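"""End-to-end procedures and Monte-Carlo operating characteristics.

Four procedures are assembled from the screening / testing / multiplicity
building blocks:

* ``no_screening``         — single-step Bonferroni interaction tests.
* ``univariate_threshold`` — univariate screen at level alpha1, then
  Bonferroni over the selected subset.
* ``univariate_rank``      — weighted bucket thresholds from the
  univariate p-value ranking.
* ``ridge_rank``           — weighted bucket thresholds from the ridge
  coefficient ranking.

``estimate_operating_characteristics`` replays a procedure over replicate
simulated trials (common random numbers across procedures) and estimates
cluster-discovery power and the familywise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .interaction import interaction_test_all
from .multiplicity import (
    DecisionSet,
    apply_schedule,
    bonferroni_schedule,
    subset_schedule,
    weighted_schedule,
)
from .screening import ridge_screen, univariate_screen
from .simulate import SimulationConfig, generate_trial
from .trial import TrialDataset

__all__ = [
    "PROCEDURES",
    "OperatingCharacteristics",
    "IndependenceDiagnostic",
    "run_procedure",
    "estimate_operating_characteristics",
    "between_stage_diagnostic",
]

PROCEDURES = ("no_screening", "univariate_threshold", "univariate_rank", "ridge_rank")


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo power / FWER estimates for one procedure and scenario.

    ``power`` is the cluster-discovery rate (probability of rejecting at
    least one biomarker in a cluster containing a true interaction); it is
    None when the scenario has no interacting biomarker.  ``fwer`` is the
    probability of at least one false rejection, where "false" defaults to
    the cluster-level event (a rejection in a cluster with no interacting
    member) and can be switched to the per-biomarker event.
    """

    procedure: str
    replicates: int
    power: float | None
    power_se: float | None
    fwer: float
    fwer_se: float
    error_level: str = "cluster"
    # per-replicate outcomes, kept so paired (common-random-number)
    # comparisons between procedures can be formed downstream
    replicate_discoveries: np.ndarray | None = None
    replicate_errors: np.ndarray | None = None


@dataclass
class IndependenceDiagnostic:
    """Pearson-correlation check between stage-1 and stage-2 statistics."""

    estimate: float
    p_value: float
    ci_low: float
    ci_high: float
    n_pairs: int


def run_procedure(
    data: TrialDataset,
    procedure: str,
    alpha: float = 0.05,
    alpha1: float = 0.05,
    B: int = 5,
    ridge_options: dict | None = None,
) -> DecisionSet:
    """Run one of the four screening-and-testing procedures on a dataset."""
    if procedure not in PROCEDURES:
        raise ConfigurationError(f"unknown procedure {procedure!r}; expected one of {PROCEDURES}")
    m = data.m
    if procedure == "no_screening":
        schedule = bonferroni_schedule(alpha, m)
        tests = interaction_test_all(data)
    elif procedure == "univariate_threshold":
        screening = univariate_screen(data)
        schedule = subset_schedule(alpha, screening, alpha1)
        tests = interaction_test_all(data, schedule.tested)
    elif procedure == "univariate_rank":
        screening = univariate_screen(data)
        schedule = weighted_schedule(alpha, screening.ranking, B)
        tests = interaction_test_all(data)
    else:  # ridge_rank
        screening = ridge_screen(data, **(ridge_options or {}))
        schedule = weighted_schedule(alpha, screening.ranking, B)
        tests = interaction_test_all(data)
    decisions = apply_schedule(tests, schedule)
    decisions.procedure = procedure
    return decisions


def _signal_clusters(config: SimulationConfig) -> np.ndarray:
    labels = config.structure.labels()
    hit = [labels[j - 1] for j, b in config.effects.interaction.items() if b != 0.0]
    return np.unique(np.asarray(hit, dtype=int))


def estimate_operating_characteristics(
    config: SimulationConfig,
    procedures: str | list[str],
    R: int,
    seed: int | None = None,
    alpha: float = 0.05,
    alpha1: float = 0.05,
    B: int = 5,
    ridge_options: dict | None = None,
    error_level: str = "cluster",
) -> dict[str, OperatingCharacteristics]:
    """Monte-Carlo power and FWER over ``R`` replicate trials.

    Replicate r uses seed ``seed + r`` (common random numbers: every
    procedure sees the same datasets).  Power is the per-replicate fraction
    of interaction-bearing clusters with at least one rejection; the
    familywise error event is a rejection in any cluster without an
    interacting member (``error_level="cluster"``), or a rejection of any
    biomarker whose own interaction coefficient is zero
    (``error_level="biomarker"``).
    """
    if R < 1:
        raise ConfigurationError("need at least one replicate")
    if error_level not in ("cluster", "biomarker"):
        raise ConfigurationError("error_level must be 'cluster' or 'biomarker'")
    if isinstance(procedures, str):
        procedures = [procedures]
    for proc in procedures:
        if proc not in PROCEDURES:
            raise ConfigurationError(f"unknown procedure {proc!r}")
    master = config.seed if seed is None else seed

    labels = config.structure.labels()
    signal_clusters = _signal_clusters(config)
    in_signal_cluster = np.isin(labels, signal_clusters)
    true_interactor = np.zeros(config.structure.m, dtype=bool)
    for j, b in config.effects.interaction.items():
        if b != 0.0:
            true_interactor[j - 1] = True

    discoveries = {p: np.zeros(R) for p in procedures}
    errors = {p: np.zeros(R, dtype=bool) for p in procedures}
    for r in range(R):
        data = generate_trial(replace(config, seed=master + r))
        ridge_opts = dict(ridge_options or {})
        ridge_opts.setdefault("cv_seed", master + r)
        for proc in procedures:
            decisions = run_procedure(
                data, proc, alpha=alpha, alpha1=alpha1, B=B, ridge_options=ridge_opts
            )
            rej = decisions.rejected  # 1-based
            if signal_clusters.size:
                rej_clusters = np.unique(labels[rej - 1]) if rej.size else np.empty(0, dtype=int)
                found = np.isin(signal_clusters, rej_clusters).sum()
                discoveries[proc][r] = found / signal_clusters.size
            if rej.size:
                if error_level == "cluster":
                    errors[proc][r] = bool((~in_signal_cluster[rej - 1]).any())
                else:
                    errors[proc][r] = bool((~true_interactor[rej - 1]).any())

    out: dict[str, OperatingCharacteristics] = {}
    for proc in procedures:
        fwer = float(errors[proc].mean())
        if signal_clusters.size:
            power = float(discoveries[proc].mean())
            power_se = float(np.sqrt(power * (1.0 - power) / R))
        else:
            power = power_se = None
        out[proc] = OperatingCharacteristics(
            procedure=proc,
            replicates=R,
            power=power,
            power_se=power_se,
            fwer=fwer,
            fwer_se=float(np.sqrt(fwer * (1.0 - fwer) / R)),
            error_level=error_level,
            replicate_discoveries=discoveries[proc] if signal_clusters.size else None,
            replicate_errors=errors[proc],
        )
    return out


def between_stage_diagnostic(stage1: np.ndarray, stage2: np.ndarray) -> IndependenceDiagnostic:
    """Pearson correlation between paired stage-1 and stage-2 statistics,
    with two-sided p-value and Fisher-z 95% confidence interval."""
    stage1 = np.asarray(stage1, dtype=float)
    stage2 = np.asarray(stage2, dtype=float)
    if stage1.shape != stage2.shape or stage1.ndim != 1:
        raise ConfigurationError("stage-1 and stage-2 statistics must be equal-length vectors")
    n = stage1.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 pairs")
    if np.std(stage1) == 0.0 or np.std(stage2) == 0.0:
        raise ConfigurationError("correlation undefined for a constant input vector")
    r, p = stats.pearsonr(stage1, stage2)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return IndependenceDiagnostic(
        estimate=float(r),
        p_value=float(p),
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        n_pairs=n,
    )
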