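"""Tabular I/O and preprocessing (missingness filter, imputation, variance filter)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .trial import TrialDataset

__all__ = [
    "ColumnRoles",
    "read_trial_table",
    "write_trial_table",
    "filter_and_impute",
    "top_variance_filter",
]

logger = logging.getLogger(__name__)


@dataclass
class ColumnRoles:
    """Column-role assignment for a trial table."""

    outcome: str = "outcome"
    treatment: str = "treatment"
    biomarkers: list[str] = field(default_factory=list)  # empty = all remaining columns


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","

def read_trial_table(path: str | Path, roles: ColumnRoles | None = None) -> tuple[pd.DataFrame, ColumnRoles]:
    """Read a delimited trial table (CSV/TSV by extension) and validate roles.

    Returns the raw (possibly missing-valued) table and the resolved roles;
    per-column missingness is logged.  Treatment must be codable to {0,1}
    on its observed values.
    """
    path = Path(path)
    roles = roles or ColumnRoles()
    sep = _delimiter_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen: set[str] = set()
    dupes = sorted({c for c in header if c in seen or seen.add(c)})
    if dupes:
        raise ValidationError(f"duplicate column names: {dupes}")
    table = pd.read_csv(path, sep=sep)
    for role, col in (("outcome", roles.outcome), ("treatment", roles.treatment)):
        if col not in table.columns:
            raise ValidationError(f"{role} column {col!r} not found in {path.name}")
    if not roles.biomarkers:
        roles = ColumnRoles(
            outcome=roles.outcome,
            treatment=roles.treatment,
            biomarkers=[c for c in table.columns if c not in (roles.outcome, roles.treatment)],
        )
    missing_cols = [c for c in roles.biomarkers if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"biomarker columns not found: {missing_cols}")
    if not roles.biomarkers:
        raise ValidationError("table contains no biomarker columns")
    t_observed = table[roles.treatment].dropna()
    t_values = set(pd.unique(t_observed))
    if not t_values <= {0, 1, 0.0, 1.0}:
        raise ValidationError(
            f"treatment column {roles.treatment!r} is not binary 0/1; offending values: "
            f"{sorted(v for v in t_values if v not in (0, 1))}"
        )
    frac = table[roles.biomarkers].isna().mean()
    for col, f in frac[frac > 0].items():
        logger.info("column %s: %.1f%% missing", col, 100 * f)
    return table, roles


def write_trial_table(data: TrialDataset, path: str | Path) -> None:
    """Write a TrialDataset as a delimited table (outcome, treatment, X1..Xm)."""
    path = Path(path)
    frame = pd.DataFrame({"outcome": data.outcome, "treatment": data.treatment.astype(int)})
    frame = pd.concat([frame, pd.DataFrame(data.biomarkers, columns=data.names)], axis=1)
    frame.to_csv(path, sep=_delimiter_for(path), index=False)


def filter_and_impute(
    table: pd.DataFrame, roles: ColumnRoles, max_missing: float = 0.10
) -> TrialDataset:
    """Apply the missingness rules and build a complete TrialDataset.

    Rows with missing outcome or treatment are dropped (count logged).
    Biomarker columns with a missing fraction strictly greater than
    ``max_missing`` are removed; remaining missing values are replaced by
    the observed-value column mean.
    """
    complete = table[roles.outcome].notna() & table[roles.treatment].notna()
    dropped_rows = int((~complete).sum())
    if dropped_rows:
        logger.info("dropped %d rows with missing outcome/treatment", dropped_rows)
    table = table.loc[complete]

    frac = table[roles.biomarkers].isna().mean()
    keep = [c for c in roles.biomarkers if frac[c] <= max_missing]
    removed = [c for c in roles.biomarkers if frac[c] > max_missing]
    if removed:
        logger.info("removed %d biomarker column(s) over the missingness cutoff: %s",
                    len(removed), removed)
    if not keep:
        raise ValidationError("all biomarker columns exceed the missingness cutoff")
    x = table[keep].astype(float)
    x = x.fillna(x.mean())
    return TrialDataset(
        outcome=table[roles.outcome].to_numpy(dtype=float),
        treatment=table[roles.treatment].to_numpy(dtype=float),
        biomarkers=x.to_numpy(),
        names=keep,
    )


def top_variance_filter(data: TrialDataset, k: int) -> TrialDataset:
    """Keep the k biomarkers with the largest (unbiased) sample variance.

    Ties break by column order, so the result is deterministic.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    if k > data.m:
        raise ConfigurationError(f"k={k} exceeds number of biomarkers m={data.m}")
    variances = data.biomarkers.var(axis=0, ddof=1)
    order = np.lexsort((np.arange(data.m), -variances))
    keep = np.sort(order[:k])
    return data.subset_biomarkers(keep)
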