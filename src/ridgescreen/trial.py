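"""Core container for a (real or simulated) randomized-trial dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["TrialDataset"]


@dataclass
class TrialDataset:
    """Outcome, treatment indicator and biomarker matrix for one trial.

    Parameters
    ----------
    outcome
        Length-``n`` continuous response vector.
    treatment
        Length-``n`` binary (0/1) treatment-arm indicator.
    biomarkers
        ``n x m`` matrix of biomarker values, one column per biomarker.
    names
        Length-``m`` biomarker names; defaults to ``X1 .. Xm``.
    clusters
        Optional length-``m`` integer cluster label per biomarker
        (1-based). Used only by the simulation/evaluation layer.
    """

    outcome: np.ndarray
    treatment: np.ndarray
    biomarkers: np.ndarray
    names: list[str] = field(default_factory=list)
    clusters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.biomarkers = np.atleast_2d(np.asarray(self.biomarkers, dtype=float))
        n = self.outcome.shape[0]
        if self.outcome.ndim != 1 or self.treatment.shape != (n,):
            raise ValidationError("outcome and treatment must be 1-d vectors of equal length")
        if self.biomarkers.shape[0] != n:
            raise ValidationError(
                f"biomarker matrix has {self.biomarkers.shape[0]} rows, expected {n}"
            )
        uniq = set(np.unique(self.treatment))
        if not uniq <= {0.0, 1.0}:
            raise ValidationError(f"treatment values must be 0/1, got {sorted(uniq)}")
        if not self.names:
            self.names = [f"X{j}" for j in range(1, self.m + 1)]
        if len(self.names) != self.m:
            raise ValidationError("names length does not match number of biomarkers")
        if self.clusters is not None:
            self.clusters = np.asarray(self.clusters, dtype=int)
            if self.clusters.shape != (self.m,):
                raise ValidationError("cluster labels must have one entry per biomarker")
        if np.isnan(self.outcome).any() or np.isnan(self.biomarkers).any():
            raise ValidationError("dataset contains missing values; preprocess first")

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def m(self) -> int:
        return self.biomarkers.shape[1]

    def subset_biomarkers(self, keep: np.ndarray) -> "TrialDataset":
        """Return a copy restricted to the biomarker columns ``keep`` (0-based)."""
        keep = np.asarray(keep, dtype=int)
        return TrialDataset(
            outcome=self.outcome.copy(),
            treatment=self.treatment.copy(),
            biomarkers=self.biomarkers[:, keep].copy(),
            names=[self.names[j] for j in keep],
            clusters=None if self.clusters is None else self.clusters[keep].copy(),
        )
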