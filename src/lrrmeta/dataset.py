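"""Containers and CSV ingestion for meta-analytic datasets.

A :class:`MetaDataset` is an ordered collection of study-level LRR effects
and within-study variances, optionally carrying the arm-level summaries
they were computed from (required by the sample-size-weighted estimator).

CSV schema (header required)::

    study_id, n_t, mean_t, sd_t, n_c, mean_c, sd_c

Missing SDs are an error; no imputation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import ArmSummary, StudyEffect, compute_lrr

__all__ = ["MetaDataset", "read_dataset", "CSV_COLUMNS"]

CSV_COLUMNS = ["study_id", "n_t", "mean_t", "sd_t", "n_c", "mean_c", "sd_c"]


@dataclass
class MetaDataset:
    """Ordered collection of K >= 2 study effects.

    Attributes
    ----------
    effects : list of StudyEffect
    labels : list of str
        Study identifiers, same order as ``effects``.
    arms : list of (ArmSummary, ArmSummary) or None
        (treatment, control) summaries per study when available.
    """

    effects: list[StudyEffect]
    labels: list[str] = field(default_factory=list)
    arms: list[tuple[ArmSummary, ArmSummary]] | None = None

    def __post_init__(self) -> None:
        if len(self.effects) < 2:
            raise ValueError(f"need at least 2 studies, got {len(self.effects)}")
        if not self.labels:
            self.labels = [f"study_{i + 1}" for i in range(len(self.effects))]
        if len(self.labels) != len(self.effects):
            raise ValueError("labels and effects length mismatch")
        if self.arms is not None and len(self.arms) != len(self.effects):
            raise ValueError("arms and effects length mismatch")

    @property
    def k(self) -> int:
        return len(self.effects)

    @property
    def lrr(self) -> np.ndarray:
        return np.array([e.lrr for e in self.effects])

    @property
    def var(self) -> np.ndarray:
        return np.array([e.var for e in self.effects])

    @property
    def effective_n(self) -> np.ndarray:
        """Per-study effective sample size ñ_i = n_T·n_C/(n_T + n_C)."""
        if self.arms is None:
            raise ValueError("arm-level sample sizes are not available")
        return np.array([t.n * c.n / (t.n + c.n) for t, c in self.arms])

    @classmethod
    def from_arrays(
        cls,
        lrr: Sequence[float],
        var: Sequence[float],
        labels: Sequence[str] | None = None,
    ) -> "MetaDataset":
        effects = [StudyEffect(lrr=float(y), var=float(v)) for y, v in zip(lrr, var)]
        return cls(effects=effects, labels=list(labels) if labels else [])

    @classmethod
    def from_arms(
        cls,
        arms: Sequence[tuple[ArmSummary, ArmSummary]],
        labels: Sequence[str] | None = None,
        bias_correct: bool = False,
    ) -> "MetaDataset":
        effects = [compute_lrr(t, c, bias_correct=bias_correct) for t, c in arms]
        return cls(
            effects=effects,
            labels=list(labels) if labels else [],
            arms=list(arms),
        )

    def with_bias_correction(self, bias_correct: bool = True) -> "MetaDataset":
        """Recompute all effects from stored arms with/without bias correction."""
        if self.arms is None:
            raise ValueError("arm-level summaries are required to recompute effects")
        return MetaDataset.from_arms(self.arms, labels=self.labels, bias_correct=bias_correct)

    def subset(self, indices: Sequence[int]) -> "MetaDataset":
        idx = list(indices)
        return MetaDataset(
            effects=[self.effects[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            arms=None if self.arms is None else [self.arms[i] for i in idx],
        )


def read_dataset(path: str | Path, bias_correct: bool = False) -> MetaDataset:
    """Read a study-summary CSV into a validated :class:`MetaDataset`.

    Raises ``ValueError`` naming the offending study for non-numeric cells,
    n < 2, missing SDs, or non-positive means; missing columns are reported
    collectively.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")

    arms: list[tuple[ArmSummary, ArmSummary]] = []
    labels: list[str] = []
    for _, row in table.iterrows():
        sid = str(row["study_id"])
        values = {}
        for col in CSV_COLUMNS[1:]:
            val = pd.to_numeric(row[col], errors="coerce")
            if pd.isna(val):
                raise ValueError(f"study {sid!r}: non-numeric or missing {col}")
            values[col] = float(val)
        try:
            t = ArmSummary(n=int(values["n_t"]), mean=values["mean_t"], sd=values["sd_t"])
            c = ArmSummary(n=int(values["n_c"]), mean=values["mean_c"], sd=values["sd_c"])
            if t.mean <= 0 or c.mean <= 0:
                raise ValueError("non-positive sample mean")
        except ValueError as err:
            raise ValueError(f"study {sid!r}: {err}") from err
        arms.append((t, c))
        labels.append(sid)

    return MetaDataset.from_arms(arms, labels=labels, bias_correct=bias_correct)
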