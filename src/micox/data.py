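"""Core data containers shared across the package.

Expression matrices are plain :class:`pandas.DataFrame` objects with
samples as rows (index = sample IDs) and genes as columns (header = gene
IDs). Survival data is a small immutable record of per-sample follow-up
times (months) and event indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurvivalData", "validate_expression"]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival outcomes.

    Attributes
    ----------
    time : ndarray of float
        Positive follow-up times in months.
    status : ndarray of int
        1 = event (death) observed, 0 = censored.
    sample_ids : ndarray
        Per-sample identifiers, aligned with ``time``/``status``.
    """

    time: np.ndarray
    status: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        ids = np.asarray(self.sample_ids)
        if not (time.shape == status.shape == ids.shape):
            raise ValueError("time, status and sample_ids must be aligned 1-d arrays")
        if time.ndim != 1:
            raise ValueError("survival data must be one-dimensional")
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be positive finite months")
        if not np.all(np.isin(status, [0, 1])):
            raise ValueError("status must contain only 0 (censored) and 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(np.int64))
        object.__setattr__(self, "sample_ids", ids)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @classmethod
    def from_arrays(cls, time, status, sample_ids=None) -> "SurvivalData":
        time = np.asarray(time, dtype=float)
        if sample_ids is None:
            sample_ids = np.array([f"S{i}" for i in range(time.size)])
        return cls(time=time, status=np.asarray(status), sample_ids=np.asarray(sample_ids))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "survival_time_months",
        status_col: str = "event_status",
        id_col: str = "sample_id",
    ) -> "SurvivalData":
        ids = df[id_col].to_numpy() if id_col in df.columns else df.index.to_numpy()
        return cls(time=df[time_col].to_numpy(dtype=float), status=df[status_col].to_numpy(), sample_ids=ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "survival_time_months": self.time,
                "event_status": self.status,
            }
        )

    def subset(self, mask_or_ids) -> "SurvivalData":
        """Select samples by boolean mask or by an ID sequence (in that order)."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            missing = [s for s in arr if s not in pos]
            if missing:
                if np.issubdtype(arr.dtype, np.integer):
                    # positional fallback for plain index arrays
                    idx = arr.astype(np.int64)
                    if idx.size and (idx.min() < 0 or idx.max() >= len(self)):
                        raise IndexError("positional indices out of range")
                    return SurvivalData(
                        time=self.time[idx],
                        status=self.status[idx],
                        sample_ids=self.sample_ids[idx],
                    )
                raise KeyError(f"unknown sample IDs: {missing}")
            idx = np.array([pos[s] for s in arr], dtype=np.int64)
        return SurvivalData(
            time=self.time[idx], status=self.status[idx], sample_ids=self.sample_ids[idx]
        )


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x genes expression frame; returns a float copy.

    Rejects duplicate sample or gene IDs, non-numeric cells and missing
    values (naming the offending genes and samples).
    """
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dups}")
    try:
        out = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"expression matrix contains non-numeric cells: {exc}") from exc
    bad = ~np.isfinite(out.to_numpy())
    if bad.any():
        rows, cols = np.nonzero(bad)
        pairs = [
            f"(sample={out.index[r]}, gene={out.columns[c]})" for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(
            f"expression matrix has {bad.sum()} missing/non-finite cells, e.g. {', '.join(pairs)}"
        )
    return out
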