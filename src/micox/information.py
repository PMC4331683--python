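"""Discretization, entropy and mutual-information statistics.

The central quantity is the pairwise outcome statistic ``I(X1, X2; Y)``:
the mutual information between a *pair* of genomic features, treated as a
single composite variable, and a binarized clinical outcome. It captures
joint (interaction) effects on the outcome that marginal measures such as
``I(X1; Y)`` miss entirely -- the canonical example being an XOR-style
dependence where each gene alone is uninformative.

All entropies and mutual informations are reported in bits (log base 2).
Continuous feature values are discretized with an equal-width histogram
before any information quantity is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizedVector",
    "BinaryOutcome",
    "discretize",
    "entropy",
    "mutual_information",
    "pair_outcome_mi",
    "binarize_outcome",
]


@dataclass(frozen=True)
class DiscretizedVector:
    """A vector of integer bin codes produced by :func:`discretize`.

    Attributes
    ----------
    codes : ndarray of int
        Bin label per sample, each in ``[0, n_bins)``.
    n_bins : int
        Number of histogram bins actually used (1 for a constant input).
    bin_edges : ndarray of float
        ``n_bins + 1`` edges; strictly increasing unless the source vector
        was constant.
    """

    codes: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.n_bins):
            raise ValueError("codes must lie in [0, n_bins)")

    def __len__(self) -> int:
        return self.codes.size


@dataclass(frozen=True)
class BinaryOutcome:
    """Binarized survival outcome: short-term (0) vs long-term (1) survival.

    Samples censored before the threshold carry no usable label (their
    long-term status is unknown) and are flagged ``kept_mask = False``.
    ``labels`` is only meaningful where ``kept_mask`` is True.
    """

    labels: np.ndarray
    threshold_months: float
    kept_mask: np.ndarray
    sample_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.labels.shape != self.kept_mask.shape:
            raise ValueError("labels and kept_mask must have the same shape")

    @property
    def kept_labels(self) -> np.ndarray:
        """Labels restricted to the kept samples."""
        return self.labels[self.kept_mask]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


def _as_codes(x) -> np.ndarray:
    if isinstance(x, DiscretizedVector):
        return x.codes
    return np.asarray(x, dtype=np.int64)


def discretize(values, n_bins: int = 3) -> DiscretizedVector:
    """Equal-width histogram discretization of a real-valued vector.

    Bins span ``[min, max]`` of the data; the maximum value is assigned to
    the last bin. A constant vector collapses to a single bin rather than
    erroring, because flat features do occur in real profiles.

    Parameters
    ----------
    values : array-like of float
        Non-empty vector of finite values.
    n_bins : int
        Requested number of bins, ``>= 1``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if v.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if not np.all(np.isfinite(v)):
        raise ValueError("values contain non-finite entries")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return DiscretizedVector(
            codes=np.zeros(v.size, dtype=np.int64),
            n_bins=1,
            bin_edges=np.array([lo, hi]),
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    codes = np.minimum(((v - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)
    return DiscretizedVector(codes=codes, n_bins=n_bins, bin_edges=edges)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    # sorting makes the float sum exactly invariant to cell relabeling
    p = np.sort(counts[counts > 0]) / n
    return float(-(p * np.log2(p)).sum())


def entropy(*vectors, joint: bool = True) -> float:
    """Empirical (joint) Shannon entropy in bits.

    With one vector, returns its marginal entropy; with several, the joint
    entropy of the tuple (``joint`` is accepted for interface clarity but
    multiple vectors are always combined jointly). ``0 * log 0`` is 0.
    """
    if not vectors:
        raise ValueError("at least one vector required")
    codes = [_as_codes(v) for v in vectors]
    n = codes[0].size
    if n == 0:
        raise ValueError("vectors must be non-empty")
    for c in codes:
        if c.size != n:
            raise ValueError("all vectors must have the same length")
    if len(codes) == 1:
        _, counts = np.unique(codes[0], return_counts=True)
    else:
        _, counts = np.unique(np.column_stack(codes), axis=0, return_counts=True)
    return _entropy_from_counts(counts)


def mutual_information(x, y) -> float:
    """I(X; Y) = H(X) + H(Y) - H(X, Y), in bits, clamped at 0."""
    cx, cy = _as_codes(x), _as_codes(y)
    if cx.size != cy.size:
        raise ValueError("x and y must have the same length")
    mi = entropy(cx) + entropy(cy) - entropy(cx, cy)
    return max(mi, 0.0)


def pair_outcome_mi(x1, x2, y) -> float:
    """I(X1, X2; Y): information the gene *pair* carries about the outcome.

    The pair ``(x1, x2)`` is treated as one composite discrete variable, so
    the statistic is symmetric under swapping its members and is never less
    than either marginal ``I(Xi; Y)``. When ``y`` is a
    :class:`BinaryOutcome`, all vectors are restricted to its kept samples.
    """
    c1, c2 = _as_codes(x1), _as_codes(x2)
    if isinstance(y, BinaryOutcome):
        mask = y.kept_mask
        if c1.size != mask.size or c2.size != mask.size:
            raise ValueError("x1, x2 and outcome must have the same length")
        c1, c2, cy = c1[mask], c2[mask], y.labels[mask]
    else:
        cy = _as_codes(y)
    if not (c1.size == c2.size == cy.size):
        raise ValueError("x1, x2 and y must have the same length")
    if c1.size < 2:
        raise ValueError("need at least 2 kept samples")
    # composite code for the pair
    pair = c1 * (c2.max() + 1) + c2
    mi = entropy(pair) + entropy(cy) - entropy(pair, cy)
    return max(mi, 0.0)


def binarize_outcome(surv, threshold_months: float = 36.0) -> BinaryOutcome:
    """Convert survival (time, status) to a binary long/short-term label.

    A sample is labelled 1 (long-term) when its survival time exceeds the
    threshold and 0 otherwise. Samples censored *before* the threshold are
    dropped (``kept_mask = False``): they are alive at last contact but we
    cannot know whether they survived past the threshold.

    Parameters
    ----------
    surv : SurvivalData
        Per-sample times (months) and event status.
    threshold_months : float
        Positive cut between short- and long-term survival (default 36,
        i.e. 3 years).
    """
    if threshold_months <= 0:
        raise ValueError("threshold_months must be positive")
    time = np.asarray(surv.time, dtype=float)
    status = np.asarray(surv.status, dtype=np.int64)
    labels = (time > threshold_months).astype(np.int64)
    kept = ~((status == 0) & (time < threshold_months))
    ids = getattr(surv, "sample_ids", None)
    return BinaryOutcome(
        labels=labels,
        threshold_months=float(threshold_months),
        kept_mask=kept,
        sample_ids=None if ids is None else np.asarray(ids),
    )
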