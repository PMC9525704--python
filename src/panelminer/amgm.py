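"""AMGM dispersion scores.

The arithmetic-mean-to-geometric-mean ratio (AMGM) of a feature vector is a
dispersion measure R >= 1 that equals 1 exactly when the feature is constant.
The classic form AM/GM collapses to an uninformative 0-denominator whenever a
single sample reports zero — ubiquitous in expression data — so the modified
form exponentiates values first:

    R = mean(exp(x)) / exp(mean(x))

which is the AM/GM ratio of exp(x) and is finite for any finite input.  Scores
are intended to be computed on min-max-scaled training data so the
exponentials stay bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AMGMScores", "amgm_score", "amgm_scores", "select_top_k"]


@dataclass
class AMGMScores:
    """Per-feature AMGM dispersion scores (variant 'classic' or 'modified')."""

    feature_ids: list[str]
    r: np.ndarray
    am: np.ndarray
    gm: np.ndarray
    mean: np.ndarray
    variant: str

    def __getitem__(self, feature_id: str) -> float:
        return float(self.r[self.feature_ids.index(feature_id)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_ids, map(float, self.r)))

    def to_frame(self) -> pd.DataFrame:
        order = np.lexsort((np.array(self.feature_ids, dtype=object), -self.r))
        return pd.DataFrame(
            {
                "feature_id": [self.feature_ids[i] for i in order],
                "amgm": self.r[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def _scores(values: np.ndarray, variant: str) -> tuple[np.ndarray, ...]:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if variant == "modified":
        xbar = values.mean(axis=0)
        # mean(exp(x)) / exp(xbar) computed as mean(exp(x - xbar)): exact and
        # immune to overflow for shifted data
        r = np.exp(values - xbar).mean(axis=0)
        am = np.exp(values).mean(axis=0)
        gm = np.exp(xbar)
        # constant features score exactly 1 (AM = GM); the floating-point
        # mean of n equal values need not be one of them, so force exactness
        constant = values.max(axis=0) == values.min(axis=0)
        r = np.where(constant, 1.0, r)
    elif variant == "classic":
        if np.any(values <= 0):
            raise ValueError(
                "classic AMGM requires strictly positive values "
                "(a zero makes the geometric mean vanish); use variant='modified'"
            )
        xbar = values.mean(axis=0)
        am = xbar
        gm = np.exp(np.log(values).mean(axis=0))
        r = am / gm
    else:
        raise ValueError("variant must be 'classic' or 'modified'")
    return r, am, gm, xbar


def amgm_score(values, variant: str = "modified") -> float:
    """AMGM dispersion of a single feature vector."""
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    r, *_ = _scores(v, variant)
    return float(r[0])


def amgm_scores(X, variant: str = "modified") -> AMGMScores:
    """AMGM dispersion of every feature of a cohort (columns of ``X.values``)."""
    r, am, gm, mean = _scores(X.values, variant)
    return AMGMScores(
        feature_ids=list(X.feature_ids), r=r, am=am, gm=gm, mean=mean, variant=variant
    )


def select_top_k(scores: AMGMScores, k: int) -> list[str]:
    """IDs of the ``k`` highest-scoring features, sorted by descending score.

    Ties are broken by feature-ID sort order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scores.feature_ids):
        raise ValueError(f"k={k} exceeds the number of features ({len(scores.feature_ids)})")
    order = np.lexsort((np.array(scores.feature_ids, dtype=object), -scores.r))
    return [scores.feature_ids[i] for i in order[:k]]
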