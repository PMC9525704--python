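"""Reading, redundancy removal, hold-out splitting and normalization.

Two per-feature transforms are supported, both with parameters estimated on
the training partition only:

* z-score:  y = (x - mu) / sigma          (population standard deviation)
* min-max:  y = (x - Min) / (Max - Min)   (values clipped to [0, 1] outside
  the training range, so downstream discretization stays well defined)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LabeledExpression

__all__ = [
    "SplitDataset",
    "NormalizationParams",
    "read_expression_table",
    "remove_redundant_features",
    "split_holdout",
    "fit_normalization",
    "zscore_normalize",
    "minmax_normalize",
]


@dataclass
class SplitDataset:
    """Stratified hold-out partitions (default 70/10/20 train/validation/test)."""

    train: LabeledExpression
    validation: LabeledExpression
    test: LabeledExpression
    fractions: tuple[float, float, float]
    seed: int

    @property
    def parts(self) -> dict[str, LabeledExpression]:
        return {"train": self.train, "validation": self.validation, "test": self.test}


@dataclass
class NormalizationParams:
    """Train-estimated per-feature mean/sd and min/max."""

    feature_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    vmin: np.ndarray
    vmax: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mu": self.mu,
                "sigma": self.sigma,
                "min": self.vmin,
                "max": self.vmax,
            }
        )

    def _check(self, X: LabeledExpression) -> None:
        if list(X.feature_ids) != list(self.feature_ids):
            raise ValueError("normalization parameters were fitted on a different feature set")


def read_expression_table(
    path: str,
    orientation: str = "samples",
    label_source: str = "embedded",
    sep: str = "\t",
) -> LabeledExpression:
    """Read a delimited expression table into a samples x features cohort.

    ``orientation='features'`` transposes a features-in-rows table.
    ``label_source`` is either ``'embedded'`` (a ``subtype`` column in the
    matrix file) or the path of a sidecar TSV with columns
    (sample_id, subtype).
    """
    if orientation not in ("samples", "features"):
        raise ValueError("orientation must be 'samples' or 'features'")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    labels_by_sample: dict[str, str] = {}
    if label_source == "embedded":
        if orientation != "samples":
            raise ValueError("embedded labels require samples-in-rows orientation")
        if "subtype" not in df.columns:
            raise ValueError(f"{path}: no 'subtype' column for embedded labels")
        labels_by_sample = df["subtype"].to_dict()
        df = df.drop(columns=["subtype"])
    if orientation == "features":
        df = df.T
    # strict numeric parse with coordinates in the error message
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & ~df.isna().to_numpy() | df.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at sample "
            f"{df.index[i]!r}, feature {df.columns[j]!r}"
        )
    if label_source != "embedded":
        lab = pd.read_csv(label_source, sep=sep, dtype=str)
        labels_by_sample = dict(zip(lab["sample_id"], lab["subtype"]))
    missing = [s for s in df.index if s not in labels_by_sample or pd.isna(labels_by_sample[s])]
    if missing:
        raise ValueError(f"missing subtype label for sample(s): {missing[:5]}")
    labels = np.array([labels_by_sample[s] for s in df.index], dtype=object)
    # numpy's strtod is round-trip exact; pandas' fast parser is not
    values = df.to_numpy(dtype=str).astype(float)
    return LabeledExpression(
        values=values,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        labels=labels,
    )


def remove_redundant_features(
    X: LabeledExpression,
) -> tuple[LabeledExpression, list[str]]:
    """Drop zero-variance features and exact duplicate columns.

    Among exact duplicates the feature first in feature-ID sort order is kept.
    Returns the reduced cohort and the sorted list of removed feature IDs.
    """
    if X.n_features == 0 or X.n_samples == 0:
        raise ValueError("empty matrix")
    removed: set[str] = set()
    var = X.values.var(axis=0)
    for j in np.flatnonzero(var == 0.0):
        removed.add(X.feature_ids[j])
    seen: dict[bytes, str] = {}
    order = np.argsort(np.array(X.feature_ids, dtype=object))
    for j in order:
        fid = X.feature_ids[j]
        if fid in removed:
            continue
        key = X.values[:, j].tobytes()
        if key in seen:
            removed.add(fid)
        else:
            seen[key] = fid
    kept = [f for f in X.feature_ids if f not in removed]
    if not kept:
        raise ValueError("redundancy removal would discard every feature")
    return X.subset_features(kept), sorted(removed)


def _largest_remainder(total: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [total * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    short = total - sum(counts)
    # distribute leftovers by descending remainder; ties by partition order
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_holdout(
    X: LabeledExpression,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> SplitDataset:
    """Stratified train/validation/test hold-out split.

    Per-class counts follow largest-remainder rounding of the target
    fractions; membership within a class is a seeded random permutation.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    part_idx: dict[str, list[int]] = {"train": [], "validation": [], "test": []}
    for cls in X.classes:
        members = np.flatnonzero(X.labels == cls)
        if len(members) < 3:
            raise ValueError(
                f"class {cls!r} has {len(members)} samples; need >= 3 to populate all partitions"
            )
        counts = _largest_remainder(len(members), fractions)
        perm = rng.permutation(members)
        part_idx["train"].extend(perm[: counts[0]])
        part_idx["validation"].extend(perm[counts[0] : counts[0] + counts[1]])
        part_idx["test"].extend(perm[counts[0] + counts[1] :])
    parts = {
        name: X.take_samples(np.sort(np.array(idx, dtype=int)))
        for name, idx in part_idx.items()
    }
    return SplitDataset(
        train=parts["train"],
        validation=parts["validation"],
        test=parts["test"],
        fractions=fractions,
        seed=seed,
    )


def fit_normalization(train: LabeledExpression) -> NormalizationParams:
    """Estimate per-feature mu/sigma (population sd) and min/max on training data."""
    v = train.values
    return NormalizationParams(
        feature_ids=list(train.feature_ids),
        mu=v.mean(axis=0),
        sigma=v.std(axis=0),
        vmin=v.min(axis=0),
        vmax=v.max(axis=0),
    )


def _transformed(X: LabeledExpression, values: np.ndarray) -> LabeledExpression:
    return LabeledExpression(
        values=values,
        sample_ids=list(X.sample_ids),
        feature_ids=list(X.feature_ids),
        labels=X.labels.copy(),
        provenance=None if X.provenance is None else X.provenance.copy(),
        groups=None if X.groups is None else X.groups.copy(),
    )


def zscore_normalize(X: LabeledExpression, params: NormalizationParams) -> LabeledExpression:
    """Apply y = (x - mu) / sigma with train-estimated parameters."""
    params._check(X)
    zero = np.flatnonzero(params.sigma == 0.0)
    if zero.size:
        raise ValueError(f"zero standard deviation for feature {params.feature_ids[zero[0]]!r}")
    return _transformed(X, (X.values - params.mu) / params.sigma)


def minmax_normalize(X: LabeledExpression, params: NormalizationParams) -> LabeledExpression:
    """Apply y = (x - Min) / (Max - Min); out-of-range values clip to [0, 1]."""
    params._check(X)
    flat = np.flatnonzero(params.vmax == params.vmin)
    if flat.size:
        raise ValueError(f"constant training range for feature {params.feature_ids[flat[0]]!r}")
    scaled = (X.values - params.vmin) / (params.vmax - params.vmin)
    return _transformed(X, np.clip(scaled, 0.0, 1.0))
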