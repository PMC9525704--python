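"""Synthetic multi-subtype expression cohorts.

The generator emulates the statistical structure of a TCGA-style renal-cell
carcinoma cohort: a handful of strongly imbalanced subtype classes, a minority
of subtype-informative high-dispersion features, blocks of mutually redundant
(near-duplicate) features, constant/all-zero features, a large background of
uninformative noise features, and optional planted item-co-occurrence patterns
that association-rule mining should recover as class rules.

Expression intensities are log-normal: each feature's value is ``exp(g)`` with
``g`` Gaussian on the log scale.  Informative features shift their log-mean by
``effect_size`` in one subtype (up or down) for a random ``responder_frac`` of
that subtype's samples, and members of one signal group share a latent factor
(moderate within-group correlation, as real expression signatures do);
redundant features are near-duplicate jittered copies of an informative
template; constant features are identically zero.  Background ("noise")
features are zero-inflated: each is detected in a random fraction of samples
and sits at a low detection floor elsewhere — the dropout-zero texture of
real expression matrices, and the reason the modified AMGM score exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "PlantedRule",
    "SimConfig",
    "LabeledExpression",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "recovery_scenario",
]

#: Discretization levels used by planted rules and by rule mining.
LEVELS = ("low", "medium", "high")

# Sampling bands inside each equal-width third of [0, 1]; margins keep planted
# values inside their bin after the slight shift introduced by min-max scaling.
_LEVEL_BANDS = {"low": (0.03, 0.30), "medium": (0.36, 0.63), "high": (0.70, 0.97)}


@dataclass(frozen=True)
class PlantedRule:
    """A planted co-occurrence pattern: ``features`` of samples of ``subtype``
    are forced into the given discretization ``levels`` with high probability.
    """

    features: tuple[str, ...]
    levels: tuple[str, ...]
    subtype: str

    def __post_init__(self) -> None:
        if len(self.features) != len(self.levels):
            raise ValueError("planted rule needs one level per feature")
        for lev in self.levels:
            if lev not in LEVELS:
                raise ValueError(f"unknown level {lev!r}; expected one of {LEVELS}")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the mRNA arm of the study cohort this generator emulates:
    three imbalanced subtypes of 611/321/89 patients.  ``frac_informative`` of
    the features carry a subtype signal; informative features are assigned
    round-robin to ``n_informative_groups`` signal patterns (up/down regulation
    in one subtype), and group membership is what panel-recovery statistics
    count.  Each redundant block is one informative template plus
    ``block_size - 1`` near-duplicate copies.
    """

    n_features: int = 2000
    class_sizes: tuple[int, ...] = (611, 321, 89)
    class_names: tuple[str, ...] | None = None
    frac_informative: float = 0.10
    n_informative_groups: int = 6
    n_redundant_blocks: int = 5
    block_size: int = 5
    n_constant: int = 10
    effect_size: float = 3.0
    noise_sd: float = 0.3
    responder_frac: float = 0.8
    group_factor_sd: float = 0.4
    redundant_jitter_sd: float = 0.05
    bg_support_range: tuple[float, float] = (0.05, 0.95)
    bg_floor_logmean: float = -4.0
    bg_floor_logsd: float = 0.5
    planted_rules: tuple[PlantedRule, ...] = ()
    planted_rule_prob: float = 0.95
    seed: int = 0

    # ---- derived layout -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        return tuple(f"class{i + 1}" for i in range(len(self.class_sizes)))

    @property
    def n_informative(self) -> int:
        return int(round(self.frac_informative * self.n_features))

    @property
    def n_redundant(self) -> int:
        return self.n_redundant_blocks * (self.block_size - 1)

    @property
    def planted_feature_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for rule in self.planted_rules:
            for f in rule.features:
                if f not in seen:
                    seen.append(f)
        return tuple(seen)

    @property
    def n_noise(self) -> int:
        return (
            self.n_features
            - self.n_informative
            - self.n_redundant
            - self.n_constant
            - len(self.planted_feature_names)
        )

    def validate(self) -> None:
        if not self.class_sizes:
            raise ValueError("class_sizes must be non-empty")
        if any(c < 1 for c in self.class_sizes):
            raise ValueError("every class size must be >= 1")
        if not 0.0 < self.frac_informative < 1.0:
            raise ValueError("frac_informative must be in (0, 1)")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.n_redundant_blocks > self.n_informative:
            raise ValueError("need at least one informative template per redundant block")
        if self.class_names is not None and len(self.class_names) != len(self.class_sizes):
            raise ValueError("class_names length must match class_sizes")
        if self.n_noise < 0:
            raise ValueError(
                "n_features too small for the requested archetypes "
                f"(informative={self.n_informative}, redundant={self.n_redundant}, "
                f"constant={self.n_constant}, planted={len(self.planted_feature_names)})"
            )
        if not 0.0 < self.planted_rule_prob <= 1.0:
            raise ValueError("planted_rule_prob must be in (0, 1]")
        if not 0.0 < self.responder_frac <= 1.0:
            raise ValueError("responder_frac must be in (0, 1]")
        lo, hi = self.bg_support_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("bg_support_range must satisfy 0 < low < high < 1")
        names = self.names
        for rule in self.planted_rules:
            if rule.subtype not in names:
                raise ValueError(f"planted rule targets unknown subtype {rule.subtype!r}")


@dataclass
class LabeledExpression:
    """A samples x features expression matrix with subtype labels.

    ``provenance`` tags each feature with its generative archetype
    (informative / redundant / constant / noise); ``groups`` holds the signal
    group of informative and redundant features (-1 otherwise).  Both are
    ``None`` for cohorts read from plain files without a sidecar.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    labels: np.ndarray
    provenance: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("row count must equal label count")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal sample_ids length")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("column count must equal feature_ids length")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def feature_index(self, feature_ids: list[str]) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        return np.array([pos[f] for f in feature_ids], dtype=int)

    def subset_features(self, feature_ids: list[str]) -> "LabeledExpression":
        idx = self.feature_index(feature_ids)
        return LabeledExpression(
            values=self.values[:, idx].copy(),
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            labels=self.labels.copy(),
            provenance=None if self.provenance is None else self.provenance[idx].copy(),
            groups=None if self.groups is None else self.groups[idx].copy(),
        )

    def take_samples(self, idx: np.ndarray) -> "LabeledExpression":
        idx = np.asarray(idx, dtype=int)
        return LabeledExpression(
            values=self.values[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            labels=self.labels[idx].copy(),
            provenance=None if self.provenance is None else self.provenance.copy(),
            groups=None if self.groups is None else self.groups.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledExpression):
            return NotImplemented
        same_meta = (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and list(self.labels) == list(other.labels)
        )
        if not same_meta or not np.array_equal(self.values, other.values):
            return False
        for a, b in ((self.provenance, other.provenance), (self.groups, other.groups)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


def _group_pattern(group: int, n_classes: int) -> tuple[int, float]:
    """Map a group index to (target class, log-scale direction)."""
    target = group % n_classes
    direction = 1.0 if (group // n_classes) % 2 == 0 else -1.0
    return target, direction


def generate_cohort(config: SimConfig) -> LabeledExpression:
    """Draw a labeled cohort from ``config``; the seed fully determines it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.names
    n = sum(config.class_sizes)
    p = config.n_features
    labels = np.concatenate(
        [np.repeat(name, size) for name, size in zip(names, config.class_sizes)]
    ).astype(object)
    class_index = np.concatenate(
        [np.repeat(i, size) for i, size in enumerate(config.class_sizes)]
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    values = np.empty((n, p))
    feature_ids: list[str] = []
    provenance = np.empty(p, dtype=object)
    groups = np.full(p, -1, dtype=int)
    n_classes = len(config.class_sizes)

    col = 0
    # latent factor per signal group: moderate within-group correlation
    group_factor = rng.normal(0.0, 1.0, size=(config.n_informative_groups, n))
    # informative features (the first n_redundant_blocks serve as templates)
    template_cols: list[int] = []
    for j in range(config.n_informative):
        g = j % config.n_informative_groups
        target, direction = _group_pattern(g, n_classes)
        responds = rng.random(n) < config.responder_frac
        mu = np.where((class_index == target) & responds, direction * config.effect_size, 0.0)
        mu = mu + config.group_factor_sd * group_factor[g]
        values[:, col] = np.exp(rng.normal(mu, config.noise_sd))
        feature_ids.append(f"inf_g{g}_{j:04d}")
        provenance[col] = "informative"
        groups[col] = g
        if j < config.n_redundant_blocks:
            template_cols.append(col)
        col += 1

    # redundant blocks: jittered copies of their template
    for b, tcol in enumerate(template_cols):
        for k in range(config.block_size - 1):
            jitter = np.exp(rng.normal(0.0, config.redundant_jitter_sd, size=n))
            values[:, col] = values[:, tcol] * jitter
            feature_ids.append(f"red_b{b}_{k:03d}")
            provenance[col] = "redundant"
            groups[col] = groups[tcol]
            col += 1

    # constant (all-zero) features
    for j in range(config.n_constant):
        values[:, col] = 0.0
        feature_ids.append(f"const_{j:04d}")
        provenance[col] = "constant"
        col += 1

    # zero-inflated background: detected in a random fraction of samples,
    # at a low detection floor elsewhere
    lo, hi = config.bg_support_range
    for j in range(config.n_noise):
        frac = rng.uniform(lo, hi)
        detected = rng.random(n) < frac
        expressed = np.exp(rng.normal(0.0, config.noise_sd, size=n))
        floor = np.exp(rng.normal(config.bg_floor_logmean, config.bg_floor_logsd, size=n))
        values[:, col] = np.where(detected, expressed, floor)
        feature_ids.append(f"noise_{j:04d}")
        provenance[col] = "noise"
        col += 1

    # planted-rule features: uniform background, forced level per subtype
    planted = config.planted_feature_names
    planted_cols = {}
    for name in planted:
        values[:, col] = rng.uniform(0.0, 1.0, size=n)
        feature_ids.append(name)
        provenance[col] = "informative"
        planted_cols[name] = col
        col += 1
    for r, rule in enumerate(config.planted_rules):
        in_class = labels == rule.subtype
        for fname, level in zip(rule.features, rule.levels):
            c = planted_cols[fname]
            groups[c] = config.n_informative_groups + r
            lo, hi = _LEVEL_BANDS[level]
            forced = rng.random(size=n) < config.planted_rule_prob
            draw = rng.uniform(lo, hi, size=n)
            mask = in_class & forced
            values[mask, c] = draw[mask]

    assert col == p
    return LabeledExpression(values, sample_ids, feature_ids, labels, provenance, groups)


# ---------------------------------------------------------------------------
# I/O


def _sidecar_paths(path: str) -> tuple[str, str]:
    return path + ".labels.tsv", path + ".features.tsv"


def write_cohort(cohort: LabeledExpression, path: str, orientation: str = "samples") -> None:
    """Write a cohort as TSV.

    ``orientation='samples'`` puts samples in rows with an embedded ``subtype``
    column; ``orientation='features'`` puts features in rows and writes a
    sidecar ``<path>.labels.tsv`` with (sample_id, subtype).  Feature
    provenance, when present, goes to ``<path>.features.tsv`` so the cohort
    round-trips losslessly.
    """
    if cohort.n_samples == 0:
        raise IOError("refusing to write a cohort with zero samples")
    if orientation not in ("samples", "features"):
        raise ValueError("orientation must be 'samples' or 'features'")
    label_path, feat_path = _sidecar_paths(path)
    if orientation == "samples":
        df = pd.DataFrame(cohort.values, index=cohort.sample_ids, columns=cohort.feature_ids)
        df.insert(len(df.columns), "subtype", list(cohort.labels))
        df.to_csv(path, sep="\t", index_label="sample_id")
    else:
        df = pd.DataFrame(cohort.values.T, index=cohort.feature_ids, columns=cohort.sample_ids)
        df.to_csv(path, sep="\t", index_label="feature_id")
        pd.DataFrame({"sample_id": cohort.sample_ids, "subtype": list(cohort.labels)}).to_csv(
            label_path, sep="\t", index=False
        )
    if cohort.provenance is not None:
        pd.DataFrame(
            {
                "feature_id": cohort.feature_ids,
                "archetype": list(cohort.provenance),
                "group": cohort.groups if cohort.groups is not None else -1,
            }
        ).to_csv(feat_path, sep="\t", index=False)


def read_cohort(path: str, orientation: str = "samples") -> LabeledExpression:
    """Read a cohort written by :func:`write_cohort` (inverse operation)."""
    import os

    from .preprocess import read_expression_table

    label_path, feat_path = _sidecar_paths(path)
    label_source = "embedded" if orientation == "samples" else label_path
    cohort = read_expression_table(path, orientation=orientation, label_source=label_source)
    if os.path.exists(feat_path):
        meta = pd.read_csv(feat_path, sep="\t")
        order = cohort.feature_index(list(meta["feature_id"]))
        provenance = np.empty(cohort.n_features, dtype=object)
        groups = np.full(cohort.n_features, -1, dtype=int)
        provenance[order] = meta["archetype"].to_numpy(dtype=object)
        groups[order] = meta["group"].to_numpy(dtype=int)
        cohort.provenance = provenance
        cohort.groups = groups
    return cohort


# ---------------------------------------------------------------------------
# Ready-made scenarios


def recovery_scenario(
    n_features: int = 2000,
    class_sizes: tuple[int, ...] = (180, 94, 26),
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A three-subtype cohort with planted signal for end-to-end recovery runs.

    Class sizes keep the strongly imbalanced proportions of the emulated renal
    cohort (minority prevalence < 10%, so class rules for it are suppressed at
    the default minimum support).  Two co-occurrence patterns are planted: a
    two-feature high/high rule for the majority subtype and a single-feature
    rule for the second subtype.
    """
    names = ("KIRC", "KIRP", "KICH")[: len(class_sizes)]
    rules = (
        PlantedRule(("planted_kirc_a", "planted_kirc_b"), ("high", "high"), names[0]),
    )
    if len(names) > 1:
        rules = rules + (PlantedRule(("planted_kirp_a",), ("high",), names[1]),)
    cfg = SimConfig(
        n_features=n_features,
        class_sizes=class_sizes,
        class_names=names,
        planted_rules=rules,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
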