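"""Clinical feature schema and mixed-type encoding.

The cohorts handled by this package carry 28 clinical and therapy features
describing a primary breast tumor: patient and tumor characteristics (age,
diameter, histology, receptor status, grading, lymph-node involvement, ...)
and the adjuvant therapy actually performed (chemotherapy, hormone therapy,
trastuzumab, schemes, timings).  Features are mixed continuous / ordinal /
nominal / binary and may be missing ("NA").

The schema records, for every feature, its kind, the admissible category
values (ordered, for ordinals), the marginal distribution targeted by the
synthetic generator, and the missingness rate.  A single encoding --
standardized continuous/ordinal columns, one-hot nominal indicators scaled by
1/sqrt(k) -- is shared by the nearest-neighbour imputation and every
downstream classifier, so no feature family dominates Euclidean geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "NA"

CONTINUOUS = "continuous"
ORDINAL = "ordinal"
NOMINAL = "nominal"
BINARY = "binary"


@dataclass(frozen=True)
class Feature:
    """One clinical feature: its type, categories and generator targets.

    ``categories`` is empty for continuous features and ordered for ordinal
    ones.  ``marginal`` holds the generator's target category probabilities
    (categoricals) aligned with ``categories``; ``quantile_anchors`` holds
    five values interpreted as the 0/25/50/75/100th percentiles of a
    piecewise-linear quantile function (continuous features).
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    missing_rate: float = 0.0
    marginal: tuple[float, ...] = ()
    quantile_anchors: tuple[float, ...] = ()
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, ORDINAL, NOMINAL, BINARY):
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate for {self.name!r} not in [0, 1]")
        if self.kind == CONTINUOUS:
            if self.categories:
                raise ValueError(f"continuous feature {self.name!r} has categories")
        else:
            if len(self.categories) < 2:
                raise ValueError(f"categorical feature {self.name!r} needs >= 2 categories")
        if self.marginal and len(self.marginal) != len(self.categories):
            raise ValueError(f"marginal length mismatch for {self.name!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of the 28 cohort features."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def with_missing_scale(self, scale: float) -> "FeatureSchema":
        """Return a copy with every missingness rate multiplied by ``scale``."""
        if scale < 0:
            raise ValueError("missingness scale must be non-negative")
        feats = []
        for f in self.features:
            rate = min(1.0, f.missing_rate * scale)
            feats.append(
                Feature(
                    f.name, f.kind, f.categories, rate, f.marginal,
                    f.quantile_anchors, f.integer_valued,
                )
            )
        return FeatureSchema(tuple(feats))


def _cat(name, kind, cats_counts, n_missing, n_total=529):
    cats = tuple(c for c, _ in cats_counts)
    total = sum(c for _, c in cats_counts)
    marginal = tuple(c / total for _, c in cats_counts)
    return Feature(name, kind, cats, n_missing / n_total, marginal)


def _cont(name, anchors, n_missing, n_total=529, integer_valued=False):
    return Feature(
        name, CONTINUOUS, (), n_missing / n_total,
        quantile_anchors=tuple(float(a) for a in anchors),
        integer_valued=integer_valued,
    )


def default_schema() -> FeatureSchema:
    """The 28-feature clinical schema with its reference marginal targets.

    Category probabilities are observed frequencies among non-missing records
    of the reference cohort table; continuous anchors reproduce its printed
    median and quartiles, with plausible clinical extremes for the tails.
    Therapy indicator features (CT, HT, trastuzumab) and both scheme fields
    are generated *conditionally* on the therapy combination, so their
    marginal targets here are the ones implied by that joint draw; see
    :func:`ide_ensemble.cohort.generate_cohort`.
    """
    f = [
        _cont("age", (25, 45, 51, 60, 90), 0),
        _cat("prev. tumor", BINARY, [("No", 513), ("Yes", 16)], 0),
        _cat("diameter", ORDINAL,
             [("T1a", 19), ("T1b", 45), ("T1c", 227), ("T2", 187), ("T3", 14), ("T4", 21)], 16),
        _cat("multiple", BINARY, [("No", 419), ("Yes", 108)], 2),
        _cat("hist. type", NOMINAL, [("ductal", 468), ("lobular", 43), ("other", 18)], 0),
        _cat("surgery", BINARY, [("quadrantectomy", 339), ("mastectomy", 190)], 0),
        _cont("ER", (0, 0, 44, 80, 100), 5),
        _cont("PgR", (0, 0, 21, 70, 100), 6),
        _cont("Ki67", (0, 10, 22, 40, 98), 11),
        _cat("grading", ORDINAL, [("G1", 48), ("G2", 231), ("G3", 229)], 21),
        _cat("HER2", BINARY, [("Neg", 336), ("Pos", 85)], 108),
        _cat("HER2/neu+", ORDINAL, [("0", 162), ("1", 99), ("2", 61), ("3", 71)], 136),
        _cat("in situ comp.", NOMINAL,
             [("absent", 405), ("present, not typed", 69), ("G1", 22), ("G2", 15), ("G3", 16)], 2),
        _cat("LVI", NOMINAL,
             [("absent", 339), ("focal", 101), ("extensive", 29), ("present, not typed", 60)], 0),
        _cat("status l.", ORDINAL, [("N0", 271), ("N1", 187), ("N2", 41), ("N3", 21)], 9),
        _cat("sentinel l.", NOMINAL, [("Not done", 438), ("Negative", 52), ("Positive", 33)], 6),
        _cat("dissection l.", BINARY, [("Yes", 466), ("No", 52)], 11),
        _cont("eradicated l.", (0, 14, 19, 24, 45), 18, integer_valued=True),
        _cont("metastatic l.", (0, 0, 0, 2, 30), 29, integer_valued=True),
        # Therapy block: marginals implied by the "ther. comb" joint draw.
        _cat("CT", BINARY, [("No", 161), ("Yes", 366)], 2),
        _cat("HT", BINARY, [("No", 144), ("Yes", 383)], 2),
        _cat("trastuzumab", BINARY, [("No", 464), ("Yes", 63)], 1),
        _cat("CT scheme", NOMINAL,
             [("absent", 161), ("Anthra. + taxane", 80), ("Anthra.", 120), ("taxane", 3),
              ("CMF", 97), ("other", 66)], 5),
        _cat("HT scheme", NOMINAL,
             [("absent", 144), ("Tamoxifen", 30), ("LHRHa", 4), ("Tamoxifen + LHRHa", 89),
              ("AI", 171), ("Tamoxifen + AI", 29), ("LHRHa + AI", 14), ("other", 46)], 6),
        _cat("ther. comb", NOMINAL,
             [("No", 4), ("HT", 157), ("CT", 116), ("CT + HT", 187),
              ("CT + trastuzumab", 24), ("CT + HT + trastuzumab", 39)], 2),
        _cont("CT months", (0, 0, 3, 5, 12), 14),
        _cont("diag.–surg. months", (0, 0, 0, 0, 8), 0),
        _cont("surg.–ther. months", (0, 1, 1, 1, 12), 18),
    ]
    schema = FeatureSchema(tuple(f))
    assert len(schema) == 28
    return schema


# ---------------------------------------------------------------------------
# Mixed-type encoding


@dataclass
class EncodingStats:
    """Standardization statistics fitted on complete cases."""

    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)


def _ordinal_rank(feature: Feature, values: pd.Series) -> pd.Series:
    lookup = {c: i for i, c in enumerate(feature.categories)}
    return values.map(lookup).astype(float)


def fit_encoding_stats(df: pd.DataFrame, schema: FeatureSchema) -> EncodingStats:
    """Fit means/stds for continuous and (ranked) ordinal features.

    Rows with missing entries contribute only their non-missing values.
    """
    stats = EncodingStats()
    for feat in schema:
        if feat.kind not in (CONTINUOUS, ORDINAL):
            continue
        col = df[feat.name]
        if feat.kind == CONTINUOUS:
            vals = pd.to_numeric(col[col.astype(str) != MISSING], errors="coerce")
        else:
            vals = _ordinal_rank(feat, col[col.astype(str) != MISSING].astype(str))
        mean = float(vals.mean()) if len(vals) else 0.0
        std = float(vals.std(ddof=0)) if len(vals) else 1.0
        stats.means[feat.name] = mean
        stats.stds[feat.name] = std if std > 0 else 1.0
    return stats


def encode_features(
    df: pd.DataFrame,
    schema: FeatureSchema,
    stats: EncodingStats | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray, EncodingStats]:
    """Encode a feature table into a numeric matrix.

    Continuous and ordinal (integer-ranked) features are standardized;
    nominal/binary features are one-hot encoded with each indicator scaled by
    1/sqrt(k) for a k-category feature, so every feature contributes unit-order
    variance to Euclidean distances.

    Returns ``(X, column_names, column_feature_index, stats)`` where missing
    entries are NaN in every encoded column of their feature, and
    ``column_feature_index[j]`` maps encoded column j back to its schema
    feature position.
    """
    if stats is None:
        stats = fit_encoding_stats(df, schema)
    cols: list[np.ndarray] = []
    names: list[str] = []
    owner: list[int] = []
    for fi, feat in enumerate(schema):
        raw = df[feat.name]
        is_missing = raw.astype(str) == MISSING
        if feat.kind == CONTINUOUS:
            vals = pd.to_numeric(raw.mask(is_missing), errors="coerce").to_numpy(float)
            z = (vals - stats.means[feat.name]) / stats.stds[feat.name]
            cols.append(z)
            names.append(feat.name)
            owner.append(fi)
        elif feat.kind == ORDINAL:
            ranks = _ordinal_rank(feat, raw.astype(str).mask(is_missing)).to_numpy(float)
            z = (ranks - stats.means[feat.name]) / stats.stds[feat.name]
            cols.append(z)
            names.append(feat.name)
            owner.append(fi)
        else:  # nominal / binary -> scaled one-hot
            k = len(feat.categories)
            scale = 1.0 / np.sqrt(k)
            vals = raw.astype(str)
            for cat in feat.categories:
                ind = np.where(is_missing, np.nan, (vals == cat).astype(float) * scale)
                cols.append(ind.astype(float))
                names.append(f"{feat.name}={cat}")
                owner.append(fi)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, np.asarray(owner), stats
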