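"""Synthetic clinical cohorts and nearest-complete-case imputation.

The generator draws patient tables whose 28 features follow the reference
marginal distributions of the schema, plants a logistic risk signal on a known
feature subset (Ki67 up, ER down, grading up, metastatic lymph nodes up),
draws invasive-disease-event (IDE) times from a piecewise-exponential model
whose two segment rates are calibrated so the realized 5- and 10-year event
fractions hit the configured prevalences, and finally flips the outcome of a
chosen fraction of patients whose encoded features are typical of their own
class -- the planted "confounding patients", whose clinical profile ends up
resembling the class opposite to their label and whose identities are kept
in a ground-truth side channel.

Missing values use the ``"NA"`` marker.  Imputation replaces *all* missing
entries of a patient with the corresponding values of the complete-data
patient at minimum Euclidean distance in the mixed encoding, computed over
the query's non-missing features only; equidistant donors resolve to the
smallest patient id.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    CONTINUOUS,
    MISSING,
    FeatureSchema,
    default_schema,
    encode_features,
    fit_encoding_stats,
)
from .utils import ConfigurationError, ImputationError

EVENT_TYPES = ("none", "recurrence", "contralateral", "second_tumor")
#: probability of each event type, given that an event occurs
EVENT_TYPE_MIX = {"recurrence": 0.76, "contralateral": 0.155, "second_tumor": 0.085}

#: features carrying the planted risk signal, with their log-odds weights
#: per standard deviation (higher proliferation, grade and nodal burden and
#: lower estrogen-receptor expression raise event risk)
SIGNAL_WEIGHTS = {"Ki67": 1.0, "ER": -1.0, "grading": 0.7, "metastatic l.": 0.8}

META_COLUMNS = ["patient_id", "followup_months", "event_type", "event_months"]


@dataclass
class GroundTruth:
    """Side channel recording what the generator planted."""

    signal_features: list[str]
    signal_weights: dict[str, float]
    flipped_ids: list[int]
    risk_score: dict[int, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["risk_score"] = {int(k): v for k, v in d.get("risk_score", {}).items()}
        return cls(**d)


@dataclass
class CohortTable:
    """A patient table: id, 28 features, follow-up and event record."""

    data: pd.DataFrame
    schema: FeatureSchema
    ground_truth: GroundTruth | None = None

    def __len__(self) -> int:
        return len(self.data)

    def feature_frame(self) -> pd.DataFrame:
        return self.data[self.schema.names]

    def validate(self) -> None:
        df = self.data
        if df["patient_id"].duplicated().any():
            raise ValueError("patient_id values are not unique")
        if (df["followup_months"] < 0).any():
            raise ValueError("negative follow-up")
        bad = ~df["event_type"].isin(EVENT_TYPES)
        if bad.any():
            raise ValueError(f"unknown event types: {df.loc[bad, 'event_type'].unique()}")
        has_event = df["event_type"] != "none"
        if df.loc[has_event, "event_months"].isna().any():
            raise ValueError("event without event_months")
        if df.loc[~has_event, "event_months"].notna().any():
            raise ValueError("event_months present without an event")
        em = df.loc[has_event, "event_months"].astype(float)
        if (em <= 0).any():
            raise ValueError("event_months must be positive")
        if (em > df.loc[has_event, "followup_months"].astype(float)).any():
            raise ValueError("event_months exceeds followup_months")
        for feat in self.schema:
            col = df[feat.name]
            nonmiss = col[col.astype(str) != MISSING]
            if feat.kind == CONTINUOUS:
                vals = pd.to_numeric(nonmiss, errors="raise").astype(float)
                if (vals < 0).any():
                    raise ValueError(f"negative value in {feat.name}")
                if feat.name in ("ER", "PgR", "Ki67") and (vals > 100).any():
                    raise ValueError(f"{feat.name} exceeds 100")
            else:
                bad = ~nonmiss.astype(str).isin(feat.categories)
                if bad.any():
                    raise ValueError(
                        f"invalid category in {feat.name}: {nonmiss[bad].unique()[:5]}"
                    )

    def has_missing(self) -> bool:
        ff = self.feature_frame().astype(str)
        return bool((ff == MISSING).to_numpy().any())

    # -- CSV round trip ------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, na_rep=MISSING)

    @classmethod
    def from_csv(cls, path: str | Path, schema: FeatureSchema | None = None) -> "CohortTable":
        schema = schema or default_schema()
        df = pd.read_csv(path, keep_default_na=False, dtype=str)
        df["patient_id"] = df["patient_id"].astype(int)
        df["followup_months"] = df["followup_months"].astype(int)
        df["event_months"] = pd.array(
            [int(float(v)) if v != MISSING else None for v in df["event_months"]],
            dtype="Int64",
        )
        for feat in schema:
            if feat.kind == CONTINUOUS:
                df[feat.name] = [
                    float(v) if v != MISSING else MISSING for v in df[feat.name]
                ]
        return cls(df, schema)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults reproduce the reference cohort's scale: 529 patients with 26.8%
    showing an IDE within 60 months and 39.1% within 120 months.
    """

    n_patients: int = 529
    seed: int = 0
    prevalence_5y: float = 142 / 529
    prevalence_10y: float = 207 / 529
    signal_strength: float = 2.0
    noise_rate: float = 0.10
    missingness_scale: float = 1.0
    schema: FeatureSchema | None = None

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not 0.0 < self.prevalence_5y < 1.0:
            raise ConfigurationError("prevalence_5y must lie in (0, 1)")
        if not 0.0 < self.prevalence_10y < 1.0:
            raise ConfigurationError("prevalence_10y must lie in (0, 1)")
        if self.prevalence_10y < self.prevalence_5y:
            raise ConfigurationError("prevalence_10y cannot be below prevalence_5y")
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be non-negative")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ConfigurationError("noise_rate must lie in [0, 0.5)")
        if self.missingness_scale < 0:
            raise ConfigurationError("missingness_scale must be non-negative")

    @classmethod
    def from_mapping(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown generator fields: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# generation internals


def _draw_continuous(feat, n, rng, u=None):
    """Piecewise-linear inverse-CDF draw through the five quantile anchors."""
    probs = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    if u is None:
        u = rng.uniform(size=n)
    vals = np.interp(u, probs, np.asarray(feat.quantile_anchors, dtype=float))
    if feat.integer_valued:
        vals = np.round(vals)
    else:
        vals = np.round(vals, 1)
    return vals


def _components(comb: str) -> set[str]:
    return set() if comb == "No" else set(comb.split(" + "))


def _draw_features(schema: FeatureSchema, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the 28 features; therapy indicators and schemes follow the
    therapy-combination draw for logical consistency (CT=No implies
    CT scheme=absent, trastuzumab only with CT, CT months=0 without CT)."""
    out: dict[str, np.ndarray | list] = {}
    comb_feat = schema["ther. comb"]
    comb = rng.choice(comb_feat.categories, size=n, p=np.asarray(comb_feat.marginal))
    has = {name: np.array([name in _components(c) for c in comb]) for name in ("CT", "HT", "trastuzumab")}

    derived = {"ther. comb", "CT", "HT", "trastuzumab", "CT scheme", "HT scheme", "CT months"}
    for feat in schema:
        if feat.name in derived:
            continue
        if feat.kind == CONTINUOUS:
            out[feat.name] = _draw_continuous(feat, n, rng)
        else:
            out[feat.name] = rng.choice(feat.categories, size=n, p=np.asarray(feat.marginal))

    out["ther. comb"] = comb
    for name in ("CT", "HT", "trastuzumab"):
        out[name] = np.where(has[name], "Yes", "No")
    for scheme_name, flag in (("CT scheme", has["CT"]), ("HT scheme", has["HT"])):
        feat = schema[scheme_name]
        cats = list(feat.categories)
        marg = np.asarray(feat.marginal, dtype=float)
        active = [c for c in cats if c != "absent"]
        p = np.array([marg[cats.index(c)] for c in active])
        p = p / p.sum()
        drawn = rng.choice(active, size=n, p=p)
        out[scheme_name] = np.where(flag, drawn, "absent")
    ctm = schema["CT months"]
    # conditional draw for treated patients = upper tail of the marginal
    # quantile function above the untreated mass
    p_absent = float(np.mean(~has["CT"])) if n else 0.0
    u = rng.uniform(size=n) * (1 - p_absent) + p_absent
    months = _draw_continuous(ctm, n, rng, u=u)
    out["CT months"] = np.where(has["CT"], months, 0.0)
    return pd.DataFrame({f.name: out[f.name] for f in schema})


def _risk_score(df: pd.DataFrame, schema: FeatureSchema, signal_strength: float) -> np.ndarray:
    """Linear predictor of event risk over the planted signal features."""
    eta = np.zeros(len(df))
    for name, w in SIGNAL_WEIGHTS.items():
        feat = schema[name]
        if feat.kind == CONTINUOUS:
            vals = pd.to_numeric(df[name]).to_numpy(float)
        else:  # ordinal rank
            lookup = {c: i for i, c in enumerate(feat.categories)}
            vals = df[name].map(lookup).to_numpy(float)
        sd = vals.std()
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        eta += w * z
    return signal_strength * eta


def _calibrate_rate(target_count, event_fn, lo=1e-8, hi=10.0, iters=60):
    """Bisect a hazard-scale so the realized recorded-event count hits target."""
    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        if event_fn(mid) < target_count:
            lo = mid
        else:
            hi = mid
    return hi


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a synthetic cohort per the configured study conditions.

    Event times follow a two-segment exponential model (rates on [0, 60] and
    (60, 120+] months) whose scales are calibrated by bisection against the
    configured 5-/10-year prevalences, with patient-level proportional-hazard
    factors ``exp(eta_i)`` from the planted logistic risk score.  Censoring
    times are uniform on [24, 300] months.  Label flips planting confounding
    patients are applied after calibration, nearest-to-opposite-centroid
    first, and recorded in the ground-truth side channel.
    """
    config.validate()
    schema = config.schema or default_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    df = _draw_features(schema, n, rng)
    eta = _risk_score(df, schema, config.signal_strength)
    hazard_mult = np.exp(eta - eta.mean())

    censor = np.round(rng.uniform(24, 300, size=n)).astype(int)
    u1 = rng.uniform(size=n)
    u2 = rng.uniform(size=n)

    # Segment 1: events in (0, 60].
    target5 = int(round(config.prevalence_5y * n))
    t1 = lambda r: -np.log1p(-u1) / (r * hazard_mult)
    rec5 = lambda r: int(np.sum(t1(r) <= np.minimum(60, censor)))
    r1 = _calibrate_rate(target5, rec5, lo=1e-9, hi=1.0)
    T1 = t1(r1)
    ev1 = T1 <= np.minimum(60, censor)

    # Segment 2: events in (60, 120]; only patients latent-event-free at 60.
    target10 = int(round(config.prevalence_10y * n))
    open2 = T1 > 60
    t2 = lambda r: 60 + (-np.log1p(-u2)) / (r * hazard_mult)
    rec10 = lambda r: int(ev1.sum() + np.sum(open2 & (t2(r) <= np.minimum(120, censor))))
    r2 = _calibrate_rate(target10, rec10, lo=1e-9, hi=1.0)
    T2 = t2(r2)
    ev2 = open2 & (T2 <= np.minimum(120, censor))
    # beyond 120 months the segment-2 hazard keeps running
    ev_late = open2 & ~ev2 & (T2 <= censor)

    event_time = np.full(n, np.nan)
    event_time[ev1] = T1[ev1]
    event_time[ev2 | ev_late] = T2[ev2 | ev_late]
    has_event = ~np.isnan(event_time)

    event_months = np.where(has_event, np.maximum(1, np.ceil(event_time)), 0).astype(int)
    followup = np.where(has_event, np.maximum(event_months, censor), censor).astype(int)

    mix = np.array([EVENT_TYPE_MIX[t] for t in EVENT_TYPES[1:]])
    types = rng.choice(EVENT_TYPES[1:], size=n, p=mix / mix.sum())
    event_type = np.where(has_event, types, "none")

    patient_id = np.arange(1, n + 1)

    # ---- plant confounding patients by label flips ------------------------
    # Flip the outcome of records with strong but not extreme own-class
    # character, measured by the projection of the encoded features onto the
    # axis joining the class centroids.  After the flip their clinical
    # profile is that of a clearly typical member of the class opposite to
    # their label -- the defining trait of a confounding patient.  The most
    # extreme 5% tail is skipped (such outliers resemble nobody and distort
    # class-variance estimates rather than confound).  Event-side flips are
    # restricted to events within 60 months so a flip confounds both
    # horizons, and flips come from both classes proportionally so the
    # confounder model can train on a two-class set.
    flipped: list[int] = []
    if config.noise_rate > 0 and has_event.any() and (~has_event).any():
        X, _, _, _ = encode_features(df, schema)
        y = has_event & (event_months <= 120)
        mu1 = X[y].mean(axis=0)
        mu0 = X[~y].mean(axis=0)
        proj = X @ (mu1 - mu0)
        n_flip = int(round(config.noise_rate * n))
        n_flip_pos = int(round(n_flip * y.mean()))
        picks: list[int] = []
        for cls, quota in ((True, n_flip_pos), (False, n_flip - n_flip_pos)):
            members = np.flatnonzero(y == cls)
            if cls:
                members = members[event_months[members] <= 60]
            typicality = proj[members] if cls else -proj[members]
            order_c = members[np.argsort(-typicality, kind="stable")]
            skip = int(np.ceil(0.05 * len(order_c)))
            # draw at random from the typical half (tail excluded) rather than
            # taking a contiguous block: a dense flipped cluster would be
            # learnable as a pattern of its own, scattered flips are not
            pool = order_c[skip:max(skip + quota, int(0.55 * len(order_c)))]
            take = min(quota, len(pool))
            picks.extend(rng.choice(pool, size=take, replace=False))
        for i in picks:
            if y[i]:  # event patient becomes a long-followup control
                event_type[i] = "none"
                event_months[i] = 0
                has_event[i] = False
                followup[i] = max(followup[i], 170)
            else:  # control becomes an early-event patient
                t = int(rng.integers(6, 61))
                event_type[i] = rng.choice(EVENT_TYPES[1:], p=mix / mix.sum())
                event_months[i] = t
                has_event[i] = True
                followup[i] = max(followup[i], t)
            flipped.append(int(patient_id[i]))

    # ---- missingness ------------------------------------------------------
    eff_schema = schema.with_missing_scale(config.missingness_scale)
    df = df.astype(object)
    for feat in eff_schema:
        if feat.missing_rate > 0:
            mask = rng.uniform(size=n) < feat.missing_rate
            df.loc[mask, feat.name] = MISSING

    data = df.copy()
    data.insert(0, "patient_id", patient_id)
    data["followup_months"] = followup
    data["event_type"] = event_type
    data["event_months"] = pd.array(
        [int(m) if h else None for m, h in zip(event_months, has_event)], dtype="Int64"
    )

    gt = GroundTruth(
        signal_features=list(SIGNAL_WEIGHTS),
        signal_weights=dict(SIGNAL_WEIGHTS),
        flipped_ids=sorted(flipped),
        risk_score={int(pid): float(e) for pid, e in zip(patient_id, eta)},
    )
    table = CohortTable(data, schema, gt)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# imputation


def impute_missing(cohort: CohortTable, schema: FeatureSchema | None = None) -> CohortTable:
    """Replace every incomplete patient's missing values from its nearest
    complete-data patient.

    Distance is Euclidean in the mixed encoding (continuous/ordinal columns
    standardized over complete cases, nominal one-hot scaled by 1/sqrt(k)),
    restricted to the query patient's non-missing features.  All missing
    entries come from the single nearest complete donor; ties resolve to the
    smallest patient id.  Complete patients are returned unchanged.
    """
    schema = schema or cohort.schema
    if len(cohort) == 0:
        raise ImputationError("empty cohort")
    df = cohort.data.reset_index(drop=True)
    feats = df[schema.names]
    miss_mask = feats.astype(str).eq(MISSING)
    incomplete = miss_mask.any(axis=1)
    if not incomplete.any():
        out = CohortTable(df.copy(), schema, cohort.ground_truth)
        return out
    complete_idx = np.flatnonzero(~incomplete.to_numpy())
    if complete_idx.size == 0:
        raise ImputationError("no patient with complete data exists")

    stats = fit_encoding_stats(feats.iloc[complete_idx], schema)
    X, _, owner, _ = encode_features(feats, schema, stats=stats)

    # donors ordered by ascending patient id so argmin ties pick the smallest
    donor_order = complete_idx[np.argsort(df.loc[complete_idx, "patient_id"].to_numpy())]
    Xd = X[donor_order]

    out = df.copy()
    for i in np.flatnonzero(incomplete.to_numpy()):
        row = X[i]
        usable = ~np.isnan(row)
        diff = Xd[:, usable] - row[usable]
        dist = np.einsum("ij,ij->i", diff, diff)
        donor = donor_order[int(np.argmin(dist))]
        for col in schema.names:
            if miss_mask.at[i, col]:
                out.at[i, col] = df.at[donor, col]
    table = CohortTable(out, schema, cohort.ground_truth)
    return table
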