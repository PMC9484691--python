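"""All-relevant feature selection against permuted shadow copies.

Every schema feature gets a shadow twin: its encoded column block with rows
independently permuted, which preserves the marginal distribution but breaks
any association with the label.  A random forest is fit on real + shadow
blocks; a feature scores a *hit* in an iteration when its importance (summed
over its encoded columns) exceeds the maximum shadow importance.  Hits
accumulate over iterations and a two-sided binomial test at level alpha
confirms features hitting significantly more than half the time and rejects
those hitting significantly less; rejected features leave the model matrix.
The loop stops when every feature is decided or after ``max_iter``
iterations; undecided (tentative) features count as not confirmed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier


def shadow_feature_select(
    X: np.ndarray,
    y: np.ndarray,
    owner: np.ndarray,
    n_features: int,
    seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 100,
    alpha: float = 0.05,
) -> np.ndarray:
    """Return a boolean confirmation mask over the ``n_features`` schema features.

    ``owner`` maps each encoded column of ``X`` to its schema feature index.
    """
    rng = np.random.default_rng(seed)
    owner = np.asarray(owner)
    n = len(y)
    active = np.ones(n_features, dtype=bool)      # still in the model matrix
    undecided = np.ones(n_features, dtype=bool)
    confirmed = np.zeros(n_features, dtype=bool)
    hits = np.zeros(n_features, dtype=int)
    tested = np.zeros(n_features, dtype=int)

    for _ in range(max_iter):
        feat_idx = np.flatnonzero(active)
        col_mask = np.isin(owner, feat_idx)
        cols = np.flatnonzero(col_mask)
        Xr = X[:, cols]
        # shadow: permute each feature's column block jointly
        Xs = np.empty_like(Xr)
        sub_owner = owner[cols]
        for f in feat_idx:
            block = np.flatnonzero(sub_owner == f)
            Xs[:, block] = Xr[np.asarray(rng.permutation(n))][:, block]
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(np.hstack([Xr, Xs]), y)
        imp = rf.feature_importances_
        real_imp = np.zeros(n_features)
        shadow_imp = np.zeros(n_features)
        for bi, f in enumerate(sub_owner):
            real_imp[f] += imp[bi]
            shadow_imp[f] += imp[len(cols) + bi]
        shadow_max = shadow_imp[feat_idx].max()
        hit = real_imp > shadow_max
        hits[undecided & hit] += 1
        tested[undecided] += 1

        for f in np.flatnonzero(undecided):
            t, h = tested[f], hits[f]
            if binom.sf(h - 1, t, 0.5) < alpha / 2:
                confirmed[f] = True
                undecided[f] = False
            elif binom.cdf(h, t, 0.5) < alpha / 2:
                undecided[f] = False
                active[f] = False   # rejected: drop from the model matrix
        if not undecided.any() or not active.any():
            break
    return confirmed
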