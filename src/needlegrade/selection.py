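"""Feature sensitivity screening and successive-projections selection.

Screening: a one-way ANOVA of each feature against damage level. A
feature is *sensitive* when its F statistic exceeds the upper critical
value at tail probability 0.01, and *highly sensitive* at tail 1e-10
(the criticals for 4 groups of 210 trees round to the conventional 3.34
and 13.57 under the (4, 840) degrees-of-freedom convention used when the
thresholds were published; the F statistic itself uses the classical
k-1 / n-k degrees of freedom).

Selection: the successive projections algorithm (SPA), a forward selector
for low-collinearity subsets. Starting from each candidate feature it
grows a chain by repeatedly appending the feature whose projection onto
the orthogonal complement of the chain's span has the largest residual
norm; every chain prefix of length k in [k_min, k_max] is scored by the
validation misclassification of a nearest-class-centroid model on
standardised features, and the lowest-error subset wins (ties break to
the smaller subset, then to lexicographic feature order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vegindex import FeatureTable

__all__ = [
    "FeatureSensitivity",
    "SelectionResult",
    "anova_f",
    "f_critical",
    "screen_features",
    "spa_select",
]


@dataclass(frozen=True)
class FeatureSensitivity:
    feature: str
    F: float
    p: float
    sensitive: bool
    highly_sensitive: bool

    def __post_init__(self) -> None:
        if self.highly_sensitive and not self.sensitive:
            raise ValueError("highly_sensitive implies sensitive")


def f_critical(alpha_tail: float, df1: int, df2: int) -> float:
    """Upper-tail critical value of the F(df1, df2) distribution."""
    if not (0.0 < alpha_tail < 1.0):
        raise ValueError("alpha_tail must lie in (0, 1)")
    if df1 <= 0 or df2 <= 0 or not np.isfinite(df1) or not np.isfinite(df2):
        raise ValueError("degrees of freedom must be positive and finite")
    return float(stats.f.isf(alpha_tail, df1, df2))


def anova_f(values: Sequence[float], levels: Sequence[int],
            feature: str = "feature",
            alpha: float = 0.01, alpha_high: float = 1e-10,
            ) -> FeatureSensitivity:
    """One-way ANOVA F of a feature across damage-level groups.

    Degenerate separation (zero within-group variance, distinct means)
    yields an infinite F, flagged sensitive.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(levels)
    groups = [x[g == lvl] for lvl in np.unique(g)]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(grp) < 2 for grp in groups):
        raise ValueError("every group needs >= 2 observations")
    n = x.size
    grand = x.mean()
    ss_between = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(F, df1, df2))
    sensitive = F > f_critical(alpha, df1, df2)
    highly = F > f_critical(alpha_high, df1, df2)
    return FeatureSensitivity(feature=feature, F=float(F), p=p,
                              sensitive=sensitive,
                              highly_sensitive=highly and sensitive)


def screen_features(table: FeatureTable, levels: Sequence[int],
                    alpha: float = 0.01,
                    alpha_high: float = 1e-10) -> pd.DataFrame:
    """ANOVA screening of every feature; returns the sensitivity report."""
    rows = [anova_f(table.values[c].to_numpy(), levels, feature=c,
                    alpha=alpha, alpha_high=alpha_high)
            for c in table.values.columns]
    return pd.DataFrame(
        {"feature": [r.feature for r in rows],
         "F": [r.F for r in rows],
         "p": [r.p for r in rows],
         "sensitive": [r.sensitive for r in rows],
         "highly_sensitive": [r.highly_sensitive for r in rows]}
    ).set_index("feature")


@dataclass
class SelectionResult:
    """SPA outcome: explored chains, per-subset validation errors, winner."""

    chains: dict[str, list[str]]  # start feature -> chain (selection order)
    #: residual norm at each chain step; entry 0 is the forced start
    #: column's norm, entries 1.. are the successive argmax residual norms,
    #: which contract monotonically (orthogonal projection can only shrink)
    norm_traces: dict[str, list[float]]
    errors: dict[tuple[str, int], float]  # (start, k) -> validation error
    selected: list[str] = field(default_factory=list)  # in selection order
    validation_error: float = float("nan")

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected subset contains duplicates")


class _NearestCentroid:
    """Nearest class centroid on standardised features (subset scorer)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NearestCentroid":
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mu_) / self.sd_
        self.classes_ = np.unique(y)
        self.centroids_ = np.vstack([Z[y == c].mean(axis=0)
                                     for c in self.classes_])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu_) / self.sd_
        d = ((Z[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d, axis=1)]


def _stratified_holdout(y: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Boolean mask marking a stratified validation subset."""
    mask = np.zeros(y.size, dtype=bool)
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        n_val = max(1, int(round(fraction * idx.size)))
        mask[rng.permutation(idx)[:n_val]] = True
    return mask


def spa_select(X: FeatureTable | np.ndarray, y: Sequence[int],
               k_min: int, k_max: int,
               val_fraction: float = 0.25, seed: int = 0,
               feature_names: Sequence[str] | None = None,
               ) -> SelectionResult:
    """Successive projections selection of a low-collinearity subset.

    ``X`` should be normalised features (rows = trees). Every feature is
    tried as a chain start; chains are grown by maximal residual norm
    after orthogonal projection onto the span of the already-selected
    columns; subsets of size k_min..k_max are scored by nearest-centroid
    validation error.
    """
    if isinstance(X, FeatureTable):
        feature_names = X.feature_names
        mat = X.values.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(mat.shape[1])]
    y = np.asarray(y)
    n, m = mat.shape
    if not (1 <= k_min <= k_max <= m):
        raise ValueError(f"need 1 <= k_min <= k_max <= {m}")
    if np.isnan(mat).any():
        raise ValueError("X must have no missing values")

    rng = np.random.default_rng(seed)
    val_mask = _stratified_holdout(y, val_fraction, rng)
    X_cal, y_cal = mat[~val_mask], y[~val_mask]
    X_val, y_val = mat[val_mask], y[val_mask]

    # chains are built on centred calibration columns
    C = X_cal - X_cal.mean(axis=0)
    norms0 = np.linalg.norm(C, axis=0)
    tol = 1e-10 * max(norms0.max(), 1.0)

    chains: dict[str, list[str]] = {}
    traces: dict[str, list[float]] = {}
    longest = 0
    for start in range(m):
        if norms0[start] <= tol:
            continue  # constant column cannot start a chain
        chain = [start]
        trace = [float(norms0[start])]
        Q = C[:, [start]] / norms0[start]
        residual = C - Q @ (Q.T @ C)
        while len(chain) < k_max:
            rnorm = np.linalg.norm(residual, axis=0)
            rnorm[chain] = -1.0
            nxt = int(np.argmax(rnorm))
            if rnorm[nxt] <= tol:
                break  # remaining columns lie in the span: chain exhausted
            chain.append(nxt)
            trace.append(float(rnorm[nxt]))
            qn = residual[:, [nxt]] / rnorm[nxt]
            Q = np.hstack([Q, qn])
            residual = residual - qn @ (qn.T @ residual)
        chains[feature_names[start]] = [feature_names[j] for j in chain]
        traces[feature_names[start]] = trace
        longest = max(longest, len(chain))
    if longest < k_min:
        raise ValueError(
            f"rank-deficient feature matrix: longest projection chain has "
            f"{longest} features, below k_min={k_min}")

    name_to_col = {feature_names[j]: j for j in range(m)}
    errors: dict[tuple[str, int], float] = {}
    best: tuple[float, int, tuple[str, ...], str] | None = None
    for start, chain in chains.items():
        for k in range(k_min, min(k_max, len(chain)) + 1):
            subset = chain[:k]
            cols = [name_to_col[f] for f in subset]
            model = _NearestCentroid().fit(X_cal[:, cols], y_cal)
            err = float(np.mean(model.predict(X_val[:, cols]) != y_val))
            errors[(start, k)] = err
            key = (err, k, tuple(sorted(subset)), start)
            if best is None or key < best:
                best = key
                selected, best_err = subset, err

    return SelectionResult(chains=chains, norm_traces=traces, errors=errors,
                           selected=list(selected), validation_error=best_err)
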