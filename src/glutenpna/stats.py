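"""Statistics layer: correlations, PCA, exponential fits, ANOVA+Tukey.

Operates on attribute tables (one row per image or per sample mean).
Attributes mix units, so PCA standardizes by default.  Exponential
decays y = a·exp(−b·x) + c are fit by bounded least squares with a
log-linear warm start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

ATTRIBUTES = [
    "lacunarity",
    "branching_rate",
    "endpoint_rate",
    "avg_protein_length_um",
    "protein_width_um",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    names: list[str]
    r: np.ndarray          # Pearson r, NaN where undefined
    n: np.ndarray          # pairwise sample counts

    def get(self, a: str, b: str) -> float:
        return float(self.r[self.names.index(a), self.names.index(b)])


@dataclass(frozen=True)
class PCAResult:
    names: list[str]
    loadings: np.ndarray            # (n_attributes, n_components)
    scores: np.ndarray              # (n_samples, n_components)
    explained_fractions: np.ndarray


@dataclass(frozen=True)
class ExpFitResult:
    a: float
    b: float
    c: float
    r_squared: float | None         # None when SStot == 0


@dataclass(frozen=True)
class GroupComparison:
    attribute: str
    group_names: list[str]
    f_statistic: float
    p_value: float
    tukey_p: dict[tuple[str, str], float]
    means: dict[str, float]
    sems: dict[str, float]
    counts: dict[str, int]


class FitError(RuntimeError):
    """Non-convergence; carries the best parameters found so far."""

    def __init__(self, message: str, best: ExpFitResult):
        super().__init__(message)
        self.best = best


def pearson_matrix(
    table: pd.DataFrame,
    attributes: list[str] | None = None,
    by: str | None = None,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over samples.

    With ``by`` given, rows are first averaged within each group (the
    per-sample-mean convention); otherwise rows are the samples.
    Missing values are dropped per pair; a constant attribute yields NaN
    for its pairs rather than a spurious 0.
    """
    attributes = attributes or [a for a in ATTRIBUTES if a in table.columns]
    data = table.groupby(by)[attributes].mean() if by else table[attributes]
    if len(data) < 3:
        raise ValueError("need at least 3 samples")
    k = len(attributes)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            pair = data[[attributes[i], attributes[j]]].dropna()
            n[i, j] = len(pair)
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if i == j:
                r[i, j] = 1.0
            elif len(pair) >= 3 and x.std() > 0 and y.std() > 0:
                r[i, j] = sps.pearsonr(x, y).statistic
    return CorrelationMatrix(list(attributes), r, n)


def pca(
    table: pd.DataFrame,
    attributes: list[str] | None = None,
    standardize: bool = True,
) -> PCAResult:
    """Principal component analysis of an attribute table.

    Standardization (the default) analyses the correlation structure,
    appropriate for attributes on different scales.  Sign convention:
    each loading vector's largest-magnitude entry is positive.
    Explained fractions cover all components and sum to 1.
    """
    attributes = attributes or [a for a in ATTRIBUTES if a in table.columns]
    if len(attributes) < 2:
        raise ValueError("need at least 2 attributes")
    X = table[attributes].dropna().to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [a for a, s in zip(attributes, sd) if s == 0]
            raise ValueError(f"constant attributes cannot be standardized: {bad}")
        X = X / sd
    # SVD of the centered (standardized) data = eigendecomposition of cov
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt.T
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    variances = s**2
    total = variances.sum()
    fractions = variances / total if total > 0 else variances
    scores = u * s
    return PCAResult(list(attributes), loadings, scores, fractions)


def fit_exponential_decay(
    x: np.ndarray, y: np.ndarray, max_iterations: int = 10000
) -> ExpFitResult:
    """Least-squares fit of y = a·exp(−b·x) + c with b >= 0.

    Initialization: c0 = min(y), a0 = max(y) − min(y), b0 from a
    log-linear regression of y − c0 on x.  Constant y returns a ≈ 0 and
    an undefined (None) R².  Non-convergence raises :class:`FitError`
    carrying the best parameters found.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        return ExpFitResult(a=0.0, b=0.0, c=float(y[0]), r_squared=None)

    c0 = float(y.min())
    a0 = float(y.max() - y.min())
    shifted = y - c0
    pos = shifted > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        slope = np.polyfit(x[pos], np.log(shifted[pos]), 1)[0]
        b0 = max(-slope, 1e-6)
    else:
        b0 = 1.0

    def model(x_, a, b, c):
        return a * np.exp(-b * x_) + c

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=[a0, b0, c0],
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=max_iterations,
        )
    except RuntimeError as exc:
        best = ExpFitResult(a0, b0, c0, r_squared=None)
        raise FitError(str(exc), best) from exc
    ssres = float(np.sum((y - model(x, *popt)) ** 2))
    return ExpFitResult(*map(float, popt), r_squared=1.0 - ssres / sstot)


def anova_tukey(
    groups: dict[str, np.ndarray], attribute: str = ""
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons and mean ± SEM.

    Tukey p-values come from the studentized-range distribution;
    two-sided, no significance gate applied.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    f_stat, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    tukey_p = {
        (names[i], names[j]): float(hsd.pvalue[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return GroupComparison(
        attribute=attribute,
        group_names=names,
        f_statistic=float(f_stat),
        p_value=float(p),
        tukey_p=tukey_p,
        means={g: float(a.mean()) for g, a in zip(names, arrays)},
        sems={g: float(sps.sem(a)) for g, a in zip(names, arrays)},
        counts={g: int(len(a)) for g, a in zip(names, arrays)},
    )
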