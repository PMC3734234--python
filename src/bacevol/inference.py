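"""Statistical layer: Spearman screening and principal-component-regression
(PCR) partitioning of independent feature contributions to the
evolutionary rate.

PCR sidesteps the collinearity of genomic features by regressing ER on all
principal components of the z-scored feature matrix. Because sample PCs
are exactly orthogonal, their R-squared values add, and each component's
R-squared can be attributed back to features by its squared (unit-norm)
eigenvector loadings:

    contribution_j = sum_k  v_jk^2 * R2_k

which sums over features to the full OLS R-squared of ER on all features.
Proportions are contributions normalized to sum 1. All components are
retained — the point is orthogonal decomposition, not dimension reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: eigenvalues below this are treated as null directions (no R2 assigned)
_EIG_TOL = 1e-10


@dataclass(frozen=True)
class CorrelationScreen:
    """Per-feature Spearman correlation with ER (pairwise-complete)."""

    table: pd.DataFrame  # index: feature; columns: rho, p_value, n_used,
    #                      is_max_abs, not_significant

    @property
    def max_abs_feature(self) -> str | None:
        hits = self.table.index[self.table["is_max_abs"]]
        return hits[0] if len(hits) else None


@dataclass(frozen=True)
class PCRResult:
    contributions: pd.Series   # per-feature independent R2_j >= 0
    proportions: pd.Series     # contributions / total, sums to 1
    total_r2: float
    component_r2: np.ndarray   # per-PC R2_k
    loadings: pd.DataFrame     # features x PCs, unit-norm eigenvectors
    eigenvalues: np.ndarray
    n_used: int


def spearman(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value from the large-sample t approximation on n-2 degrees of
    freedom. Requires >= 3 paired non-missing observations; zero variance
    in either rank vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    res = stats.spearmanr(x[mask], y[mask], alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def correlation_screen(features: pd.DataFrame, er_column: str = "ER",
                       alpha: float = 0.05) -> CorrelationScreen:
    """Spearman rho of each feature against ER, pairwise-complete.

    Features with no usable observations (or no variance) get blank rows;
    exactly one feature carries ``is_max_abs``.
    """
    if er_column not in features:
        raise ValueError(f"feature table lacks an {er_column!r} column")
    er = features[er_column].to_numpy(dtype=float)
    rows = {}
    for col in features.columns:
        if col == er_column:
            continue
        x = features[col].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(er)
        n = int(mask.sum())
        if n < 3 or np.unique(x[mask]).size < 2 or np.unique(er[mask]).size < 2:
            rows[col] = (np.nan, np.nan, n)
            continue
        rho, p = spearman(x, er)
        rows[col] = (rho, p, n)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["rho", "p_value", "n_used"])
    table["is_max_abs"] = False
    abs_rho = table["rho"].abs()
    if abs_rho.notna().any():
        table.loc[abs_rho.idxmax(), "is_max_abs"] = True
    table["not_significant"] = table["p_value"] > alpha
    return CorrelationScreen(table)


def _complete_cases(features: pd.DataFrame, er: pd.Series
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    # drop features entirely missing for this species, then complete cases
    X = features.dropna(axis=1, how="all")
    joined = X.assign(__er=er)
    joined = joined.dropna(axis=0, how="any")
    return joined.drop(columns="__er"), joined["__er"].to_numpy(dtype=float)


def pcr_contributions(features: pd.DataFrame, er: pd.Series) -> PCRResult:
    """Independent per-feature contributions to ER variance via PCR.

    ``features`` holds predictor columns only (no ER). Complete cases are
    used; constant columns are excluded. Raises when fewer complete cases
    than features + 2 remain.
    """
    X_df, y = _complete_cases(features, er)
    X_df = X_df.loc[:, X_df.std(ddof=0) > 0]
    names = list(X_df.columns)
    if len(names) < 1:
        raise ValueError("no features with variance")
    n = len(X_df)
    if n < len(names) + 2:
        raise ValueError(f"only {n} complete cases for {len(names)} features")
    X = X_df.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = (Z.T @ Z) / n
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scores = Z @ eigvec
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise ValueError("ER has zero variance on complete cases")
    comp_r2 = np.zeros(len(names))
    for k in range(len(names)):
        if eigval[k] <= _EIG_TOL:
            continue
        s = scores[:, k]
        comp_r2[k] = float(s @ yc) ** 2 / (float(s @ s) * ss_y)
    contrib = (eigvec ** 2) @ comp_r2
    total = float(comp_r2.sum())
    proportions = contrib / contrib.sum() if contrib.sum() > 0 else contrib
    return PCRResult(
        contributions=pd.Series(contrib, index=names, name="R2"),
        proportions=pd.Series(proportions, index=names, name="proportion"),
        total_r2=total,
        component_r2=comp_r2,
        loadings=pd.DataFrame(eigvec, index=names,
                              columns=[f"PC{k+1}" for k in range(len(names))]),
        eigenvalues=eigval,
        n_used=n,
    )


def pc_feature_plot(features: pd.DataFrame, er: pd.Series,
                    er_label: str = "ER") -> pd.DataFrame:
    """PC1/PC2 coordinates of every variable (ER included) for a biplot.

    Coordinates are correlation-scaled loadings (eigenvector entries times
    the square root of the eigenvalue), so each variable's squared
    coordinates over all PCs sum to 1 and PC1/PC2 coordinates lie in the
    unit disc.
    """
    X_df, y = _complete_cases(features, er)
    X_df = X_df.loc[:, X_df.std(ddof=0) > 0]
    joint = X_df.assign(**{er_label: y})
    X = joint.to_numpy(dtype=float)
    if len(X) < joint.shape[1] + 2:
        raise ValueError("too few complete cases for a PC plot")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = (Z.T @ Z) / len(Z)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))
    # deterministic orientation: largest |loading| per axis positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
    return pd.DataFrame(loadings[:, :2], index=joint.columns,
                        columns=["PC1", "PC2"])
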