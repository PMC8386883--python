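"""Per-omic preprocessing: cell-composition adjustment, z-score
standardization, and nonparametric association-based covariate filtering.

The filter keeps a molecular feature only if it associates with at least one
filter-role clinical variable at a stringent within-variable FDR (default
1e-5): rank-sum for binary variables, Kruskal-Wallis for >2 categories, and a
Spearman rank-correlation test for continuous variables. Cell-count and
demographic variables are kept out of the filter set via roles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_enrich import bh_fdr
from .datatypes import ClinicalTable, OmicsMatrix

logger = logging.getLogger("omsubtype")


@dataclass
class FilterReport:
    """Per (feature, variable) test results plus the per-feature verdict."""

    tests: pd.DataFrame  # columns: feature, variable, test, p, p_adj
    kept: pd.Series  # feature -> bool
    threshold: float

    def kept_features(self) -> list:
        return [f for f, keep in self.kept.items() if keep]

    def justification(self, feature: str) -> list:
        t = self.tests
        rows = t[(t["feature"] == feature) & (t["p_adj"] < self.threshold)]
        return rows["variable"].tolist()


def regress_out_cell_counts(X: OmicsMatrix, clinical: ClinicalTable) -> OmicsMatrix:
    """Replace each feature by its OLS residual on all cell-count covariates.

    The design includes an intercept and all cell-count variables jointly;
    zero-variance covariates are dropped with a warning and a rank-deficient
    design falls back to the least-norm solution (lstsq).
    """
    if X.adjusted:
        raise ValueError(f"{X.omic_name}: already adjusted")
    cells = clinical.cell_count_matrix(X.subject_ids)
    if cells.isna().any().any():
        raise ValueError("cell-count covariates contain missing values")
    C = cells.to_numpy(dtype=float)
    keep = []
    for j, name in enumerate(cells.columns):
        if np.ptp(C[:, j]) == 0:
            logger.warning("zero-variance cell covariate %r dropped", name)
        else:
            keep.append(j)
    design = np.column_stack([np.ones(X.n_subjects), C[:, keep]])
    if keep and np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("rank-deficient cell-count design; least-norm solution used")
    coef, *_ = np.linalg.lstsq(design, X.values, rcond=None)
    residuals = X.values - design @ coef
    return X.with_values(residuals, adjusted=True)


def zscore_standardize(X: OmicsMatrix) -> OmicsMatrix:
    """Center and scale each feature to mean 0, sample sd 1 (ddof=1)."""
    if not X.adjusted:
        raise ValueError(f"{X.omic_name}: adjust cell counts before standardizing")
    values = X.values - X.values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        names = [X.feature_ids[j] for j in np.flatnonzero(zero)[:5]]
        logger.warning(
            "%d zero-variance feature(s) set to 0 (e.g. %s); the covariate "
            "filter will decide their fate", int(zero.sum()), names,
        )
    sd[zero] = 1.0
    return X.with_values(values / sd, standardized=True)


def covariate_filter(
    X: OmicsMatrix,
    clinical: ClinicalTable,
    threshold: float = 1e-5,
):
    """Keep features associated with >=1 filter variable at adjusted p < threshold.

    Benjamini-Hochberg adjustment is applied within each clinical variable
    across features. Returns the filtered matrix and the full FilterReport;
    missing clinical values are dropped pairwise per test.
    """
    if not X.standardized:
        raise ValueError(f"{X.omic_name}: standardize before filtering")
    filter_vars = clinical.by_role("filter")
    if not filter_vars:
        raise ValueError("clinical table declares no filter-role variables")

    rows = []
    any_kept = np.zeros(X.n_features, dtype=bool)
    for var in filter_vars:
        vals = var.values.reindex(X.subject_ids)
        observed = vals.notna().to_numpy()
        v = vals[observed]
        sub = X.values[observed]
        p = _association_pvalues(sub, v, var.kind, var.name)
        if p is None:
            continue
        p_adj = bh_fdr(p)
        any_kept |= p_adj < threshold
        rows.append(
            pd.DataFrame(
                {
                    "feature": X.feature_ids,
                    "variable": var.name,
                    "test": _test_name(var.kind, v),
                    "p": p,
                    "p_adj": p_adj,
                }
            )
        )
    if not rows:
        raise ValueError("no usable filter variables after missing-data removal")
    tests = pd.concat(rows, ignore_index=True)
    kept = pd.Series(any_kept, index=X.feature_ids)
    report = FilterReport(tests=tests, kept=kept, threshold=threshold)
    kept_ids = report.kept_features()
    if not kept_ids:
        raise ValueError(
            f"{X.omic_name}: covariate filter removed every feature at "
            f"threshold {threshold}; relax the threshold"
        )
    return X.select_features(kept_ids, filtered=True), report


def _test_name(kind: str, v: pd.Series) -> str:
    if kind == "continuous":
        return "spearman"
    groups = v.dropna().unique()
    return "ranksum" if len(groups) <= 2 else "kruskal"


def _association_pvalues(sub, v, kind, name):
    """Per-feature p-values for one clinical variable; None when untestable."""
    n = sub.shape[0]
    if kind == "continuous":
        if n < 3 or v.nunique() < 2:
            logger.warning("filter variable %r has <2 distinct values; skipped", name)
            return None
        return _spearman_pvalues(sub, v.to_numpy(dtype=float))
    codes = pd.Categorical(v).codes
    levels = np.unique(codes)
    if len(levels) < 2:
        logger.warning("filter variable %r has <2 observed groups; skipped", name)
        return None
    groups = [sub[codes == g] for g in levels]
    if len(levels) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], axis=0,
                                 alternative="two-sided")
        return np.asarray(res.pvalue, dtype=float)
    p = np.empty(sub.shape[1])
    for j in range(sub.shape[1]):
        p[j] = stats.kruskal(*[g[:, j] for g in groups]).pvalue
    return p


def _spearman_pvalues(sub: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized Spearman correlation test of every column against v."""
    n = sub.shape[0]
    r_sub = stats.rankdata(sub, axis=0)
    r_v = stats.rankdata(v)
    r_sub = r_sub - r_sub.mean(axis=0)
    r_v = r_v - r_v.mean()
    denom = np.sqrt((r_sub**2).sum(axis=0) * (r_v**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, r_sub.T @ r_v / denom, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    # t-approximation, as scipy.stats.spearmanr uses for n > 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |rho| == 1
    return p
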