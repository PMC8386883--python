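"""Clinical association testing of subtype labels and annotation enrichment
of selected features.

Test choice follows the kind of each variable: ANOVA for continuous, the
chi-square test for categorical variables whose expected cell counts all
exceed 5, and Fisher's exact test otherwise (exact for 2x2, seeded
Monte-Carlo permutation for larger tables). P-values are Benjamini-Hochberg
adjusted across the tested variables; enrichment uses a one-sided
hypergeometric test adjusted within each annotation hierarchy level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationDB, ClinicalTable, OUTLIER_LABEL

logger = logging.getLogger("omsubtype")

MC_DRAWS = 10_000  # permutation draws for r x c exact tests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite p-value")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def expected_counts(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()


def choose_test(kind: str, contingency: np.ndarray | None = None) -> str:
    """anova for continuous; chi2 when all expected counts exceed 5, else
    fisher."""
    if kind == "continuous":
        return "anova"
    if contingency is None:
        raise ValueError("categorical variables need a contingency table")
    return "chi2" if (expected_counts(contingency) > 5).all() else "fisher"


def _fisher_rxc_mc(table: np.ndarray, seed: int, draws: int = MC_DRAWS) -> float:
    """Seeded Monte-Carlo permutation p-value (chi-square statistic) for
    r x c tables too sparse for the asymptotic test."""
    table = np.asarray(table, dtype=int)
    r, c = table.shape
    row = np.repeat(np.arange(r), table.sum(axis=1))
    col = np.repeat(np.arange(c), table.sum(axis=0))
    expected = expected_counts(table)

    def chi2_stat(obs):
        return ((obs - expected) ** 2 / expected).sum(axis=(-2, -1))

    observed = chi2_stat(table.astype(float))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(col, (draws, 1)), axis=1)
    flat = row[None, :] * c + perms + np.arange(draws)[:, None] * (r * c)
    counts = np.bincount(flat.ravel(), minlength=draws * r * c)
    tables = counts.reshape(draws, r, c).astype(float)
    exceed = int((chi2_stat(tables) >= observed - 1e-12).sum())
    return (1 + exceed) / (draws + 1)


def _test_one_variable(var, groups: pd.Series, seed: int):
    """(test name, p-value, per-group summary) for one clinical variable."""
    df = pd.DataFrame({"value": var.values.reindex(groups.index),
                       "group": groups}).dropna()
    if df.empty or df["value"].nunique() < 2 or df["group"].nunique() < 2:
        return None
    by_group = [g["value"] for _, g in df.groupby("group", observed=True)]
    if var.kind == "continuous":
        vals = [pd.to_numeric(g) for g in by_group]
        p = stats.f_oneway(*vals).pvalue
        summary = "; ".join(
            f"{name}: {v.mean():.3g} ({v.std(ddof=1):.3g})"
            for name, v in zip(sorted(df["group"].unique()), vals)
        )
        return "anova", float(p), summary
    tab = pd.crosstab(df["value"], df["group"])
    contingency = tab.to_numpy()
    test = choose_test(var.kind, contingency)
    if test == "chi2":
        p = stats.chi2_contingency(contingency, correction=False).pvalue
    elif contingency.shape == (2, 2):
        p = stats.fisher_exact(contingency).pvalue
    else:
        p = _fisher_rxc_mc(contingency, seed=seed)
    pct = 100.0 * tab / tab.sum(axis=0)
    summary = "; ".join(
        f"{g}: " + "/".join(f"{lvl}={pct.loc[lvl, g]:.1f}%" for lvl in tab.index)
        for g in tab.columns
    )
    return test, float(p), summary


def test_clinical_associations(
    labels,
    clinical: ClinicalTable,
    subject_ids=None,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Association of test-role clinical variables with group labels.

    ``labels`` is aligned to ``subject_ids`` (defaults to the clinical
    table's subjects); outlier labels are excluded. Missing clinical values
    are dropped pairwise per test, constant variables are skipped, and
    Benjamini-Hochberg adjustment runs across all tested variables. Rows are
    sorted by adjusted p-value.
    """
    subject_ids = list(subject_ids) if subject_ids is not None else list(
        clinical.subject_ids)
    labels = np.asarray(labels)
    groups = pd.Series(labels, index=subject_ids)
    groups = groups[~groups.isin([OUTLIER_LABEL, str(OUTLIER_LABEL)])]
    counts = groups.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >=2 groups with >=2 members each")
    rows = []
    for var in clinical.by_role("test"):
        result = _test_one_variable(var, groups, seed=seed)
        if result is None:
            logger.warning("clinical variable %r constant or unobserved; skipped",
                           var.name)
            continue
        test, p, summary = result
        rows.append({"variable": var.name, "test": test, "p": p,
                     "summary": summary})
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(p_adj=[], significant=[])
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values(["p_adj", "p", "variable"],
                             kind="stable").reset_index(drop=True)


def fisher_enrichment(
    selected,
    background,
    db: AnnotationDB,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher enrichment of selected features.

    Category members are intersected with the background universe; the
    2x2 table is (selected vs not) x (in category vs not) and the p-value is
    the hypergeometric upper tail. BH adjustment is applied within each
    hierarchy level; categories with no background members are skipped.
    """
    selected, background = set(selected), set(background)
    if not selected <= background:
        raise ValueError("selected features must be a subset of the background")
    N, n_sel = len(background), len(selected)
    rows = []
    for name, members in db.categories.items():
        in_bg = members & background
        if not in_bg:
            logger.warning("category %r has no background members; skipped", name)
            continue
        a = len(selected & in_bg)
        K = len(in_bg)
        p = float(stats.hypergeom.sf(a - 1, N, K, n_sel))
        b = n_sel - a
        c = K - a
        d = N - n_sel - c
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan)
        rows.append(
            {
                "category": name,
                "level": db.levels[name],
                "selected_in_category": a,
                "selected": n_sel,
                "background_in_category": K,
                "background": N,
                "odds_ratio": odds,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(p_adj=[], significant=[])
    table["p_adj"] = np.nan
    for level in table["level"].unique():
        at_level = table["level"] == level
        table.loc[at_level, "p_adj"] = bh_fdr(table.loc[at_level, "p"].to_numpy())
    table["significant"] = table["p_adj"] < fdr_threshold
    return table.sort_values(["p_adj", "p", "category"],
                             kind="stable").reset_index(drop=True)
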