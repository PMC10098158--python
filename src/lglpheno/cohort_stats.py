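"""Nonparametric statistical layer for cohort comparisons.

Implements the Scheirer-Ray-Hare rank factorial test and Dunn's rank
post hoc from their defining formulas (the contributions of this
module), and dispatches the standard designs (Mann-Whitney, Wilcoxon,
Kruskal-Wallis, Friedman, Spearman, chi-square, Shapiro-Wilk) to scipy.

Scheirer-Ray-Hare: all N observations are ranked together (mid-ranks
for ties); two-way ANOVA sums of squares are computed on the ranks;
each term's statistic is H = SS_term / (N(N+1)/12), divided by the tie
correction D = 1 - sum(t^3 - t)/(N^3 - N), and referred to a chi-square
distribution with the term's ANOVA degrees of freedom. Note
N(N+1)/12 x D equals SS_total/(N-1) computed on mid-ranks, so this is
the classical "SS_term / MS_total" form with ties handled once.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SRHResult", "scheirer_ray_hare", "dunn_posthoc",
           "rank_tukey_posthoc", "GroupComparison", "compare_groups",
           "pca_summary", "paired_tissue_compare", "tie_correction"]


def tie_correction(values: np.ndarray) -> float:
    """Kruskal-Wallis style tie factor D = 1 - sum(t^3 - t)/(N^3 - N)."""
    values = np.asarray(values)
    n = len(values)
    if n < 2:
        return 1.0
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)


@dataclass
class SRHResult:
    """Scheirer-Ray-Hare statistics for factors A, B and the interaction."""

    H_A: float
    H_B: float
    H_interaction: float
    df_A: int
    df_B: int
    df_interaction: int
    p_A: float
    p_B: float
    p_interaction: float
    tie_correction: float
    ss: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": ["A", "B", "interaction"],
            "H": [self.H_A, self.H_B, self.H_interaction],
            "df": [self.df_A, self.df_B, self.df_interaction],
            "p": [self.p_A, self.p_B, self.p_interaction],
        })


def scheirer_ray_hare(values, factor_a, factor_b) -> SRHResult:
    """Rank-based two-way factorial test (see module docstring).

    A factor with a single level yields NaN for its own term; the
    interaction is skipped (NaN, with a warning) when any factor-level
    cell is empty.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    mask = np.isfinite(y)
    y, a, b = y[mask], a[mask], b[mask]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    ranks = stats.rankdata(y)
    lv_a, ia = np.unique(a, return_inverse=True)
    lv_b, ib = np.unique(b, return_inverse=True)
    ka, kb = len(lv_a), len(lv_b)
    grand = ranks.sum()
    cf = grand ** 2 / n

    def group_ss(idx, k):
        sums = np.bincount(idx, weights=ranks, minlength=k)
        cnts = np.bincount(idx, minlength=k)
        return float((sums ** 2 / cnts).sum() - cf)

    ss_a = group_ss(ia, ka) if ka > 1 else float("nan")
    ss_b = group_ss(ib, kb) if kb > 1 else float("nan")
    cell_idx = ia * kb + ib
    cell_counts = np.bincount(cell_idx, minlength=ka * kb)
    complete = (cell_counts > 0).all()
    ss_total = float((ranks ** 2).sum() - cf)
    d = tie_correction(y)
    ms_total = n * (n + 1) / 12.0

    if ka > 1 and kb > 1 and complete:
        ss_cells = group_ss(cell_idx, ka * kb)
        ss_ab = ss_cells - ss_a - ss_b
    else:
        if ka > 1 and kb > 1 and not complete:
            warnings.warn("empty factor cells: interaction term skipped")
        ss_ab = float("nan")

    def h_and_p(ss, df):
        if not np.isfinite(ss) or df < 1:
            return float("nan"), float("nan")
        h = ss / ms_total / d
        return h, float(stats.chi2.sf(h, df))

    h_a, p_a = h_and_p(ss_a, ka - 1)
    h_b, p_b = h_and_p(ss_b, kb - 1)
    h_ab, p_ab = h_and_p(ss_ab, (ka - 1) * (kb - 1))
    return SRHResult(H_A=h_a, H_B=h_b, H_interaction=h_ab,
                     df_A=ka - 1, df_B=kb - 1,
                     df_interaction=(ka - 1) * (kb - 1),
                     p_A=p_a, p_B=p_b, p_interaction=p_ab,
                     tie_correction=d,
                     ss={"A": ss_a, "B": ss_b, "interaction": ss_ab,
                         "total": ss_total})


def _rank_groups(values, groups):
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    mask = np.isfinite(y)
    y, g = y[mask], g[mask]
    levels, idx = np.unique(g, return_inverse=True)
    sizes = np.bincount(idx)
    if (sizes == 0).any() or len(levels) < 2:
        raise ValueError("need >= 2 non-empty groups")
    ranks = stats.rankdata(y)
    mean_ranks = np.bincount(idx, weights=ranks) / sizes
    return y, levels, sizes, mean_ranks, len(y)


def dunn_posthoc(values, groups, adjust: str = "none") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after an omnibus rank test.

    z_ij = (meanrank_i - meanrank_j) /
           sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j)),
    two-sided normal p, optionally Bonferroni-multiplied (capped at 1).
    Returns a symmetric p matrix with z values in ``.attrs['z']``.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    y, levels, sizes, mean_ranks, n = _rank_groups(values, groups)
    _, counts = np.unique(y, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    k = len(levels)
    m = k * (k - 1) // 2
    pmat = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    zmat = pd.DataFrame(np.zeros((k, k)), index=levels, columns=levels)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
        zmat.iloc[i, j] = z
        zmat.iloc[j, i] = -z
    pmat.attrs["z"] = zmat
    pmat.attrs["adjust"] = adjust
    return pmat


def rank_tukey_posthoc(values, groups) -> pd.DataFrame:
    """Pairwise mean-rank comparisons with Tukey studentized-range p.

    The post-hoc used after the rank factorial test: q_ij =
    |meanrank_i - meanrank_j| / sqrt(var_base/2 (1/n_i + 1/n_j)) with
    the same tie-corrected rank variance as Dunn, referred to the
    studentized range distribution with k groups and infinite df.
    """
    y, levels, sizes, mean_ranks, n = _rank_groups(values, groups)
    _, counts = np.unique(y, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    k = len(levels)
    pmat = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(stats.studentized_range.sf(q, k, np.inf))
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    pmat.attrs["method"] = "rank_tukey"
    return pmat


# ---------------------------------------------------------------------------
# design dispatch
# ---------------------------------------------------------------------------

DESIGNS = ("two_independent", "k_independent", "k_paired", "two_paired",
           "factorial")


@dataclass
class GroupComparison:
    feature: str
    design: str
    test: str
    statistic: float
    p: float
    per_group: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    shapiro_p: dict | None = None
    extra: dict = field(default_factory=dict)


def _per_group_summary(df, feature, group_col) -> pd.DataFrame:
    rows = []
    for g, grp in df.groupby(group_col, sort=True):
        v = grp[feature].dropna()
        rows.append({"group": g, "n": len(v),
                     "median": float(v.median()) if len(v) else float("nan"),
                     "min": float(v.min()) if len(v) else float("nan"),
                     "max": float(v.max()) if len(v) else float("nan")})
    return pd.DataFrame(rows)


def compare_groups(df: pd.DataFrame, feature: str, group_col: str,
                   design: str, *, subject_col: str | None = None,
                   factor_b: str | None = None,
                   posthoc: str = "dunn") -> GroupComparison:
    """Dispatch a feature comparison to the design's nonparametric test.

    Shapiro-Wilk normality p-values are reported per group for
    gatekeeping diagnostics, but the nonparametric branch is always the
    one run. Missing values are excluded listwise per feature.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    data = df.dropna(subset=[feature])
    summary = _per_group_summary(data, feature, group_col)
    shapiro = {}
    for g, grp in data.groupby(group_col):
        v = grp[feature].to_numpy(dtype=float)
        if len(v) >= 3 and np.ptp(v) > 0:
            shapiro[g] = float(stats.shapiro(v).pvalue)
    groups = [grp[feature].to_numpy(dtype=float)
              for _, grp in data.groupby(group_col, sort=True)]
    ph = None

    if design == "two_independent":
        if len(groups) != 2:
            raise ValueError("two_independent needs exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        test, stat, p = "mann_whitney_u", res.statistic, res.pvalue
    elif design == "k_independent":
        if len(groups) < 3:
            raise ValueError("k_independent needs >= 3 groups")
        res = stats.kruskal(*groups)
        test, stat, p = "kruskal_wallis", res.statistic, res.pvalue
        if posthoc == "dunn":
            ph = dunn_posthoc(data[feature], data[group_col], adjust="none")
        elif posthoc == "bonferroni":
            ph = dunn_posthoc(data[feature], data[group_col], adjust="bonferroni")
    elif design == "two_paired":
        if subject_col is None:
            raise ValueError("two_paired needs subject_col")
        wide = data.pivot(index=subject_col, columns=group_col,
                          values=feature).dropna()
        if wide.shape[1] != 2:
            raise ValueError("two_paired needs exactly 2 conditions")
        x, y = wide.iloc[:, 0], wide.iloc[:, 1]
        if np.allclose(x, y):
            test, stat, p = "wilcoxon_signed_rank", 0.0, 1.0
        else:
            res = stats.wilcoxon(x, y, alternative="two-sided")
            test, stat, p = "wilcoxon_signed_rank", res.statistic, res.pvalue
    elif design == "k_paired":
        if subject_col is None:
            raise ValueError("k_paired needs subject_col")
        wide = data.pivot(index=subject_col, columns=group_col,
                          values=feature).dropna()
        res = stats.friedmanchisquare(*[wide[c] for c in wide.columns])
        test, stat, p = "friedman", res.statistic, res.pvalue
    else:  # factorial
        if factor_b is None:
            raise ValueError("factorial design needs factor_b")
        srh = scheirer_ray_hare(data[feature], data[group_col], data[factor_b])
        test, stat, p = "scheirer_ray_hare", srh.H_A, srh.p_A
        if posthoc == "rank_tukey":
            ph = rank_tukey_posthoc(data[feature], data[group_col])
        elif posthoc == "dunn":
            ph = dunn_posthoc(data[feature], data[group_col])
        return GroupComparison(feature=feature, design=design, test=test,
                               statistic=float(stat), p=float(p),
                               per_group=summary, posthoc=ph, shapiro_p=shapiro,
                               extra={"srh": srh})
    return GroupComparison(feature=feature, design=design, test=test,
                           statistic=float(stat), p=float(p),
                           per_group=summary, posthoc=ph, shapiro_p=shapiro)


def spearman(x, y) -> tuple[float, float]:
    res = stats.spearmanr(x, y, nan_policy="omit")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# PCA summary
# ---------------------------------------------------------------------------

def pca_summary(features: pd.DataFrame) -> dict:
    """Correlation-matrix PCA: variance explained and loadings.

    Features are standardised (the eigen-decomposition is of the
    correlation matrix); constant features are dropped with a warning.
    """
    X = features.select_dtypes(include=[np.number]).dropna()
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 complete samples and >= 2 features")
    keep = X.columns[X.std(ddof=0) > 0]
    dropped = [c for c in X.columns if c not in set(keep)]
    if dropped:
        warnings.warn(f"constant features dropped: {dropped}")
    X = X[keep]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant features")
    corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    eigvecs = eigvecs[:, order]
    ratio = eigvals / eigvals.sum()
    loadings = pd.DataFrame(
        eigvecs, index=list(keep),
        columns=[f"PC{i + 1}" for i in range(len(eigvals))])
    return {"explained_variance_ratio": ratio,
            "cumulative_variance_ratio": np.cumsum(ratio),
            "loadings": loadings, "dropped": dropped,
            "n_samples": int(X.shape[0])}


# ---------------------------------------------------------------------------
# paired blood / muscle comparison
# ---------------------------------------------------------------------------

def min_attainable_sign_rank_p(n: int, one_tailed: bool = True) -> float:
    """Smallest exact p of the n-pair sign-rank test (all signs concordant)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = 0.5 ** n
    return p if one_tailed else min(1.0, 2.0 * p)


def paired_tissue_compare(blood: pd.DataFrame, muscle: pd.DataFrame,
                          on: str = "donor_id",
                          alternative: str = "greater") -> pd.DataFrame:
    """Per-feature paired blood-vs-muscle sign-rank tests.

    Donors are matched on ``on``; for each shared numeric feature the
    paired difference (muscle - blood) is tested with the exact
    one-tailed Wilcoxon signed-rank test (default alternative: muscle
    greater). Each row carries the minimum attainable exact p for its
    pair count, making small-n floor effects explicit.
    """
    merged = blood.merge(muscle, on=on, suffixes=("_blood", "_muscle"))
    if merged.empty:
        raise ValueError("no matched donor pairs")
    feats = [c[:-len("_blood")] for c in merged.columns if c.endswith("_blood")
             if pd.api.types.is_numeric_dtype(merged[c])]
    rows = []
    for feat in feats:
        x = merged[f"{feat}_blood"].to_numpy(dtype=float)
        y = merged[f"{feat}_muscle"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = len(x)
        if n == 0:
            continue
        diffs = y - x
        if np.allclose(diffs, 0):
            p = 1.0
            stat = float("nan")
        else:
            res = stats.wilcoxon(y, x, alternative=alternative, method="exact")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"feature": feat, "n_pairs": n,
                     "median_diff": float(np.median(diffs)),
                     "statistic": stat, "p": float(p),
                     "min_attainable_p": min_attainable_sign_rank_p(n),
                     "at_floor": bool(np.isclose(
                         p, min_attainable_sign_rank_p(n)))})
    return pd.DataFrame(rows)
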