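"""Inferential layer: Wilcoxon tests, Spearman correlations of NRI against
climate, and PLS regression of NRI on bioclimatic factors.

The rank tests are exact for small samples without ties and fall back to
the normal approximation with tie/continuity corrections otherwise.  All
tests are two-sided.  No multiple-testing correction is applied by default;
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "spearman",
    "PLSResult",
    "pls_regression",
    "nri_climate_spearman",
    "group_summaries",
    "significance_stars",
    "benjamini_hochberg",
]

_EXACT_N = 25


def wilcoxon_signed_rank(values, mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu0``.

    Exact null distribution for n <= 25 without ties or zeros; normal
    approximation with corrections otherwise.  Returns (W+, p).
    """
    d = np.asarray(values, dtype=float) - mu0
    nz = d[d != 0]
    if nz.size < 3:
        raise ValueError("need >= 3 nonzero deviations from mu0")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    exact = nz.size <= _EXACT_N and not has_ties and nz.size == d.size
    res = sps.wilcoxon(
        d,
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=not exact,
        zero_method="wilcox",
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact for small samples without ties, normal approximation with tie
    correction otherwise.  Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = not has_ties and a.size <= _EXACT_N and b.size <= _EXACT_N
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (ties as average ranks), p from the
    t approximation.  Returns (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PLSResult:
    """PLS (NIPALS) regression summary.

    ``r2y_cumulative[k-1]`` is the fraction of response variance explained
    by the first k components (the headline number); ``r2x_cumulative`` the
    analogous fraction of predictor variance.
    """

    n_components: int
    r2y_per_component: np.ndarray
    r2y_cumulative: np.ndarray
    r2x_cumulative: np.ndarray
    x_weights: pd.DataFrame

    def __post_init__(self) -> None:
        c = np.asarray(self.r2y_cumulative)
        if np.any(np.diff(c) < -1e-9) or np.any(c > 1 + 1e-9):
            raise ValueError("cumulative R2Y must be nondecreasing and <= 1")


def pls_regression(
    X: pd.DataFrame, y, n_components: int = 3
) -> PLSResult:
    """PLS regression of a response on standardized predictors (NIPALS).

    Variance explained in ``y`` is computed from the fitted values of the
    first k components, k = 1..n_components.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float).ravel()
    if X.isna().to_numpy().any() or np.isnan(yv).any():
        raise ValueError("missing values not allowed")
    if len(X) != yv.size:
        raise ValueError("X and y length mismatch")
    if len(X) <= n_components:
        raise ValueError("need more observations than components")
    if np.ptp(yv) == 0:
        raise ValueError("constant response")
    sd = X.std(ddof=1).replace(0.0, 1.0)
    Xs = ((X - X.mean()) / sd).to_numpy()
    yc = yv - yv.mean()
    ss_tot = float(yc @ yc)

    r2y_cum = []
    for k in range(1, n_components + 1):
        fit = PLSRegression(n_components=k, scale=False).fit(Xs, yc)
        resid = yc - fit.predict(Xs).ravel()
        r2y_cum.append(1.0 - float(resid @ resid) / ss_tot)
    full = PLSRegression(n_components=n_components, scale=False).fit(Xs, yc)
    # cumulative predictor variance from scores/loadings of the full fit
    ssx_tot = float((Xs ** 2).sum())
    r2x_cum = []
    expl = 0.0
    for k in range(n_components):
        t = full.x_scores_[:, k]
        p = full.x_loadings_[:, k]
        expl += float((t ** 2).sum() * (p ** 2).sum())
        r2x_cum.append(expl / ssx_tot)
    r2y_cum = np.array(r2y_cum)
    r2y_per = np.diff(np.concatenate([[0.0], r2y_cum]))
    weights = pd.DataFrame(
        full.x_weights_,
        index=X.columns,
        columns=[f"comp{k+1}" for k in range(n_components)],
    )
    return PLSResult(
        n_components=n_components,
        r2y_per_component=r2y_per,
        r2y_cumulative=np.maximum.accumulate(r2y_cum),
        r2x_cumulative=np.array(r2x_cum),
        x_weights=weights,
    )


def significance_stars(p: float) -> str:
    """Tiered flags: * p<.1, ** p<.05, *** p<.01."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p values (optional; no correction is applied by default
    anywhere in the pipeline)."""
    return sps.false_discovery_control(np.asarray(pvals, dtype=float))


def nri_climate_spearman(
    nri: pd.Series,
    climate: pd.DataFrame,
    groups: pd.Series | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman rho and p between NRI and every climate factor, per habitat
    group and pooled ("all").  Plots are aligned on index."""
    rows = []
    common = nri.index.intersection(climate.index)
    nri = nri.loc[common]
    climate = climate.loc[common]
    group_iter: list[tuple[str, pd.Index]] = [("all", common)]
    if groups is not None:
        for g, idx in groups.loc[common].groupby(groups.loc[common]).groups.items():
            group_iter.append((str(g), pd.Index(idx)))
    for gname, idx in group_iter:
        sub_n = nri.loc[idx]
        for col in climate.columns:
            sub_c = climate.loc[idx, col]
            try:
                rho, p = spearman(sub_c.to_numpy(), sub_n.to_numpy())
            except ValueError:
                rho, p = float("nan"), float("nan")
            rows.append(
                {"group": gname, "factor": col, "rho": rho, "p": p}
            )
    out = pd.DataFrame(rows)
    if adjust:
        ok = out["p"].notna()
        out.loc[ok, "p_bh"] = benjamini_hochberg(out.loc[ok, "p"])
    out["stars"] = [
        significance_stars(p) if np.isfinite(p) else "" for p in out["p"]
    ]
    return out


def group_summaries(
    metrics: pd.DataFrame,
    groups: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-habitat summaries of community metrics (e.g. nri, pd, sr).

    Returns (per-group table, pairwise rank-sum table).  The per-group
    table holds n, the median of each metric, and for the ``nri`` column a
    Wilcoxon signed-rank p against zero with significance stars; groups
    with fewer than 3 plots (or degenerate values) get the tests skipped
    and flagged.
    """
    common = metrics.index.intersection(groups.index)
    metrics = metrics.loc[common]
    groups = groups.loc[common]
    if groups.isna().any():
        raise ValueError("every plot must belong to exactly one group")

    grows = []
    for g, idx in groups.groupby(groups).groups.items():
        sub = metrics.loc[idx]
        row: dict = {"group": g, "n": len(sub)}
        for col in metrics.columns:
            row[f"median_{col}"] = float(sub[col].median())
        if "nri" in metrics.columns:
            vals = sub["nri"].dropna().to_numpy()
            try:
                _, p = wilcoxon_signed_rank(vals)
                row["nri_vs_zero_p"] = p
                row["nri_vs_zero_stars"] = significance_stars(p)
                row["tests_skipped"] = False
            except ValueError:
                row["nri_vs_zero_p"] = float("nan")
                row["nri_vs_zero_stars"] = ""
                row["tests_skipped"] = True
        grows.append(row)
    per_group = pd.DataFrame(grows)

    prows = []
    names = sorted(groups.unique(), key=str)
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            a_idx = groups.index[groups == ga]
            b_idx = groups.index[groups == gb]
            for col in metrics.columns:
                a = metrics.loc[a_idx, col].dropna().to_numpy()
                b = metrics.loc[b_idx, col].dropna().to_numpy()
                try:
                    stat, p = wilcoxon_rank_sum(a, b)
                    skipped = False
                except ValueError:
                    stat, p, skipped = float("nan"), float("nan"), True
                prows.append(
                    {
                        "group_a": ga, "group_b": gb, "metric": col,
                        "U": stat, "p": p,
                        "stars": significance_stars(p) if np.isfinite(p) else "",
                        "tests_skipped": skipped,
                    }
                )
    pairwise = pd.DataFrame(prows)
    return per_group, pairwise
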