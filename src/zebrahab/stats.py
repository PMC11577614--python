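"""Group statistics for larva-level behavioural parameters.

The decision path mirrors standard behavioural-phenotyping practice: each
group is tested for normality (Shapiro-Wilk) and the groups for variance
homogeneity (Levene).  If every group passes normality at the chosen
alpha, a one-way ANOVA with Dunnett's many-to-one comparisons against the
control group is used; otherwise a Kruskal-Wallis omnibus test followed by
Dunn's rank-based comparisons (Holm-adjusted by default).  Mortality
counts are compared with Pearson's chi-square test without continuity
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "compare_parameters",
    "dunn_test",
    "mortality_test",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Conventional star annotation: * <0.05, ** <0.01, *** <0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """Outcome of one omnibus-plus-posthoc group comparison."""

    parameter: str
    timepoint: Optional[str]
    test_path: str  # "anova_dunnett" or "kruskal_dunn"
    normality_p: Dict[str, float]
    normality_ok: bool
    levene_p: float
    statistic: float
    pvalue: float
    comparisons: pd.DataFrame  # group, statistic, p_raw, p_adj, stars
    alpha: float = 0.05

    def summary(self) -> str:
        omni = "ANOVA" if self.test_path == "anova_dunnett" else "Kruskal-Wallis"
        post = "Dunnett" if self.test_path == "anova_dunnett" else "Dunn (Holm)"
        lines = [
            f"Comparison of {self.parameter!r}"
            + (f" at {self.timepoint}" if self.timepoint else ""),
            f"  path: {omni} + {post}  (normality "
            f"{'passed' if self.normality_ok else 'failed'}, "
            f"Levene p={self.levene_p:.3g})",
            f"  omnibus: stat={self.statistic:.4g}, p={self.pvalue:.4g} "
            f"{significance_stars(self.pvalue)}",
        ]
        for _, r in self.comparisons.iterrows():
            lines.append(
                f"    vs {r['group']:<14} p_adj={r['p_adj']:.4g} {r['stars']}"
            )
        return "\n".join(lines)


def dunn_test(
    values: Sequence[float],
    groups: Sequence,
    control: Optional[str] = None,
    p_adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's post hoc z tests on mean ranks after Kruskal-Wallis.

    Uses the pooled-rank normal approximation with tie correction
    ``T = sum(t^3 - t) / (12 (N - 1))``.  With ``control`` given, only
    many-to-one comparisons against that group are made (matching
    Dunnett-style usage); otherwise all pairs.  Adjustment is Holm by
    default ("none" disables it).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    n_tot = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term

    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n_g = {g: int((groups == g).sum()) for g in labels}

    if control is not None:
        pairs = [(control, g) for g in labels if g != control]
    else:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]

    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / n_g[a] + 1.0 / n_g[b]))
        z = (mean_rank[b] - mean_rank[a]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group": b, "reference": a, "statistic": z, "p_raw": p})
    out = pd.DataFrame(rows)
    if p_adjust == "none" or out.empty:
        out["p_adj"] = out.get("p_raw", [])
    else:
        out["p_adj"] = _holm(out["p_raw"].to_numpy())
    out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone in the raw p-values)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_groups(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    control: str = "control",
    alpha: float = 0.05,
    parameter: str = "value",
    timepoint: Optional[str] = None,
) -> ComparisonResult:
    """Run the normality-gated omnibus + post hoc comparison.

    Requires >= 2 groups with >= 3 values each, and the control group
    present.  All groups passing Shapiro-Wilk at ``alpha`` routes to
    ANOVA + Dunnett versus control; any failure (or a degenerate constant
    group, which is warned about) routes to Kruskal-Wallis + Dunn.
    """
    labels = [g for g in pd.unique(table[group_col])]
    if control not in labels:
        raise ValueError(f"control group {control!r} not present")
    labels = [control] + [g for g in labels if g != control]
    samples = {g: table.loc[table[group_col] == g, value_col]
               .dropna().to_numpy() for g in labels}
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in samples.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")

    normality_p: Dict[str, float] = {}
    all_normal = True
    for g, v in samples.items():
        if np.ptp(v) == 0.0:
            warnings.warn(
                f"group {g!r} is constant; routing to the nonparametric path"
            )
            normality_p[g] = float("nan")
            all_normal = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.shapiro(v).pvalue)
        normality_p[g] = p
        if p <= alpha:
            all_normal = False

    try:
        levene_p = float(sps.levene(*samples.values()).pvalue)
    except ValueError:
        levene_p = float("nan")

    if all_normal:
        stat, pval = sps.f_oneway(*samples.values())
        # Dunnett p-values integrate a multivariate t numerically with a
        # randomized rule; pin the state so identical inputs give
        # identical (reproducible) p-values.
        dn = sps.dunnett(*[samples[g] for g in labels[1:]],
                         control=samples[control],
                         random_state=np.random.default_rng(0))
        comparisons = pd.DataFrame({
            "group": labels[1:],
            "reference": control,
            "statistic": np.atleast_1d(dn.statistic),
            "p_raw": np.atleast_1d(dn.pvalue),  # Dunnett p is already adjusted
            "p_adj": np.atleast_1d(dn.pvalue),
        })
        comparisons["stars"] = [significance_stars(p)
                                for p in comparisons["p_adj"]]
        path = "anova_dunnett"
    else:
        stat, pval = sps.kruskal(*samples.values())
        long_vals = np.concatenate([samples[g] for g in labels])
        long_grp = np.concatenate([[g] * len(samples[g]) for g in labels])
        comparisons = dunn_test(long_vals, long_grp, control=control)
        path = "kruskal_dunn"

    return ComparisonResult(
        parameter=parameter,
        timepoint=timepoint,
        test_path=path,
        normality_p=normality_p,
        normality_ok=all_normal,
        levene_p=levene_p,
        statistic=float(stat),
        pvalue=float(pval),
        comparisons=comparisons,
        alpha=alpha,
    )


def compare_parameters(
    fit_table: pd.DataFrame,
    parameters: Sequence[str],
    control: str = "control",
    alpha: float = 0.05,
    timepoint_col: str = "timepoint",
    group_col: str = "group",
) -> pd.DataFrame:
    """Apply :func:`compare_groups` per parameter per timepoint.

    Returns a tidy results table (parameter, timepoint, path, omnibus
    statistic/p, group, adjusted p, stars).  Cells with too few larvae are
    skipped silently.
    """
    rows = []
    for tp in pd.unique(fit_table[timepoint_col]):
        sub = fit_table[fit_table[timepoint_col] == tp]
        for param in parameters:
            try:
                res = compare_groups(
                    sub.rename(columns={param: "value"}),
                    control=control, alpha=alpha,
                    parameter=param, timepoint=tp, group_col=group_col,
                )
            except ValueError:
                continue
            for _, r in res.comparisons.iterrows():
                rows.append({
                    "parameter": param, "timepoint": tp,
                    "test_path": res.test_path,
                    "omnibus_statistic": res.statistic,
                    "omnibus_p": res.pvalue,
                    "group": r["group"], "p_adj": r["p_adj"],
                    "stars": r["stars"],
                })
    return pd.DataFrame(rows)


def mortality_test(counts, correction: bool = False):
    """Pearson chi-square homogeneity test on a 2 x k dead/alive table.

    ``counts`` is array-like with two rows (dead, alive) and one column
    per group.  Yates continuity correction is off by default (the 2 x 3
    group table does not use it); pass ``correction=True`` for a corrected
    2 x 2 test.  Returns ``(chi2, p)``.
    """
    table = np.asarray(counts)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table (dead/alive rows)")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin in mortality table")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
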