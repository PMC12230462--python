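"""Relative expression and group-comparison statistics.

* ``ddct``: the Livak 2^-ddCt relative-expression method — per-sample
  dCt = Ct(target) - Ct(housekeeping), centered on the arithmetic mean
  dCt of the control group (equivalently the geometric-mean fold of
  the control group is 1), fold = 2^-ddCt.
* ``normalize_to_control``: express values as percent of the control
  group mean.
* ``compare_groups``: the group-comparison layer — unpaired t-test for
  two groups; one-way ANOVA + Tukey HSD, two-way ANOVA + Tukey within
  the second factor's levels, or Kruskal-Wallis + Dunn's rank test for
  more.  ``design="auto"`` screens each group with Shapiro-Wilk
  (alpha 0.05) and drops to the nonparametric path when any group
  fails.

Dunn's post hoc test is implemented here directly (pairwise z tests on
mean ranks with tie correction, Holm or Bonferroni adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ddct",
    "normalize_to_control",
    "compare_groups",
    "dunn_test",
]

ALPHA = 0.05


@dataclass
class TestResult:
    method: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None   # columns: group1, group2, p_adj
    alpha: float = ALPHA
    degenerate: bool = False
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def ddct(table: pd.DataFrame, housekeeping: str, control_group: str,
         target: str | None = None) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes.

    ``table`` is tidy with columns sample, group, gene, ct.  Returns a
    frame with one row per sample x target gene carrying dct, ddct and
    fold.  The control group's mean fold is 1 in the geometric sense by
    construction.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("non-finite Ct values present")
    hk = table[table["gene"] == housekeeping].set_index("sample")["ct"]
    targets = table[table["gene"] != housekeeping]
    if target is not None:
        targets = targets[targets["gene"] == target]
    missing = sorted(set(targets["sample"]) - set(hk.index))
    if missing:
        raise ValueError(f"samples missing housekeeping Ct: {missing}")
    out = targets.copy()
    out["dct"] = out["ct"].to_numpy() - hk.loc[out["sample"]].to_numpy()
    rows = []
    for gene, sub in out.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "dct"]
        if ctrl.empty:
            raise ValueError(f"control group '{control_group}' empty for "
                             f"gene {gene}")
        ddct_vals = sub["dct"] - ctrl.mean()
        sub = sub.assign(ddct=ddct_vals, fold=2.0 ** (-ddct_vals))
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)[
        ["sample", "group", "gene", "ct", "dct", "ddct", "fold"]
    ]


def normalize_to_control(table: pd.DataFrame, control_group: str,
                         value: str = "value", group: str = "group",
                         ) -> pd.DataFrame:
    """Rescale values to percent of the control-group mean (mean -> 100%)."""
    ctrl = table.loc[table[group] == control_group, value]
    if ctrl.empty:
        raise ValueError(f"control group '{control_group}' not found")
    m = ctrl.mean()
    if m == 0:
        raise ValueError("control mean is zero; percent normalization undefined")
    out = table.copy()
    out[value] = 100.0 * out[value] / m
    return out


# ---------------------------------------------------------------------------
# Dunn's post hoc (rank-based pairwise z tests)
# ---------------------------------------------------------------------------

def dunn_test(samples: dict[str, np.ndarray],
              adjust: str = "holm") -> pd.DataFrame:
    """Dunn's multiple-comparison test following Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) )
    where Rbar are mean ranks over the pooled sample and
    T = sum(t^3 - t)/(12(N-1)) corrects for ties.  Two-sided p-values
    with Holm (default) or Bonferroni adjustment.
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], float) for g in names])
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    mean_ranks, sizes = {}, {}
    i = 0
    for g in names:
        n = len(samples[g])
        mean_ranks[g] = ranks[i:i + n].mean()
        sizes[g] = n
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((g1, g2, z, p))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    df["p_adj"] = _adjust_pvalues(df["p_raw"].to_numpy(), adjust)
    return df


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError("adjust must be 'holm' or 'bonferroni'")


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _group_arrays(table: pd.DataFrame, value: str, group: str,
                  ) -> dict[str, np.ndarray]:
    out = {g: sub[value].to_numpy(dtype=float)
           for g, sub in table.groupby(group, sort=False)}
    for g, arr in out.items():
        if arr.size < 2:
            raise ValueError(f"group '{g}' has fewer than 2 observations")
    return out


def _normality_ok(samples: dict[str, np.ndarray], alpha: float) -> bool:
    for arr in samples.values():
        if arr.size < 3 or np.ptp(arr) == 0:
            continue  # Shapiro is undefined; treat as unremarkable
        if sps.shapiro(arr).pvalue < alpha:
            return False
    return True


def _tukey(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(samples)
    res = sps.tukey_hsd(*[samples[g] for g in names])
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append((names[i], names[j], float(res.pvalue[i, j])))
    return pd.DataFrame(rows, columns=["group1", "group2", "p_adj"])


def compare_groups(table: pd.DataFrame, design: str = "auto",
                   value: str = "value", group: str = "group",
                   factor2: str | None = None,
                   alpha: float = ALPHA,
                   dunn_adjust: str = "holm") -> TestResult:
    """Compare group means/distributions the way this field reports them.

    designs: ``"one-way"`` (ANOVA + Tukey HSD), ``"two-way"`` (two-factor
    ANOVA + Tukey on the group factor within each level of ``factor2``),
    ``"nonparametric"`` (Kruskal-Wallis + Dunn), ``"auto"`` (two groups ->
    t-test; otherwise one-way unless a Shapiro-Wilk screen fails, then
    nonparametric).
    """
    samples = _group_arrays(table, value, group)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    degenerate = all(np.ptp(a) == 0 for a in samples.values())
    if degenerate:
        # zero within-group variance everywhere: any test statistic is
        # 0/0; report the trivial answer (identical means: no evidence
        # of difference; different means: exact separation) with a flag
        names = list(samples)
        means = {g: float(a.mean()) for g, a in samples.items()}
        identical = np.ptp(list(means.values())) == 0
        pw = pd.DataFrame(
            [(g1, g2, 1.0 if means[g1] == means[g2] else 0.0)
             for g1, g2 in combinations(names, 2)],
            columns=["group1", "group2", "p_adj"],
        )
        return TestResult("degenerate (zero within-group variance)",
                          0.0 if identical else float("inf"),
                          1.0 if identical else 0.0,
                          pw, alpha, degenerate=True)
    if design == "auto":
        if factor2 is not None:
            design = "two-way"
        elif len(samples) == 2:
            design = "t-test"
        elif _normality_ok(samples, alpha):
            design = "one-way"
        else:
            design = "nonparametric"
    if design == "t-test" or (design == "one-way" and len(samples) == 2):
        a, b = samples.values()
        res = sps.ttest_ind(a, b)
        names = list(samples)
        pw = pd.DataFrame([(names[0], names[1], float(res.pvalue))],
                          columns=["group1", "group2", "p_adj"])
        return TestResult("unpaired t-test", float(res.statistic),
                          float(res.pvalue), pw, alpha, degenerate)
    if design == "one-way":
        f, p = sps.f_oneway(*samples.values())
        return TestResult("one-way ANOVA + Tukey HSD", float(f), float(p),
                          _tukey(samples), alpha, degenerate)
    if design == "two-way":
        if factor2 is None or factor2 not in table.columns:
            raise ValueError("two-way design requires factor2")
        return _two_way(table, value, group, factor2, alpha, degenerate)
    if design == "nonparametric":
        h, p = sps.kruskal(*samples.values())
        pw = dunn_test(samples, adjust=dunn_adjust)[
            ["group1", "group2", "p_adj"]
        ]
        return TestResult("Kruskal-Wallis + Dunn", float(h), float(p), pw,
                          alpha, degenerate)
    raise ValueError(f"unknown design '{design}'")


def _two_way(table: pd.DataFrame, value: str, group: str, factor2: str,
             alpha: float, degenerate: bool) -> TestResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={value: "_y", group: "_g", factor2: "_f"})
    model = smf.ols("_y ~ C(_g) * C(_f)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f_group = float(anova.loc["C(_g)", "F"])
    p_group = float(anova.loc["C(_g)", "PR(>F)"])
    rows = []
    for lev, sub in df.groupby("_f", sort=False):
        samples = {g: s["_y"].to_numpy(dtype=float)
                   for g, s in sub.groupby("_g", sort=False)}
        if len(samples) < 2 or any(a.size < 2 for a in samples.values()):
            continue
        pw = _tukey(samples)
        pw.insert(0, factor2, lev)
        rows.append(pw)
    pairwise = pd.concat(rows, ignore_index=True) if rows else None
    return TestResult(
        "two-way ANOVA + Tukey HSD (within factor levels)",
        f_group, p_group, pairwise, alpha, degenerate,
        details={"anova_table": anova},
    )
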