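"""Baseline-table and alpha-diversity group statistics.

Pearson chi-square (no continuity correction) or Fisher's exact test for
2x2 tables, Mann-Whitney U for unpaired numeric comparisons, Wilcoxon
signed-rank for paired ones, and the stratified alpha-diversity comparisons
the paired pre/post design calls for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Fisher's exact test replaces chi-square when any observed cell is below this.
FISHER_CELL_THRESHOLD = 5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts [[a, b], [c, d]]: rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def min_cell(self) -> int:
        return min(self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p_value: float
    test_name: str


def chi2_2x2(t: ContingencyTable2x2) -> GroupComparisonResult:
    """Pearson chi-square on a 2x2 table, one df, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); errors on a zero margin.
    """
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate 2x2 table: a row or column margin is zero")
    chi2 = t.n * (t.a * t.d - t.b * t.c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return GroupComparisonResult(float(chi2), p, "chi2")


def fisher_exact_2x2(t: ContingencyTable2x2) -> GroupComparisonResult:
    """Two-sided Fisher's exact test (hypergeometric probability sum)."""
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate 2x2 table: a row or column margin is zero")
    odds, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return GroupComparisonResult(float(odds), float(p), "fisher_exact")


def categorical_2x2(t: ContingencyTable2x2) -> GroupComparisonResult:
    """Chi-square, switching to Fisher's exact when any observed cell < 5."""
    if t.min_cell() < FISHER_CELL_THRESHOLD:
        return fisher_exact_2x2(t)
    return chi2_2x2(t)


def mann_whitney_u(x, y) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both groups have <= 25 observations and the
    pooled data are tie-free; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size <= 25 and y.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparisonResult(float(res.statistic), float(res.pvalue), f"mann_whitney_u_{method}")


def wilcoxon_signed_rank(pre, post) -> GroupComparisonResult:
    """Two-sided Wilcoxon signed-rank on paired vectors.

    Zero differences are dropped (Wilcoxon's original treatment); exact
    distribution for <= 25 non-zero pairs, normal approximation beyond.
    All-zero differences give p = 1 with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = post - pre
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p set to 1", stacklevel=2)
        return GroupComparisonResult(0.0, 1.0, "wilcoxon_signed_rank")
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (nonzero.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(post, pre, zero_method="wilcox", alternative="two-sided", method=method)
    return GroupComparisonResult(float(res.statistic), float(res.pvalue), f"wilcoxon_signed_rank_{method}")


def alpha_group_tests(alpha: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Stratified group tests on per-sample alpha-diversity metrics.

    For each metric column of ``alpha`` (all columns except sample_id):
    paired pre-versus-post signed-rank tests within each ileostomy stratum
    (subjects missing one sample are excluded from the pairing only), and
    unpaired SDD-versus-no-SDD rank-sum tests within each timepoint. The
    two-group rank-sum comparison coincides with a two-group
    Kruskal-Wallis test up to the statistic's parameterisation. Strata with
    fewer than 2 usable subjects are skipped with a warning.
    """
    merged = alpha.merge(metadata, on="sample_id", validate="one_to_one")
    metrics = [c for c in alpha.columns if c != "sample_id"]
    rows = []
    for metric in metrics:
        for ileo in ("yes", "no"):
            grp = merged[merged["ileostomy"] == ileo]
            wide = grp.pivot_table(index="subject_id", columns="timepoint", values=metric, aggfunc="first")
            if "pre" not in wide.columns or "post" not in wide.columns:
                paired = wide.iloc[0:0]
            else:
                paired = wide.dropna(subset=["pre", "post"])
            if len(paired) < 2:
                warnings.warn(
                    f"skipping paired pre/post test for {metric}, ileostomy={ileo}: "
                    f"{len(paired)} complete pair(s)",
                    stacklevel=2,
                )
                continue
            res = wilcoxon_signed_rank(paired["pre"].to_numpy(), paired["post"].to_numpy())
            rows.append(
                {
                    "metric": metric,
                    "comparison": "pre_vs_post",
                    "stratum": f"ileostomy={ileo}",
                    "n": len(paired),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "test": res.test_name,
                }
            )
        for tp in ("pre", "post"):
            grp = merged[merged["timepoint"] == tp]
            x = grp.loc[grp["sdd"] == "yes", metric].to_numpy()
            y = grp.loc[grp["sdd"] == "no", metric].to_numpy()
            if min(x.size, y.size) < 2:
                warnings.warn(
                    f"skipping SDD test for {metric}, timepoint={tp}: too few samples",
                    stacklevel=2,
                )
                continue
            res = mann_whitney_u(x, y)
            rows.append(
                {
                    "metric": metric,
                    "comparison": "sdd_vs_no_sdd",
                    "stratum": f"timepoint={tp}",
                    "n": int(x.size + y.size),
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "test": res.test_name,
                }
            )
    return pd.DataFrame(
        rows, columns=["metric", "comparison", "stratum", "n", "statistic", "p_value", "test"]
    )


def baseline_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Descriptive subject-level baseline table with group comparisons.

    Counts and percentages of the subject-level factors, compared across
    the SDD and ileostomy stratifications with chi-square or Fisher's exact
    as appropriate.
    """
    subjects = metadata.drop_duplicates("subject_id")
    rows = []
    for split in ("sdd", "ileostomy"):
        other = "ileostomy" if split == "sdd" else "sdd"
        g_yes = subjects[subjects[split] == "yes"]
        g_no = subjects[subjects[split] == "no"]
        a = int((g_yes[other] == "yes").sum())
        b = int((g_yes[other] == "no").sum())
        c = int((g_no[other] == "yes").sum())
        d = int((g_no[other] == "no").sum())
        try:
            res = categorical_2x2(ContingencyTable2x2(a, b, c, d))
            p, test = res.p_value, res.test_name
        except ValueError:
            p, test = np.nan, "degenerate"
        rows.append(
            {
                "stratification": split,
                "characteristic": other,
                f"{split}_yes_n": len(g_yes),
                f"{split}_no_n": len(g_no),
                "yes_count_in_yes": a,
                "yes_count_in_no": c,
                "p_value": p,
                "test": test,
            }
        )
    return pd.DataFrame(rows)
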