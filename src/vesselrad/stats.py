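"""Two-group comparison and adjusted-regression workflow for cohort tables.

For each measurement the two groups are first screened for normality
(Shapiro–Wilk per group at alpha = 0.05).  If both pass, a two-sample
t-test is used (pooled or Welch, chosen by a Levene variance-equality
check) and groups are summarized as mean ± sd; otherwise a Mann–Whitney U
test is used — exact enumeration over all rank splits when both groups
have n <= 8, a tie-corrected normal approximation otherwise — and groups
are summarized as median (Q1, Q3).

The adjusted analysis is an ordinary-least-squares regression of a volume
outcome on group (patient = 1), age, sex (female = 1) and BSA, with
heteroskedasticity-robust standard errors (HC3 by default).

No multiple-testing adjustment is applied; reports carry a footnote saying
so.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import EstimationError, SchemaError, ValidationError, VesselradError

GROUPS = ("control", "patient")

#: canonical measurement order: totals, then arterial bins, then venous bins
DEFAULT_MEASUREMENTS = (
    ["TIPVV", "IPVVa", "IPVVv"]
    + [f"IPVVa_{b}" for b in ("0.8-1.6", "1.6-2.4", "2.4-3.2", "3.2-4.0", ">4.0")]
    + [f"IPVVv_{b}" for b in ("0.8-1.6", "1.6-2.4", "2.4-3.2", "3.2-4.0", ">4.0")]
)


@dataclass
class GroupComparison:
    """Result of one two-group test on one measurement."""

    measurement: str
    test: str  # 'student_t' | 'welch_t' | 'mann_whitney_u'
    method: str  # 'parametric' | 'exact' | 'asymptotic'
    statistic: float  # t, or z (asymptotic U), or U_min (exact)
    statistic_name: str
    p_value: float
    n_control: int
    n_patient: int
    summary_control: str
    summary_patient: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise VesselradError(f"p-value {self.p_value} outside [0, 1]")


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney U test by full enumeration.

    Handles ties via midranks.  The two-sided p-value is the permutation
    probability of a U at least as far from its null mean nm/2 as observed,
    over all C(n+m, n) assignments of the pooled values to the first group.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    dev = abs(u_obs - n * m / 2.0)
    hits = total = 0
    for comb in itertools.combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2.0
        total += 1
        if abs(u - n * m / 2.0) >= dev - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def mann_whitney_asymptotic(x, y, continuity: bool = False) -> tuple[float, float, float]:
    """Tie-corrected normal-approximation Mann–Whitney U test.

    Returns (U of the first sample, standardized z, two-sided p).  The
    continuity correction (0.5 toward the mean) is off by default.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = len(x), len(y)
    big_n = n + m
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (big_n * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return float(u), 0.0, 1.0
    num = u - mu
    if continuity and num != 0:
        num -= 0.5 * math.copysign(1.0, num)
    z = num / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u), float(z), float(min(p, 1.0))


def _summaries(values: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{values.mean():.2f} ± {values.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def compare_groups(
    table: pd.DataFrame,
    measurement: str,
    alpha: float = 0.05,
    continuity: bool = False,
) -> GroupComparison:
    """Distribution-gated two-group comparison of one measurement.

    Shapiro–Wilk per group at ``alpha``; both normal -> t-test (pooled if a
    Levene test accepts equal variances, Welch otherwise), else
    Mann–Whitney U (exact enumeration when both n <= 8).
    """
    if measurement not in table.columns:
        raise SchemaError(f"measurement {measurement!r} not in cohort table")
    if "group" not in table.columns:
        raise SchemaError("cohort table lacks a 'group' column")
    by_group = {}
    for g in GROUPS:
        v = table.loc[table["group"] == g, measurement].dropna().to_numpy(dtype=np.float64)
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
        by_group[g] = v
    x, y = by_group["control"], by_group["patient"]

    normal = all(
        len(np.unique(v)) > 1 and sps.shapiro(v).pvalue > alpha for v in (x, y)
    )
    if normal:
        equal_var = sps.levene(x, y).pvalue > 0.05
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        test = "student_t" if equal_var else "welch_t"
        return GroupComparison(
            measurement=measurement, test=test, method="parametric",
            statistic=float(res.statistic), statistic_name="t",
            p_value=float(res.pvalue), n_control=len(x), n_patient=len(y),
            summary_control=_summaries(x, True), summary_patient=_summaries(y, True),
        )
    if len(x) <= 8 and len(y) <= 8:
        u, p = mann_whitney_exact(x, y)
        stat, name, method = min(u, len(x) * len(y) - u), "U", "exact"
    else:
        _, z, p = mann_whitney_asymptotic(x, y, continuity=continuity)
        stat, name, method = z, "Z", "asymptotic"
    return GroupComparison(
        measurement=measurement, test="mann_whitney_u", method=method,
        statistic=float(stat), statistic_name=name, p_value=float(p),
        n_control=len(x), n_patient=len(y),
        summary_control=_summaries(x, False), summary_patient=_summaries(y, False),
    )


def adjusted_regression(
    table: pd.DataFrame,
    outcome: str = "IPVVa",
    covariates: tuple[str, ...] = ("group", "age", "sex", "bsa"),
    robust: str = "HC3",
) -> pd.DataFrame:
    """OLS of ``outcome`` on group + covariates with robust standard errors.

    Group is coded patient = 1, sex female = 1.  ``robust`` selects the
    heteroskedasticity-consistent covariance (HC0–HC3; 'classical' gives
    the ordinary OLS covariance).  Returns a coefficient table with
    estimate, robust SE, t and p per term.
    """
    if outcome not in table.columns:
        raise SchemaError(f"outcome {outcome!r} not in cohort table")
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise SchemaError(f"covariate(s) {missing} not in cohort table")
    df = table.dropna(subset=[outcome, *covariates])
    if len(df) < 10:
        raise ValidationError(f"need >= 10 complete rows, got {len(df)}")

    design = pd.DataFrame(index=df.index)
    for c in covariates:
        if c == "group":
            design["group"] = (df["group"] == "patient").astype(float)
        elif c == "sex":
            design["sex_female"] = (df["sex"] == "female").astype(float)
        else:
            design[c] = df[c].astype(float)
    x_mat = sm.add_constant(design, has_constant="add")

    rank = np.linalg.matrix_rank(x_mat.to_numpy())
    if rank < x_mat.shape[1]:
        culprits = [
            col for col in design.columns
            if np.linalg.matrix_rank(x_mat.drop(columns=[col]).to_numpy()) == rank
        ]
        raise EstimationError(f"design matrix is rank deficient; collinear column(s): {culprits}")

    robust = robust.upper()
    if robust == "CLASSICAL":
        fit = sm.OLS(df[outcome].astype(float), x_mat).fit()
    elif robust in ("HC0", "HC1", "HC2", "HC3"):
        fit = sm.OLS(df[outcome].astype(float), x_mat).fit(cov_type=robust)
    else:
        raise ValidationError(f"unknown robust-SE flavor {robust!r}")
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "robust_se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )


def analyze_cohort(
    table: pd.DataFrame,
    measurements: list[str] | None = None,
    alpha: float = 0.05,
    continuity: bool = False,
) -> list[GroupComparison]:
    """Run the gated two-group test on every measurement, in table order."""
    measurements = measurements or [m for m in DEFAULT_MEASUREMENTS if m in table.columns]
    return [compare_groups(table, m, alpha=alpha, continuity=continuity) for m in measurements]


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "measurement": [c.measurement for c in comparisons],
            "control": [c.summary_control for c in comparisons],
            "patient": [c.summary_patient for c in comparisons],
            "test": [c.test for c in comparisons],
            "method": [c.method for c in comparisons],
            "statistic_name": [c.statistic_name for c in comparisons],
            "statistic": [c.statistic for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
        }
    )


def render_report(
    comparisons: list[GroupComparison],
    regression: pd.DataFrame | None,
    out_dir: str | Path,
    table: pd.DataFrame | None = None,
    plots: bool = False,
) -> Path:
    """Write comparisons.csv, regression.csv and a human-readable report.

    Rows keep the order supplied (totals first, then arterial bins, then
    venous bins, mirroring the standard report layout).  With ``plots`` and
    a cohort table, per-measurement group boxplots are saved as PNG.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comp_df = comparisons_frame(comparisons)
    comp_df.to_csv(out_dir / "comparisons.csv", index=False)

    lines = [
        "Group comparison of BSA-normalized vessel volumes (mL·m⁻²)",
        "normal data: mean ± sd, t-test; non-normal: median (Q1, Q3), Mann–Whitney U",
        "p-values are unadjusted for multiple comparisons",
        "",
        f"{'measurement':<16}{'control':>24}{'patient':>24}{'stat':>10}{'p':>10}",
    ]
    for c in comparisons:
        lines.append(
            f"{c.measurement:<16}{c.summary_control:>24}{c.summary_patient:>24}"
            f"{c.statistic_name + '=' + format(c.statistic, '.3f'):>10}{c.p_value:>10.3f}"
        )
    if regression is not None:
        regression.to_csv(out_dir / "regression.csv")
        lines += ["", "Adjusted regression (robust SEs):", regression.to_string()]
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")

    if plots and table is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for c in comparisons:
            fig, ax = plt.subplots(figsize=(3.2, 3.2))
            data = [
                table.loc[table["group"] == g, c.measurement].dropna() for g in GROUPS
            ]
            ax.boxplot(data, tick_labels=list(GROUPS))
            ax.set_title(c.measurement)
            ax.set_ylabel("mL·m⁻²")
            fig.tight_layout()
            safe = c.measurement.replace(">", "gt").replace(".", "p")
            fig.savefig(out_dir / f"box_{safe}.png", dpi=120)
            plt.close(fig)
    return out_dir
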