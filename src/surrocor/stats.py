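"""Cohort statistics: Friedman + Dunn-Bonferroni, Mann-Whitney with effect
size r, Spearman correlations, and the independent-samples t-test with
Cohen's d.

The rank tests follow the SPSS conventions common in the clinical
literature: the Friedman statistic is the tie-corrected chi-square on
within-patient mid-ranks; the Mann-Whitney U is reported as min(U1, U2)
with a tie- and continuity-corrected normal z (negative by construction,
as printed in clinical tables) and effect size r = |z| / sqrt(N); the
Dunn-Bonferroni post hoc compares Friedman mean ranks with a Bonferroni
factor over the k(k-1)/2 pairs.  Spearman's Rho and the pooled-variance
t-test delegate to scipy behind this surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

ROI_LABELS = ["A", "A_R", "A_L", "B", "B_R", "B_L", "C", "C_R", "C_L"]
MAG_COLS = [f"mag_{lab}" for lab in ROI_LABELS]
R_COLS = [f"r_{lab}" for lab in ROI_LABELS]
COVARIATE_COLS = ["sat_pct", "vat_pct", "tat_pct", "bmi", "height_cm"]
REQUIRED_COLS = (
    ["patient_id", "sex", "height_cm", "bmi", "sat_pct", "vat_pct", "tat_pct",
     "ts_magnitude_mm"] + MAG_COLS + R_COLS
)

__all__ = [
    "TestResult",
    "friedman",
    "dunn_bonferroni",
    "mann_whitney",
    "effect_size_r",
    "spearman",
    "ttest_ind",
    "cohens_d_from_t",
    "validate_cohort",
    "build_reports",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, and effect size where defined."""

    name: str
    statistic: float
    p: float
    df: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    ci: tuple[float, float] | None = None
    ns: tuple[int, ...] | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def _as_table(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected an n x k table (patients x conditions)")
    if np.isnan(v).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    return v


def _row_ranks(v: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, v)


def friedman(values) -> TestResult:
    """Friedman test for k repeated conditions over n subjects.

    Tie-corrected chi-square on within-subject mid-ranks, df = k - 1,
    upper-tail chi-square p.  Requires n >= 2, k >= 3 and no missing cells.
    """
    v = _as_table(values)
    n, k = v.shape
    if n < 2 or k < 3:
        raise ValueError("friedman needs n >= 2 subjects and k >= 3 conditions")
    ranks = _row_ranks(v)
    col_sums = ranks.sum(axis=0)
    ssbn = float((col_sums**2).sum())
    ties = 0.0
    for row in v:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k**2 - 1))
    numerator = 12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)
    if c <= 0:  # every row fully tied: no information, no effect
        stat = 0.0
    else:
        stat = numerator / c
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(
        name="Friedman Chi2", statistic=float(stat), df=float(k - 1), p=p,
        ns=(n, k),
    )


def dunn_bonferroni(values, labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn post hoc on Friedman mean ranks with Bonferroni adjustment.

    For each of the k(k-1)/2 condition pairs,
    z = (meanrank_i - meanrank_j) / sqrt(k(k+1) / (6 n)), two-sided normal
    p, adjusted p = min(1, p * k(k-1)/2).  Returns a tidy DataFrame.
    """
    v = _as_table(values)
    n, k = v.shape
    if n < 2 or k < 3:
        raise ValueError("post hoc needs n >= 2 subjects and k >= 3 conditions")
    if labels is None:
        labels = [f"c{j}" for j in range(k)]
    if len(labels) != k:
        raise ValueError("need one label per condition")
    mean_ranks = _row_ranks(v).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * float(sps.norm.sf(abs(z)))
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "mean_rank_i": mean_ranks[i],
                "mean_rank_j": mean_ranks[j],
                "z": z,
                "p": min(p, 1.0),
                "p_adjusted": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows)


def mann_whitney(a, b) -> TestResult:
    """Mann-Whitney U test between two independent groups.

    U is reported as min(U_a, U_b); z uses the normal approximation with
    tie correction and a 0.5 continuity correction toward the mean (so z is
    <= 0, the convention of clinical tables); two-sided p; effect size
    r = |z| / sqrt(n_a + n_b).  When every pooled value is tied the data
    carry no ordering evidence: z = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    diff = u - mu
    if sigma2 <= 0:  # every pooled value tied: no evidence either way
        z = 0.0
    elif diff < 0:
        z = (diff + 0.5) / np.sqrt(sigma2)
    elif diff > 0:
        z = (diff - 0.5) / np.sqrt(sigma2)
    else:
        z = 0.0
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(
        name="Mann-Whitney U",
        statistic=float(u),
        p=p,
        effect_size=effect_size_r(z, N),
        effect_size_name="r",
        ns=(n1, n2),
        extra={"z": float(z), "U1": float(u1), "U2": float(u2)},
    )


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = |z| / sqrt(N)."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    return float(abs(z) / np.sqrt(n_total))


def spearman(x, y) -> TestResult:
    """Spearman's Rho: Pearson correlation of mid-ranks, t-distribution p.

    Flagged undefined (NaN statistic and p) when either series has zero
    rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs equal-length series with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return TestResult(
            name="Spearman Rho", statistic=float("nan"), p=float("nan"),
            ns=(x.size,), extra={"undefined": "zero rank variance"},
        )
    res = sps.spearmanr(x, y)
    return TestResult(
        name="Spearman Rho",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        ns=(x.size,),
    )


def ttest_ind(a, b) -> TestResult:
    """Independent-samples pooled-variance t-test with Cohen's d.

    df = n_a + n_b - 2; 95% CI of the mean difference; d is the absolute
    standardised mean difference over the pooled SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    ci = res.confidence_interval(0.95)
    d = abs(a.mean() - b.mean()) / np.sqrt(sp2)
    return TestResult(
        name="t",
        statistic=float(res.statistic),
        df=float(n1 + n2 - 2),
        p=float(res.pvalue),
        effect_size=float(d),
        effect_size_name="Cohen's d",
        ci=(float(ci.low), float(ci.high)),
        ns=(n1, n2),
    )


def cohens_d_from_t(t: float, n_a: int, n_b: int) -> float:
    """Cohen's d recovered from a pooled t statistic:
    d = |t| * sqrt(1/n_a + 1/n_b)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be >= 2")
    return float(abs(t) * np.sqrt(1.0 / n_a + 1.0 / n_b))


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the cohort table invariants; raises naming what is wrong."""
    missing = [c for c in REQUIRED_COLS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {', '.join(missing)}")
    if cohort["patient_id"].duplicated().any():
        raise ValueError("duplicated patient_id")
    if not cohort["sex"].isin(["M", "F"]).all():
        raise ValueError("sex must be 'M' or 'F' for every patient")


def _iqr(x: pd.Series) -> float:
    return float(x.quantile(0.75) - x.quantile(0.25))


def build_reports(
    cohort: pd.DataFrame, out_dir=None, aggregator: str = "mean"
) -> dict[str, pd.DataFrame]:
    """Build the three cohort reports; optionally write CSV + Markdown.

    - ``friedman_posthoc``: Friedman Chi2 over the nine ROIs (magnitude and
      correlation blocks) with the Dunn-Bonferroni pairwise matrix.
    - ``sex_comparison``: per-ROI median (IQR) by sex with Mann-Whitney
      U, z, p and effect size r, for both blocks.
    - ``covariate_spearman``: Spearman Rho of the five covariates against
      the nine ROIs, both blocks, flagged significant at p < 0.05.

    Needs >= 2 patients and both sexes present for the sex comparison.
    """
    validate_cohort(cohort)
    reports: dict[str, pd.DataFrame] = {}

    fried_rows = []
    posthoc_frames = []
    for block, cols in [("magnitude", MAG_COLS), ("correlation", R_COLS)]:
        table = cohort[cols].to_numpy(dtype=float)
        res = friedman(table)
        fried_rows.append(
            {"block": block, "chi2": res.statistic, "df": res.df, "p": res.p,
             "n_patients": len(cohort)}
        )
        ph = dunn_bonferroni(table, labels=ROI_LABELS)
        ph.insert(0, "block", block)
        posthoc_frames.append(ph)
    reports["friedman"] = pd.DataFrame(fried_rows)
    reports["friedman_posthoc"] = pd.concat(posthoc_frames, ignore_index=True)

    sexes = sorted(cohort["sex"].unique())
    sex_rows = []
    if len(sexes) == 2:
        men = cohort[cohort["sex"] == "M"]
        women = cohort[cohort["sex"] == "F"]
        for block, cols in [("magnitude", MAG_COLS), ("correlation", R_COLS)]:
            for lab, col in zip(ROI_LABELS, cols):
                res = mann_whitney(men[col].to_numpy(), women[col].to_numpy())
                sex_rows.append(
                    {
                        "block": block,
                        "roi": lab,
                        "median_men": float(men[col].median()),
                        "iqr_men": _iqr(men[col]),
                        "median_women": float(women[col].median()),
                        "iqr_women": _iqr(women[col]),
                        "U": res.statistic,
                        "z": res.extra["z"],
                        "p": res.p,
                        "r": res.effect_size,
                        "significant": res.p < 0.05,
                    }
                )
        if len(men) >= 2 and len(women) >= 2:
            ts_res = ttest_ind(
                men["ts_magnitude_mm"].to_numpy(), women["ts_magnitude_mm"].to_numpy()
            )
            reports["ts_sex_ttest"] = pd.DataFrame(
                [{
                    "t": ts_res.statistic, "df": ts_res.df, "p": ts_res.p,
                    "ci_low": ts_res.ci[0], "ci_high": ts_res.ci[1],
                    "cohens_d": ts_res.effect_size,
                    "n_men": ts_res.ns[0], "n_women": ts_res.ns[1],
                }]
            )
    reports["sex_comparison"] = pd.DataFrame(sex_rows)

    sp_rows = []
    undefined = TestResult("Spearman Rho", float("nan"), float("nan"))
    for block, cols in [("magnitude", MAG_COLS), ("correlation", R_COLS)]:
        for cov in COVARIATE_COLS:
            for lab, col in zip(ROI_LABELS, cols):
                res = (
                    spearman(cohort[cov].to_numpy(), cohort[col].to_numpy())
                    if len(cohort) >= 3
                    else undefined
                )
                sp_rows.append(
                    {
                        "block": block,
                        "covariate": cov,
                        "roi": lab,
                        "rho": res.statistic,
                        "p": res.p,
                        "significant": bool(np.isfinite(res.p) and res.p < 0.05),
                    }
                )
    reports["covariate_spearman"] = pd.DataFrame(sp_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in reports.items():
            frame.to_csv(out_dir / f"{name}.csv", index=False)
            (out_dir / f"{name}.md").write_text(frame_to_markdown(frame))
    return reports


def frame_to_markdown(frame: pd.DataFrame, float_fmt: str = ".3f") -> str:
    """Render a DataFrame as a GitHub pipe table (floats at 3 decimals)."""

    def fmt(v) -> str:
        if isinstance(v, (float, np.floating)):
            return "nan" if not np.isfinite(v) else format(v, float_fmt)
        return str(v)

    cols = [str(c) for c in frame.columns]
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for rec in frame.itertuples(index=False):
        lines.append("| " + " | ".join(fmt(v) for v in rec) + " |")
    return "\n".join(lines) + "\n"
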