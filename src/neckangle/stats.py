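"""Reliability statistics for the two-rater validation design.

Implements the battery used to validate the measurement: descriptives
per displacement level, single-measures absolute-agreement intraclass
correlation from the two-way ANOVA decomposition (the "two-way mixed,
absolute agreement" model of McGraw & Wong, SPSS convention) with
F-based 95% confidence interval and p-value, Pearson correlation, and
paired Student t-tests with 95% confidence intervals.

Alpha conventions follow the study: 0.05 two-tailed for ICC and paired
t, 0.01 two-tailed for Pearson.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .series import MeasurementSeries


@dataclass(frozen=True)
class ICCResult:
    """Single-measures absolute-agreement ICC with F-based CI and p."""

    icc: float
    ci_low: float
    ci_high: float
    p: float
    n_subjects: int
    k_raters: int
    model: str = "two-way mixed, absolute agreement, single measures"

    def __post_init__(self):
        if not (self.ci_low <= self.icc + 1e-12 and self.icc <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the ICC estimate")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be a probability")


@dataclass(frozen=True)
class PairedTestResult:
    """Paired Student t-test, from raw differences or printed summaries."""

    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    exact_agreement: bool = False

    def __post_init__(self):
        if not self.exact_agreement:
            if not (self.ci_low <= self.mean_diff <= self.ci_high):
                raise ValueError("CI must bracket the mean difference")


def descriptives(series: MeasurementSeries) -> pd.DataFrame:
    """Min, max, mean, sample SD and variance per (rater, level) cell."""
    df = series.data
    grouped = df.groupby(["rater", "set_angle_deg"])["measured_angle_deg"]
    sizes = grouped.size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"need at least 2 measurements per cell; short cells: {bad}")
    out = grouped.agg(n="size", min="min", max="max", mean="mean",
                      sd=lambda x: x.std(ddof=1),
                      variance=lambda x: x.var(ddof=1)).reset_index()
    return out


def _anova_mean_squares(M: np.ndarray):
    """Two-way single-observation ANOVA mean squares: rows (subjects),
    columns (raters), error."""
    n, k = M.shape
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((M - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute_agreement(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measures.

    ``matrix`` is subjects x raters with no missing cells.  The
    confidence interval and the p-value (H0: ICC = 0) use the
    F-distribution procedures of McGraw & Wong (1996), matching the
    SPSS "two-way mixed, absolute agreement" output.
    """
    M = np.asarray(pd.DataFrame(matrix), dtype=float)
    if M.ndim != 2:
        raise ValueError("matrix must be 2D (subjects x raters)")
    n, k = M.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(M)):
        raise ValueError("missing or non-finite cells; the design must be complete")

    msr, msc, mse = _anova_mean_squares(M)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300:
        raise ValueError("degenerate matrix: zero total variance")
    icc = (msr - mse) / denom

    # p-value for H0: ICC = 0 (F = MSR/MSE)
    if mse <= 0:
        # perfect agreement within rounding: exact fit
        p = 0.0
        lo, hi = icc, icc
        return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                         p=p, n_subjects=n, k_raters=k)
    F0 = msr / mse
    p = float(sps.f.sf(F0, n - 1, (n - 1) * (k - 1)))

    # Satterthwaite df for the CI
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = ((a * msc) ** 2 / (k - 1)
               + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = num / den if den > 0 else 1.0
        f_up = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_lo = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lo = (n * (msr - f_up * mse)
              / (f_up * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_lo * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_lo * msr))
    else:  # icc == 1 exactly
        lo = hi = icc
    lo = min(lo, icc)
    hi = max(hi, icc)
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     p=p, n_subjects=n, k_raters=k)


def pearson(x, y, alpha: float = 0.01):
    """Sample Pearson correlation with two-tailed t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_t(diff=None, *, mean: float = None, sd: float = None,
             n: int = None, alpha: float = 0.05) -> PairedTestResult:
    """Paired Student t-test from raw differences or a printed summary.

    Accepting (mean, sd, n) summaries allows re-deriving published
    confidence bounds from a results table without the raw data.
    """
    if diff is not None:
        d = np.asarray(diff, float)
        if d.ndim != 1 or len(d) < 2:
            raise ValueError("need at least 2 paired differences")
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        n = len(d)
    else:
        if mean is None or sd is None or n is None:
            raise ValueError("provide raw differences or (mean, sd, n)")
        mean, sd, n = float(mean), float(sd), int(n)
        if n < 2:
            raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("zero variance of differences; test degenerate "
                         "(exact agreement)")
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
    return PairedTestResult(mean_diff=mean, sd_diff=sd,
                            ci_low=mean - tcrit * se, ci_high=mean + tcrit * se,
                            t=float(t), df=df, p=p)


@dataclass
class ValidationReport:
    """Analogues of the study's three results tables."""

    descriptives: pd.DataFrame          # per rater x level (table-1 analogue)
    per_replicate: pd.DataFrame         # ICC + Pearson per replicate (table-2)
    icc_pooled: ICCResult               # all (level, replicate) pairs as subjects
    icc_mean_of_replicates: float
    paired_by_level: pd.DataFrame       # paired t per level (table-3 analogue)

    def to_files(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.per_replicate.to_csv(out / "icc_per_replicate.csv", index=False)
        self.paired_by_level.to_csv(out / "paired_t_by_level.csv", index=False)
        summary = {
            "icc_pooled": self.icc_pooled.icc,
            "icc_pooled_ci": [self.icc_pooled.ci_low, self.icc_pooled.ci_high],
            "icc_pooled_p": self.icc_pooled.p,
            "icc_mean_of_replicates": self.icc_mean_of_replicates,
        }
        import json

        (out / "summary.json").write_text(json.dumps(summary, indent=2))


def run_validation_battery(series: MeasurementSeries) -> ValidationReport:
    """Compute the full table battery from a balanced two-rater series."""
    series.require_balanced()
    raters = series.raters
    if len(raters) != 2:
        raise ValueError("the validation battery expects exactly two raters")

    desc = descriptives(series)

    rows = []
    iccs = []
    for rep in series.replicates:
        M = series.matrix_for_replicate(rep)
        res = icc_absolute_agreement(M.to_numpy())
        x, y = M.iloc[:, 0].to_numpy(), M.iloc[:, 1].to_numpy()
        try:
            r, rp = pearson(x, y)
        except ValueError:
            r, rp = np.nan, np.nan
        iccs.append(res.icc)
        rows.append({"replicate": rep, "icc": res.icc, "icc_ci_low": res.ci_low,
                     "icc_ci_high": res.ci_high, "icc_p": res.p,
                     "pearson_r": r, "pearson_p": rp})
    per_rep = pd.DataFrame(rows)

    icc_pooled = icc_absolute_agreement(series.pooled_matrix().to_numpy())

    paired_rows = []
    df = series.data
    for lvl in series.levels:
        sub = df[df["set_angle_deg"] == lvl].pivot(index="replicate",
                                                   columns="rater",
                                                   values="measured_angle_deg")
        d = (sub[raters[0]] - sub[raters[1]]).to_numpy(float)
        if np.std(d, ddof=1) == 0:
            paired_rows.append({"set_angle_deg": lvl, "mean_diff": float(d.mean()),
                                "sd_diff": 0.0, "ci_low": float(d.mean()),
                                "ci_high": float(d.mean()), "t": np.nan,
                                "df": len(d) - 1, "p": np.nan,
                                "exact_agreement": True})
            continue
        res = paired_t(d)
        paired_rows.append({"set_angle_deg": lvl, "mean_diff": res.mean_diff,
                            "sd_diff": res.sd_diff, "ci_low": res.ci_low,
                            "ci_high": res.ci_high, "t": res.t, "df": res.df,
                            "p": res.p, "exact_agreement": False})
    paired = pd.DataFrame(paired_rows)

    return ValidationReport(descriptives=desc, per_replicate=per_rep,
                            icc_pooled=icc_pooled,
                            icc_mean_of_replicates=float(np.mean(iccs)),
                            paired_by_level=paired)
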