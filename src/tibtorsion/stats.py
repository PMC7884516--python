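"""Agreement statistics for rater and method comparison.

Implements the intraclass correlation coefficients used to report
interobserver and intermethod agreement — ICC for absolute agreement from a
two-way ANOVA, as single measures ICC(A,1) (two-way random reading) and as
average measures ICC(A,k) (two-way mixed reading) — with 95% confidence
intervals by the McGraw & Wong (1996) F-based procedure, alongside paired
and independent t-tests, the Shapiro-Wilk normality check, and mean
absolute differences (MAD).

With mean squares from the two-way layout (MSR rows/subjects, MSC
columns/raters, MSE residual), n subjects and k raters:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

Complete cases are required: no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateFitError, ValidationError


@dataclass
class RaterTable:
    """n subjects x k raters (or methods) measurement matrix, degrees."""

    values: np.ndarray
    subject_ids: list = None
    rater_ids: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("RaterTable values must be a 2D matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValidationError("RaterTable needs at least 2 subjects and 2 raters")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"RaterTable has a missing/non-finite cell at row {bad[0]}, "
                f"column {bad[1]} (complete cases required)"
            )
        if self.subject_ids is None:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if self.rater_ids is None:
            self.rater_ids = [f"r{j}" for j in range(k)]
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValidationError("RaterTable id lengths do not match the matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path) -> "RaterTable":
        """First column subject id, one column per rater, header row."""
        df = pd.read_csv(Path(path))
        if df.shape[1] < 3:
            raise ValidationError(
                "rater CSV needs a subject-id column plus at least 2 rater columns"
            )
        if df.isna().any().any():
            row = int(np.argwhere(df.isna().to_numpy())[0][0])
            col = df.columns[int(np.argwhere(df.isna().to_numpy())[0][1])]
            raise ValidationError(
                f"rater CSV has a missing cell at row {row}, column '{col}'"
            )
        return cls(
            values=df.iloc[:, 1:].to_numpy(dtype=float),
            subject_ids=df.iloc[:, 0].astype(str).tolist(),
            rater_ids=[str(c) for c in df.columns[1:]],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.rater_ids)
        df.insert(0, "subject", self.subject_ids)
        df.to_csv(Path(path), index=False)


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str  # "A1" or "Ak"
    n: int
    k: int
    mean_squares: dict = field(default_factory=dict)

    def __str__(self):
        return (
            f"ICC({self.model}) = {self.estimate:.3f} "
            f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}, n={self.n}, k={self.k})"
        )


def _mean_squares(table: RaterTable) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (subjects), columns (raters), error."""
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(max(mse, 0.0))


def icc_agreement_single(table: RaterTable, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): absolute agreement of single measures, two-way model."""
    msr, msc, mse = _mean_squares(table)
    n, k = table.n, table.k
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-30 or (msr < 1e-30 and msc < 1e-30 and mse < 1e-30):
        raise DegenerateFitError("ICC undefined: table has zero total variance")
    est = (msr - mse) / denom
    lo, hi = _icc_a1_ci(msr, msc, mse, n, k, est, alpha)
    return ICCResult(float(est), lo, hi, "A1", n, k, {"MSR": msr, "MSC": msc, "MSE": mse})


def icc_agreement_average(table: RaterTable, alpha: float = 0.05) -> ICCResult:
    """ICC(A,k): absolute agreement of average measures, two-way model."""
    msr, msc, mse = _mean_squares(table)
    n, k = table.n, table.k
    denom = msr + (msc - mse) / n
    if abs(denom) < 1e-30 or (msr < 1e-30 and msc < 1e-30 and mse < 1e-30):
        raise DegenerateFitError("ICC undefined: table has zero total variance")
    est = (msr - mse) / denom
    single = icc_agreement_single(table, alpha)
    lo = _spearman_brown(single.ci_low, k)
    hi = _spearman_brown(single.ci_high, k)
    return ICCResult(float(est), lo, hi, "Ak", n, k, {"MSR": msr, "MSC": msc, "MSE": mse})


def _spearman_brown(r: float, k: int) -> float:
    denom = 1.0 + (k - 1) * r
    if abs(denom) < 1e-30:
        return 1.0
    return float(k * r / denom)


def _icc_a1_ci(msr, msc, mse, n, k, est, alpha) -> tuple[float, float]:
    """McGraw & Wong F-based 95% interval for ICC(A,1), with the
    Satterthwaite degrees of freedom of the mixed denominator."""
    if est >= 1.0 - 1e-12:
        return 1.0, 1.0
    a = (k * est) / (n * (1.0 - est))
    b = 1.0 + (k * est * (n - 1.0)) / (n * (1.0 - est))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
    f1 = sps.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f2 = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# t-tests, normality, MAD


def paired_t(a, b) -> dict:
    """Paired-samples t-test plus the mean difference +/- sd and range that
    clinical method-comparison tables report."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired_t needs two equal-length vectors, n >= 2")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd < 1e-30:
        if np.allclose(d, 0):
            return {
                "t": 0.0,
                "df": len(d) - 1,
                "p": 1.0,
                "mean_difference": 0.0,
                "sd_difference": 0.0,
                "range": (0.0, 0.0),
            }
        raise DegenerateFitError("paired_t: zero-variance non-zero differences")
    res = sps.ttest_rel(a, b)
    return {
        "t": float(res.statistic),
        "df": int(len(d) - 1),
        "p": float(res.pvalue),
        "mean_difference": float(np.mean(d)),
        "sd_difference": sd,
        "range": (float(d.min()), float(d.max())),
    }


def independent_t(a, b, equal_var: bool = True) -> dict:
    """Two-sided independent-samples t-test (pooled variance by default;
    Welch with ``equal_var=False``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValidationError("independent_t needs two vectors of length >= 2")
    if np.std(a, ddof=1) < 1e-30 and np.std(b, ddof=1) < 1e-30:
        if abs(np.mean(a) - np.mean(b)) < 1e-30:
            return {"t": 0.0, "df": len(a) + len(b) - 2, "p": 1.0}
        raise DegenerateFitError("independent_t: zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def normality_check(x) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p). Requires 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ValidationError("normality_check requires a vector with 3 <= n <= 5000")
    if np.std(x) < 1e-30:
        raise DegenerateFitError("normality_check: constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def mean_abs_diff(a, b) -> float:
    """Mean absolute difference between paired measurements, degrees."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValidationError("mean_abs_diff needs two equal-length vectors")
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# method comparison report


def method_comparison_report(tables: dict, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise method comparisons on common subjects.

    ``tables`` maps method name -> measurement vector (aligned by subject).
    Each pair gets the average-measures absolute-agreement ICC (the model
    used for intermethod agreement), the paired t-test with mean difference
    +/- sd and range, the MAD, a Shapiro-Wilk check of the differences, and
    a significance flag at p <= alpha.
    """
    if len(tables) < 2:
        raise ValidationError("method_comparison_report needs >= 2 methods")
    names = list(tables)
    vectors = {m: np.asarray(v, dtype=float) for m, v in tables.items()}
    n = len(vectors[names[0]])
    if n < 2:
        raise ValidationError("method_comparison_report needs >= 2 common subjects")
    for m, v in vectors.items():
        if len(v) != n:
            raise ValidationError(f"method '{m}' has {len(v)} subjects, expected {n}")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = vectors[names[i]], vectors[names[j]]
            icc = icc_agreement_average(RaterTable(np.column_stack([a, b])))
            try:
                t = paired_t(a, b)
            except DegenerateFitError:
                t = {"t": np.nan, "p": np.nan, "mean_difference": float(np.mean(a - b)),
                     "sd_difference": 0.0, "range": (0.0, 0.0)}
            d = a - b
            try:
                _, p_norm = normality_check(d)
            except (ValidationError, DegenerateFitError):
                p_norm = np.nan
            rows.append(
                {
                    "method_a": names[i],
                    "method_b": names[j],
                    "n": n,
                    "icc_avg": icc.estimate,
                    "icc_ci_low": icc.ci_low,
                    "icc_ci_high": icc.ci_high,
                    "mean_a": float(np.mean(a)),
                    "mean_b": float(np.mean(b)),
                    "mean_difference": t["mean_difference"],
                    "sd_difference": t["sd_difference"],
                    "range_low": t["range"][0],
                    "range_high": t["range"][1],
                    "t": t["t"],
                    "p": t["p"],
                    "significant": bool(t["p"] <= alpha) if np.isfinite(t["p"]) else False,
                    "mad": mean_abs_diff(a, b),
                    "shapiro_p_diff": p_norm,
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "RaterTable",
    "ICCResult",
    "icc_agreement_single",
    "icc_agreement_average",
    "paired_t",
    "independent_t",
    "normality_check",
    "mean_abs_diff",
    "method_comparison_report",
]
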