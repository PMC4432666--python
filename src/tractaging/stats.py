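"""Longitudinal change statistics for tract mean FA and along-tract profiles.

The analysis follows the emulated study's scheme: per-subject annual
percentage FA change (each subject's own inter-scan interval), a single-pass
2.5-SD outlier exclusion on those rates, paired t-tests between two waves or
one-way repeated-measures ANOVA over three, Bonferroni-corrected alphas
(0.05/22 = 0.0023 for tract means, 0.05/100 = 0.0005 for the 100 along-tract
segments), and a Pearson correlation between baseline age and yearly change.
The mean percentage change is first calculated per subject and then averaged
over the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .core import InsufficientDataError, InvalidParameterError

Z_OUTLIER_DEFAULT = 2.5
MEAN_INTERVAL_YEARS = 3.6  # cohort-mean inter-wave interval, fallback only
ALPHA_DEFAULT = 0.05


def annual_pct_change(fa_a: float, fa_b: float, interval_years: float) -> float:
    """Percentage FA change per year: 100 * (fa_b - fa_a) / fa_a / interval."""
    fa_a = np.asarray(fa_a, dtype=float)
    interval = np.asarray(interval_years, dtype=float)
    if np.any(interval <= 0):
        raise InvalidParameterError("interval must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 100.0 * (np.asarray(fa_b, dtype=float) - fa_a) / fa_a / interval
    rate = np.where(fa_a > 0, rate, np.nan)
    return float(rate) if rate.ndim == 0 else rate


def exclude_outliers(values: np.ndarray, z_threshold: float = Z_OUTLIER_DEFAULT
                     ) -> tuple[np.ndarray, int]:
    """Single-pass z-score exclusion against the whole-sample variation.

    Returns (keep mask, M excluded).  SD uses the n-1 denominator; zero SD
    excludes nothing.  NaN values are excluded but not counted in M.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise InsufficientDataError("outlier rule needs >=3 values")
    mean = v[finite].mean()
    sd = v[finite].std(ddof=1)
    keep = finite.copy()
    if sd > 0:
        keep &= np.abs(v - mean) <= z_threshold * sd
    m = int(finite.sum() - (keep & finite).sum())
    return keep, m


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p: float
    degenerate: bool = False


def paired_t(x_w1: np.ndarray, x_w2: np.ndarray) -> TestResult:
    """Classical paired t-test on wave differences (pairwise deletion)."""
    a = np.asarray(x_w1, dtype=float)
    b = np.asarray(x_w2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        raise InsufficientDataError("paired t needs >=2 complete pairs")
    d = b - a
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return TestResult(0.0, (n - 1,), 1.0, degenerate=True)
        return TestResult(np.inf * np.sign(d.mean()), (n - 1,), 0.0, degenerate=True)
    t, p = sps.ttest_rel(b, a)
    return TestResult(float(t), (n - 1,), float(p))


def rm_anova(matrix: np.ndarray) -> TestResult:
    """One-way within-subject ANOVA on a subjects x waves matrix.

    Listwise deletion of incomplete rows; no sphericity correction;
    df1 = waves - 1, df2 = (waves - 1)(subjects - 1).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise InsufficientDataError("need a subjects x waves matrix with >=2 waves")
    m = m[np.all(np.isfinite(m), axis=1)]
    n_sub, n_wav = m.shape
    if n_sub < 3:
        raise InsufficientDataError("RM-ANOVA needs >=3 complete subjects")
    if np.allclose(m, m[:, [0]]):
        return TestResult(0.0, (n_wav - 1, (n_wav - 1) * (n_sub - 1)), 1.0,
                          degenerate=True)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_sub), n_wav),
            "wave": np.tile(np.arange(n_wav), n_sub),
            "fa": m.ravel(),
        }
    )
    res = AnovaRM(long, depvar="fa", subject="subject", within=["wave"]).fit()
    row = res.anova_table.iloc[0]
    return TestResult(float(row["F Value"]),
                      (float(row["Num DF"]), float(row["Den DF"])),
                      float(row["Pr > F"]))


def bonferroni_alpha(alpha: float = ALPHA_DEFAULT, m: int = 1) -> float:
    """Family-wise corrected alpha = alpha / m, reported to 4 decimals."""
    if m < 1:
        raise InvalidParameterError("number of comparisons must be >=1")
    return round(alpha / m, 4)


def pearson_age_change(age_w1: np.ndarray, yearly_change: np.ndarray) -> tuple[float, float]:
    """Pearson r between baseline age and yearly FA change, two-sided p."""
    a = np.asarray(age_w1, dtype=float)
    c = np.asarray(yearly_change, dtype=float)
    ok = np.isfinite(a) & np.isfinite(c)
    a, c = a[ok], c[ok]
    if a.size < 3:
        raise InsufficientDataError("Pearson correlation needs >=3 pairs")
    if np.std(a) == 0 or np.std(c) == 0:
        raise InvalidParameterError("zero variance in one variable")
    r, p = sps.pearsonr(a, c)
    return float(r), float(p)


@dataclass
class ChangeResult:
    """Per-connection longitudinal change summary (one table row)."""

    connection: str
    wave_mean: dict[int, float]
    wave_sd: dict[int, float]
    p: float
    n_used: int
    pct_change_per_year: float
    n_excluded: int
    significant: bool
    corrected_alpha: float

    def as_row(self) -> dict:
        row = {"connection": self.connection}
        for w in sorted(self.wave_mean):
            row[f"wave{w}_mean"] = self.wave_mean[w]
            row[f"wave{w}_sd"] = self.wave_sd[w]
        row.update(
            p_value=self.p, N=self.n_used,
            pct_change_per_year=self.pct_change_per_year, M=self.n_excluded,
            significant=self.significant, corrected_alpha=self.corrected_alpha,
        )
        return row


def _per_subject_rates(sub: pd.DataFrame, waves: list[int],
                       overall_rate: bool = False) -> float:
    """Annual % change for one subject across the requested waves.

    Two waves: the single-interval rate.  Three waves: mean of the two
    per-interval rates by default; `overall_rate=True` uses the wave-1 ->
    last-wave change over the total elapsed time instead.
    """
    sub = sub.set_index("wave")
    if overall_rate or len(waves) == 2:
        w0, w1 = waves[0], waves[-1]
        total = float(
            sum(sub.loc[w, "interval_years"] for w in waves[1:])
        )
        if total <= 0:
            total = MEAN_INTERVAL_YEARS * (len(waves) - 1)
        return annual_pct_change(sub.loc[w0, "fa"], sub.loc[w1, "fa"], total)
    rates = []
    for wa, wb in zip(waves[:-1], waves[1:]):
        iv = float(sub.loc[wb, "interval_years"])
        if not np.isfinite(iv) or iv <= 0:
            iv = MEAN_INTERVAL_YEARS
        rates.append(annual_pct_change(sub.loc[wa, "fa"], sub.loc[wb, "fa"], iv))
    return float(np.mean(rates))


def connection_change_table(
    cohort: pd.DataFrame,
    connections: list[str] | None = None,
    waves: list[int] | None = None,
    z_threshold: float = Z_OUTLIER_DEFAULT,
    n_comparisons: int | None = None,
    overall_rate: bool = False,
) -> list[ChangeResult]:
    """Per-connection longitudinal change statistics from a long cohort table.

    `cohort` columns: subject, wave, connection, fa, interval_years (years
    since previous wave; ignored/0 at wave 1), optionally age.

    Per connection: subjects with all requested waves are kept (pairwise for
    two waves, listwise for three); per-subject annual rates are screened by
    the z-score outlier rule; wave means/SDs, the paired t (2 waves) or
    RM-ANOVA (3 waves) p-value and the cohort mean rate are computed on the
    retained subjects.  Significance is flagged at alpha/m where m defaults
    to the number of tested connections.
    """
    if waves is None:
        waves = sorted(cohort["wave"].unique())
    if connections is None:
        connections = sorted(cohort["connection"].unique())
    m = n_comparisons if n_comparisons is not None else len(connections)
    alpha_c = bonferroni_alpha(ALPHA_DEFAULT, m)

    results = []
    for conn in connections:
        sub = cohort[(cohort["connection"] == conn) & (cohort["wave"].isin(waves))]
        if sub.empty:
            warnings.warn(f"connection {conn!r} absent from cohort; skipped",
                          stacklevel=2)
            continue
        counts = sub.groupby("subject")["wave"].nunique()
        complete = counts[counts == len(waves)].index
        sub = sub[sub["subject"].isin(complete)]
        if len(complete) < 3:
            warnings.warn(f"connection {conn!r}: <3 complete subjects; skipped",
                          stacklevel=2)
            continue
        rates = sub.groupby("subject", sort=True).apply(
            _per_subject_rates, waves=waves, overall_rate=overall_rate,
            include_groups=False,
        )
        keep_mask, n_excl = exclude_outliers(rates.to_numpy(), z_threshold)
        kept_subjects = rates.index[keep_mask]
        kept = sub[sub["subject"].isin(kept_subjects)]
        pivot = kept.pivot_table(index="subject", columns="wave", values="fa")
        pivot = pivot[waves]
        wave_mean = {w: float(pivot[w].mean()) for w in waves}
        wave_sd = {w: float(pivot[w].std(ddof=1)) for w in waves}
        if len(waves) == 2:
            res = paired_t(pivot[waves[0]].to_numpy(), pivot[waves[1]].to_numpy())
        else:
            res = rm_anova(pivot.to_numpy())
        pct = float(rates[keep_mask].mean())
        results.append(
            ChangeResult(
                connection=conn, wave_mean=wave_mean, wave_sd=wave_sd,
                p=res.p, n_used=int(len(kept_subjects)),
                pct_change_per_year=pct, n_excluded=n_excl,
                significant=bool(res.p < alpha_c), corrected_alpha=alpha_c,
            )
        )
    return results


def change_table_frame(results: list[ChangeResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


@dataclass
class SegmentTestResult:
    """Per-segment longitudinal test along a 100-segment tract profile."""

    mean_fa: dict[int, np.ndarray]  # wave -> (n_segments,)
    se: dict[int, np.ndarray]
    pct_change_per_year: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    corrected_alpha: float

    def to_frame(self) -> pd.DataFrame:
        n = self.p.shape[0]
        df = pd.DataFrame({"segment": np.arange(1, n + 1)})
        for w in sorted(self.mean_fa):
            df[f"wave{w}_mean"] = self.mean_fa[w]
            df[f"wave{w}_se"] = self.se[w]
        df["pct_change_per_year"] = self.pct_change_per_year
        df["p_value"] = self.p
        df["significant"] = self.significant
        return df


def segmentwise_longitudinal_test(
    profiles: np.ndarray,
    intervals: np.ndarray | None = None,
    waves: list[int] | None = None,
    n_comparisons: int | None = None,
) -> SegmentTestResult:
    """Segment-wise paired t (2 waves) or RM-ANOVA (3 waves) across subjects.

    `profiles` has shape (subjects, waves, segments): per-subject per-wave
    segment mean FA.  `intervals` (subjects, waves-1) are per-subject years
    between consecutive waves (default: the cohort mean 3.6).  Significance
    is flagged at alpha / n_segments (0.0005 for 100 segments).  Segments
    with any missing data are masked (NaN p, not significant).
    """
    prof = np.asarray(profiles, dtype=float)
    if prof.ndim != 3:
        raise InvalidParameterError("profiles must be (subjects, waves, segments)")
    n_sub, n_wav, n_seg = prof.shape
    if waves is None:
        waves = list(range(1, n_wav + 1))
    if intervals is None:
        intervals = np.full((n_sub, n_wav - 1), MEAN_INTERVAL_YEARS)
    intervals = np.asarray(intervals, dtype=float)
    m = n_comparisons if n_comparisons is not None else n_seg
    alpha_c = bonferroni_alpha(ALPHA_DEFAULT, m)

    mean_fa, se = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, w in enumerate(waves):
            mean_fa[w] = np.nanmean(prof[:, k, :], axis=0)
            cnt = np.sum(np.isfinite(prof[:, k, :]), axis=0)
            se[w] = np.where(
                cnt > 1,
                np.nanstd(prof[:, k, :], axis=0, ddof=1) / np.sqrt(np.maximum(cnt, 1)),
                0.0,
            )
        # per-subject per-segment annual rates, averaged over intervals then subjects
        seg_rates = []
        for k in range(n_wav - 1):
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (
                    100.0
                    * (prof[:, k + 1, :] - prof[:, k, :])
                    / prof[:, k, :]
                    / intervals[:, [k]]
                )
            seg_rates.append(r)
        pct = np.nanmean(np.nanmean(np.stack(seg_rates), axis=0), axis=0)

    p = np.full(n_seg, np.nan)
    for j in range(n_seg):
        col = prof[:, :, j]
        complete = col[np.all(np.isfinite(col), axis=1)]
        if complete.shape[0] < 3:
            continue
        try:
            if n_wav == 2:
                p[j] = paired_t(complete[:, 0], complete[:, 1]).p
            else:
                p[j] = rm_anova(complete).p
        except InsufficientDataError:
            continue
    significant = np.where(np.isfinite(p), p < alpha_c, False)
    return SegmentTestResult(mean_fa, se, pct, p, significant, alpha_c)
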