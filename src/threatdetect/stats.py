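"""Inferential toolkit: paired tests, 2x2 within-subject ANOVA, ART, effect sizes.

Conventions follow the study's analysis choices:

- Wilcoxon signed-rank tests drop zero differences, use mid-ranks for ties,
  and report a continuity-corrected normal-approximation Z (exact enumeration
  for small samples); the effect size is r = |Z| / sqrt(n) with n the number
  of pairs entered (including zeros).
- Paired t tests report Cohen's d for paired designs, d = t / sqrt(n).
- The 2x2 repeated-measures ANOVA reports F(1, n-1) per effect with partial
  eta squared F df1 / (F df1 + df2); for two-level factors each effect F is
  the square of the paired t on the corresponding within-subject contrast.
- The aligned-rank-transform (ART) ANOVA aligns the responses for one effect
  by removing the cell-mean estimates of all other effects, ranks the aligned
  values across the whole sample, and runs the parametric ANOVA on ranks.
- Effect-size confidence intervals use a subject-level percentile bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from threatdetect.errors import ContractError

TWO = "two"
GREATER = "greater"  # alternative: x tends to exceed y
LESS = "less"


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, effect size, optional CI."""

    __test__ = False  # not a pytest collectable

    test_name: str
    statistic: float
    statistic_label: str  # Z, t, F, rho, W
    df: tuple | None
    p_value: float
    tails: str
    effect_size: float
    effect_label: str  # r, d, partial_eta_sq, rho
    ci_level: float | None = None
    ci: tuple | None = None
    n: int = 0
    note: str = ""

    def to_row(self) -> dict:
        df1, df2 = (self.df if self.df is not None else (None, None))
        lo, hi = (self.ci if self.ci is not None else (None, None))
        return {
            "test_name": self.test_name,
            "statistic_label": self.statistic_label,
            "statistic": self.statistic,
            "df1": df1,
            "df2": df2,
            "p": self.p_value,
            "tails": self.tails,
            "effect_label": self.effect_label,
            "effect": self.effect_size,
            "ci_low": lo,
            "ci_high": hi,
            "ci_level": self.ci_level,
            "n": self.n,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# effect-size arithmetic
# ---------------------------------------------------------------------------

def effect_r_from_z(z: float, n: int) -> float:
    """Rank-correlation effect size r = |Z| / sqrt(n)."""
    if n < 1:
        raise ContractError("n must be at least 1")
    return abs(z) / np.sqrt(n)


def cohen_d_from_t(t: float, n: int) -> float:
    """Paired-design Cohen's d (difference-score SD units): t / sqrt(n)."""
    if n < 2:
        raise ContractError("n must be at least 2")
    return t / np.sqrt(n)


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F ratio: F df1 / (F df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ContractError("need F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(diffs))
    return float(ranks[diffs > 0].sum()), ranks


def _wilcoxon_exact_p(diffs: np.ndarray, tails: str) -> float:
    """Exact signed-rank p by enumerating all sign assignments (handles ties)."""
    w_obs, ranks = _signed_rank_statistic(diffs)
    n = len(ranks)
    masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    totals = masks @ ranks
    ge = float(np.mean(totals >= w_obs - 1e-12))
    le = float(np.mean(totals <= w_obs + 1e-12))
    if tails == GREATER:
        return ge
    if tails == LESS:
        return le
    return min(1.0, 2.0 * min(ge, le))


def wilcoxon_signed_rank(
    x,
    y,
    tails: str = TWO,
    method: str = "auto",
    ci_level: float | None = None,
    n_resamples: int = 2000,
    seed: int = 0,
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic policy); the reported statistic is
    the continuity-corrected normal-approximation Z.  ``method`` selects the
    p-value computation: ``"exact"`` enumerates all sign assignments,
    ``"approx"`` uses the normal approximation, ``"auto"`` picks exact for
    12 or fewer non-zero differences.  The effect size r = |Z| / sqrt(n)
    uses the number of pairs entered; its CI, when requested, is a
    subject-level percentile bootstrap.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be equal-length 1-D paired vectors")
    n_pairs = len(x)
    if n_pairs < 5:
        raise ContractError("need at least 5 pairs")
    diffs = x - y
    diffs = diffs[diffs != 0]
    nz = len(diffs)
    if nz == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, "Z", None, 1.0, tails, 0.0, "r",
            n=n_pairs, note="degenerate: all differences zero",
        )

    w_plus, ranks = _signed_rank_statistic(diffs)
    mu = nz * (nz + 1) / 4.0
    var = nz * (nz + 1) * (2 * nz + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sd = np.sqrt(var) if var > 0 else np.nan
    centred = w_plus - mu
    z = 0.0 if var <= 0 else (centred - 0.5 * np.sign(centred)) / sd

    if method == "auto":
        method = "exact" if nz <= 12 else "approx"
    if method == "exact":
        p = _wilcoxon_exact_p(diffs, tails)
    elif method == "approx":
        if tails == TWO:
            p = 2.0 * sps.norm.sf(abs(z))
        elif tails == GREATER:
            p = sps.norm.sf(z)
        else:
            p = sps.norm.cdf(z)
    else:
        raise ContractError(f"unknown method {method!r}")

    r = effect_r_from_z(z, n_pairs)
    ci = None
    if ci_level is not None:
        def stat(xb, yb):
            try:
                res = wilcoxon_signed_rank(xb, yb, tails=tails, method="approx")
            except ContractError:
                return 0.0
            return res.effect_size

        ci = bootstrap_ci((x, y), stat, level=ci_level, n_resamples=n_resamples, seed=seed)
    return TestResult(
        "wilcoxon_signed_rank", float(z), "Z", None, float(min(p, 1.0)), tails,
        float(r), "r", ci_level=ci_level, ci=ci, n=n_pairs,
    )


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

def paired_t(
    x,
    y,
    tails: str = TWO,
    ci_level: float | None = None,
    n_resamples: int = 2000,
    seed: int = 0,
) -> TestResult:
    """Classical paired t test with Cohen's d = t / sqrt(n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be equal-length 1-D paired vectors")
    n = len(x)
    if n < 3:
        raise ContractError("need at least 3 pairs")
    diffs = x - y
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise ContractError("zero variance of the paired differences")
    alternative = {TWO: "two-sided", GREATER: "greater", LESS: "less"}[tails]
    t, p = sps.ttest_rel(x, y, alternative=alternative)
    d = cohen_d_from_t(float(t), n)
    ci = None
    if ci_level is not None:
        def stat(xb, yb):
            db = xb - yb
            sd = db.std(ddof=1)
            return 0.0 if sd == 0 else float(db.mean() / sd)

        ci = bootstrap_ci((x, y), stat, level=ci_level, n_resamples=n_resamples, seed=seed)
    return TestResult(
        "paired_t", float(t), "t", (1, n - 1), float(p), tails, d, "d",
        ci_level=ci_level, ci=ci, n=n,
    )


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA and ART
# ---------------------------------------------------------------------------

def _pivot_2x2(
    data: pd.DataFrame, subject: str, factor_a: str, factor_b: str, value: str
) -> tuple[np.ndarray, list, list]:
    wide = data.pivot_table(index=subject, columns=[factor_a, factor_b], values=value)
    a_levels = sorted(data[factor_a].unique())
    b_levels = sorted(data[factor_b].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ContractError("both factors must have exactly 2 levels")
    try:
        wide = wide[[(a, b) for a in a_levels for b in b_levels]]
    except KeyError as err:
        raise ContractError(f"missing design cell: {err}") from err
    if wide.isna().any().any():
        raise ContractError("missing cells; impute or drop incomplete subjects first")
    return wide.to_numpy(), a_levels, b_levels


def rm_anova_2x2(
    data: pd.DataFrame,
    subject: str = "subject_id",
    factor_a: str = "A",
    factor_b: str = "B",
    value: str = "value",
) -> dict[str, TestResult]:
    """2x2 within-subject ANOVA from a long table; one result per effect.

    With 1 numerator df, each effect's F is the squared paired t on the
    corresponding within-subject contrast; partial eta squared is attached.
    """
    m, _, _ = _pivot_2x2(data, subject, factor_a, factor_b, value)
    n = m.shape[0]
    if n < 3:
        raise ContractError("need at least 3 complete subjects")
    x11, x12, x21, x22 = m.T
    contrasts = {
        factor_a: (x11 + x12 - x21 - x22) / 2.0,
        factor_b: (x11 - x12 + x21 - x22) / 2.0,
        f"{factor_a} x {factor_b}": (x11 - x12 - x21 + x22) / 2.0,
    }
    out = {}
    for name, contrast in contrasts.items():
        sd = contrast.std(ddof=1)
        if sd == 0:
            F, p = 0.0 if np.allclose(contrast.mean(), 0) else np.inf, np.nan
        else:
            t = contrast.mean() / (sd / np.sqrt(n))
            F = float(t**2)
            p = float(sps.f.sf(F, 1, n - 1))
        out[name] = TestResult(
            f"rm_anova[{name}]", F, "F", (1, n - 1), p, TWO,
            partial_eta_sq(F, 1, n - 1) if np.isfinite(F) else 1.0, "partial_eta_sq", n=n,
        )
    return out


def align_responses(
    data: pd.DataFrame,
    effect: str,
    subject: str = "subject_id",
    factor_a: str = "A",
    factor_b: str = "B",
    value: str = "value",
) -> pd.Series:
    """Aligned responses for one effect ("A", "B" or "AxB") via cell means."""
    d = data.copy()
    cell = d.groupby([factor_a, factor_b])[value].transform("mean")
    mean_a = d.groupby(factor_a)[value].transform("mean")
    mean_b = d.groupby(factor_b)[value].transform("mean")
    grand = d[value].mean()
    resid = d[value] - cell
    if effect == "A":
        return resid + mean_a - grand
    if effect == "B":
        return resid + mean_b - grand
    if effect == "AxB":
        return resid + cell - mean_a - mean_b + grand
    raise ContractError(f"unknown effect {effect!r}")


def art_anova_2x2(
    data: pd.DataFrame,
    subject: str = "subject_id",
    factor_a: str = "A",
    factor_b: str = "B",
    value: str = "value",
) -> dict[str, TestResult]:
    """Aligned-rank-transform factorial ANOVA for a 2x2 within-subject design.

    For each effect, responses are aligned (all other estimated effects
    removed), ranked across the entire sample with mid-ranks, and submitted
    to the parametric 2x2 ANOVA; only the effect the data were aligned for
    is interpreted from each pass.
    """
    keys = {"A": factor_a, "B": factor_b, "AxB": f"{factor_a} x {factor_b}"}
    out = {}
    for effect, key in keys.items():
        d = data.copy()
        aligned = align_responses(d, effect, subject, factor_a, factor_b, value)
        d["_rank"] = sps.rankdata(aligned)
        res = rm_anova_2x2(d, subject, factor_a, factor_b, "_rank")[key]
        res.test_name = f"art_anova[{key}]"
        out[key] = res
    return out


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x, y, ci_level: float | None = None, n_resamples: int = 2000, seed: int = 0) -> TestResult:
    """Spearman rank-order correlation (mid-ranks for ties), rho(df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ContractError("x and y must be equal-length 1-D vectors of length >= 4")
    n = len(x)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return TestResult(
            "spearman", float("nan"), "rho", (n - 2, None), float("nan"), TWO,
            float("nan"), "rho", n=n, note="degenerate: constant input",
        )
    rho, p = sps.spearmanr(x, y)
    ci = None
    if ci_level is not None:
        def stat(xb, yb):
            if np.allclose(xb, xb[0]) or np.allclose(yb, yb[0]):
                return 0.0
            return float(sps.spearmanr(xb, yb)[0])

        ci = bootstrap_ci((x, y), stat, level=ci_level, n_resamples=n_resamples, seed=seed)
    return TestResult(
        "spearman", float(rho), "rho", (n - 2, None), float(p), TWO, float(rho), "rho",
        ci_level=ci_level, ci=ci, n=n,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    data,
    statistic,
    level: float = 0.95,
    n_resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Subject-level percentile bootstrap interval for an effect-size statistic.

    ``data`` is one array or a tuple of equal-length arrays resampled jointly
    (paired designs); ``statistic`` receives the resampled array(s) and
    returns a scalar.  Deterministic for a given seed.  A statistic that is
    constant across all resamples yields a zero-width interval with a warning.
    """
    if not 0.0 < level < 1.0:
        raise ContractError("level must lie in (0, 1)")
    arrays = data if isinstance(data, tuple) else (np.asarray(data, float),)
    arrays = tuple(np.asarray(a, float) for a in arrays)
    n = len(arrays[0])
    if n < 5:
        raise ContractError("need at least 5 subjects to bootstrap")
    if any(len(a) != n for a in arrays):
        raise ContractError("all arrays must have equal length")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        estimates[b] = statistic(*(a[idx] for a in arrays))
    if np.allclose(estimates, estimates[0]):
        warnings.warn("degenerate bootstrap: statistic constant across resamples", stacklevel=2)
        return (float(estimates[0]), float(estimates[0]))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))
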