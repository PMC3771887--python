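"""Behavioral boundary-extension diagnostics.

Ratings on the raw 1-5 scale ("Much closer" ... "Much farther") are recoded to
a signed scale s = raw - 3, so negative means "closer".  Boundary extension on
identical pairs (CC, WW) predicts negative mean ratings: the second, identical
view is judged closer than the remembered (boundary-extended) first view.  The
critical diagnostic is the mismatch asymmetry: ratings on WC trials are larger
in magnitude than on CW trials, tested by a paired t of (-1 x WC) against CW
per-subject means.  Response-time ANOVAs collapse the sparse extreme
categories (raw 1-2 -> "closer", 4-5 -> "wider"; confidence 1-2 -> low,
4-5 -> high) and exclude subjects with empty design cells listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS
from .roi_stats import AnovaResult, rm_anova_two_way

RATING_CATEGORIES: tuple[str, ...] = ("closer", "same", "wider")
CONFIDENCE_LEVELS: tuple[str, ...] = ("low", "medium", "high")


def recode_ratings(behavior: pd.DataFrame) -> pd.DataFrame:
    """Add signed ratings and collapsed categories to a behavioral table.

    Columns added: ``rating_signed`` (raw - 3, in {-2..+2}), ``category``
    ("closer"/"same"/"wider", collapsing raw {1,2} and {4,5}), and
    ``confidence_level`` ("low"/"medium"/"high", same collapsing).  Errors on
    out-of-range ratings (including already-recoded input).
    """
    for col in ("rating", "confidence"):
        vals = behavior[col].to_numpy()
        if not np.isin(vals, [1, 2, 3, 4, 5]).all():
            raise ValueError(f"{col} values must be raw 1-5 responses")
    out = behavior.copy()
    s = out["rating"].to_numpy(int) - 3
    out["rating_signed"] = s
    out["category"] = np.where(s < 0, "closer", np.where(s > 0, "wider", "same"))
    c = out["confidence"].to_numpy(int)
    out["confidence_level"] = np.where(c <= 2, "low",
                                       np.where(c == 3, "medium", "high"))
    return out


@dataclass(frozen=True)
class BeTestResult:
    """One-sample boundary-extension t-test on per-subject mean ratings."""

    condition: str
    mean: float
    sd: float
    t: float
    df: int
    p: float
    cohen_d: float
    scope: str  # "all" | "block1"
    n_subjects: int


def _subject_means(recoded: pd.DataFrame, condition: str,
                   scope: str) -> np.ndarray:
    df = recoded[recoded["condition"] == condition]
    if scope == "block1":
        df = df[df["block"] == 1]
    elif scope != "all":
        raise ValueError("scope must be 'all' or 'block1'")
    return df.groupby("subject")["rating_signed"].mean().to_numpy()


def _onesample(x: np.ndarray) -> tuple[float, float, float, int, float, float]:
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    t = mean / (sd / np.sqrt(n)) if sd > 0 else (0.0 if mean == 0 else np.inf)
    p = float(2 * stats.t.sf(abs(t), n - 1)) if np.isfinite(t) else 0.0
    d = mean / sd if sd > 0 else 0.0
    return mean, sd, t, n - 1, p, d


def be_onesample_tests(recoded: pd.DataFrame, scope: str = "all",
                       conditions: tuple[str, ...] = ("CC", "WW")
                       ) -> list[BeTestResult]:
    """Test per-subject mean recoded ratings of identical pairs against 0.

    Boundary extension predicts negative means (test picture judged closer
    than the remembered first view).  Cohen's d = mean / sd of the
    per-subject means.
    """
    results = []
    for cond in conditions:
        x = _subject_means(recoded, cond, scope)
        mean, sd, t, df, p, d = _onesample(x)
        results.append(BeTestResult(cond, mean, sd, t, df, p, d, scope, len(x)))
    return results


@dataclass(frozen=True)
class AsymmetryResult:
    """Paired t of (-1 x WC) vs CW per-subject mean ratings."""

    mean_neg_wc: float
    mean_cw: float
    t: float
    df: int
    p: float
    cohen_d: float
    larger_magnitude: str  # "WC" | "CW" | "equal"
    n_subjects: int


def asymmetry_test(recoded: pd.DataFrame) -> AsymmetryResult:
    """Mismatch-asymmetry diagnostic: |WC ratings| vs |CW ratings|.

    WC per-subject means are multiplied by -1 (they are negative under BE) and
    compared to the CW means with a paired t-test; a positive t means the WC
    magnitude is larger.
    """
    wc = _subject_means(recoded, "WC", "all")
    cw = _subject_means(recoded, "CW", "all")
    if len(wc) != len(cw):
        raise ValueError("WC and CW must cover the same subjects")
    diff = -wc - cw
    mean, sd, t, df, p, d = _onesample(diff)
    larger = "WC" if mean > 0 else ("CW" if mean < 0 else "equal")
    return AsymmetryResult(float((-wc).mean()), float(cw.mean()), t, df, p, d,
                           larger, len(wc))


@dataclass
class RtAnovaResult:
    anova: AnovaResult
    n_subjects_used: int
    n_subjects_excluded: int
    excluded_subjects: tuple


def _rt_anova(recoded: pd.DataFrame, rt_col: str, cat_col: str,
              cat_levels: tuple[str, ...], alpha: float) -> RtAnovaResult:
    per = (recoded.groupby(["subject", cat_col, "condition"], observed=True)[rt_col]
           .mean().reset_index())
    n_cells = len(cat_levels) * len(CONDITIONS)
    counts = per.groupby("subject").size()
    complete = counts[counts == n_cells].index
    excluded = tuple(sorted(set(counts.index) - set(complete)))
    if len(complete) < 2:
        raise ValueError("fewer than 2 subjects with complete RT cells")
    use = per[per["subject"].isin(complete)]
    res = rm_anova_two_way(use, value=rt_col, factor_a=cat_col,
                           factor_b="condition", levels_a=cat_levels,
                           levels_b=CONDITIONS, alpha=alpha)
    return RtAnovaResult(res, len(complete), len(excluded), excluded)


def rt_anovas(recoded: pd.DataFrame, alpha: float = 0.05
              ) -> tuple[RtAnovaResult, RtAnovaResult]:
    """RT ANOVAs: (a) camera-angle category (3) x type (4) on rating RTs;
    (b) confidence level (3) x type (4) on confidence RTs.

    Subjects with any empty cell are excluded listwise; the exclusion count is
    reported in the result.
    """
    a = _rt_anova(recoded, "rt_rating_ms", "category", RATING_CATEGORIES, alpha)
    b = _rt_anova(recoded, "rt_conf_ms", "confidence_level", CONFIDENCE_LEVELS,
                  alpha)
    return a, b
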