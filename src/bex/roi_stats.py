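"""P3b ROI analysis and repeated-measures ANOVA machinery.

Mean amplitudes over 500-560 ms in three centro-parietal ROIs (left {CP1,P1},
middle {CPz,Pz}, right {CP2,P2}) enter a two-way within-subject ANOVA with
factors pair type (CC/WW/CW/WC) x laterality (left/middle/right).

The ANOVA uses the classical within-subject sums-of-squares decomposition:
each effect is tested against its own subject-by-effect interaction term.
Sphericity violations are handled with the Greenhouse-Geisser epsilon,
computed per effect by Box's formula from the covariance of the effect's
orthonormalized contrasts; corrected p-values evaluate F at (eps*df1,
eps*df2).  Effect size is partial eta squared, SS_effect / (SS_effect +
SS_error).  Post-hoc pairwise comparisons use Tukey's HSD with the tested
effect's own error mean square and studentized-range p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import CONDITIONS
from .epochs import SubjectERP
from .montage import ROIS

P3B_WINDOW_MS: tuple[float, float] = (500.0, 560.0)


# ---------------------------------------------------------------------------
# ROI amplitudes
# ---------------------------------------------------------------------------

def roi_mean_amplitude(erps: list[SubjectERP],
                       window_ms: tuple[float, float] = P3B_WINDOW_MS,
                       rois: dict[str, tuple[str, ...]] | None = None
                       ) -> pd.DataFrame:
    """Tidy table (subject, condition, roi, amplitude): mean over the ROI's
    channels and the window's samples, endpoints inclusive."""
    if rois is None:
        rois = ROIS
    rows = []
    for erp in erps:
        tmask = (erp.times >= window_ms[0]) & (erp.times <= window_ms[1])
        if not tmask.any():
            raise ValueError(f"window {window_ms} outside the time axis")
        for roi, chans in rois.items():
            idx = [erp.channel_index(c) for c in chans]
            for cond, arr in erp.data.items():
                rows.append((erp.subject, cond, roi,
                             float(arr[np.ix_(idx, np.flatnonzero(tmask))].mean())))
    return pd.DataFrame(rows, columns=["subject", "condition", "roi", "amplitude"])


def _pivot(table: pd.DataFrame, value: str, factor_a: str, factor_b: str | None,
           levels_a, levels_b=None) -> np.ndarray:
    """Tidy table -> complete (n_subjects, a[, b]) array; errors on missing
    or duplicated cells."""
    cols = ["subject", factor_a] + ([factor_b] if factor_b else [])
    wide = table.pivot_table(index="subject", columns=cols[1:], values=value,
                             aggfunc="mean")
    subjects = wide.index.to_numpy()
    if factor_b:
        try:
            wide = wide.reindex(columns=pd.MultiIndex.from_product(
                [levels_a, levels_b]))
        except Exception as e:  # pragma: no cover
            raise ValueError(f"incomplete table: {e}") from e
        arr = wide.to_numpy().reshape(len(subjects), len(levels_a), len(levels_b))
    else:
        arr = wide.reindex(columns=list(levels_a)).to_numpy()
    if np.isnan(arr).any():
        raise ValueError("incomplete table: missing cells")
    return arr


# ---------------------------------------------------------------------------
# Core within-subject ANOVA
# ---------------------------------------------------------------------------

def _gg_epsilon(scores: np.ndarray) -> float:
    """Box's Greenhouse-Geisser epsilon from subject x contrast scores."""
    k = scores.shape[1]
    if k <= 1:
        return 1.0
    s = np.cov(scores, rowvar=False)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    denom = k * np.trace(s @ s)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr ** 2 / denom))


def _contrasts(k: int) -> np.ndarray:
    """Orthonormal basis of the contrast space (k x (k-1))."""
    return linalg.null_space(np.ones((1, k)))


@dataclass
class AnovaResult:
    """Effect table plus post-hoc comparisons.

    ``anova`` rows: effect, F, df1, df2, eps, p_uncorrected, p_gg,
    partial_eta_sq.  ``posthoc`` maps effect name -> pairwise table.
    """

    anova: pd.DataFrame
    posthoc: dict[str, pd.DataFrame]
    levels: dict[str, tuple]
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        return self.anova.set_index("effect").loc[name]


def _anova_two_way_array(y: np.ndarray, name_a: str, name_b: str,
                         levels_a, levels_b, alpha: float = 0.05,
                         posthoc: bool = True) -> AnovaResult:
    """Two-way fully within-subject ANOVA on a complete (n, a, b) array."""
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * ((m_a - g) ** 2).sum()
    ss_b = n * a * ((m_b - g) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2).sum()
    ss_s = a * b * ((m_s - g) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2).sum()
    ss_tot = ((y - g) ** 2).sum()
    ss_sab = max(ss_tot - (ss_a + ss_b + ss_ab + ss_s + ss_sa + ss_sb), 0.0)
    # sums of squares at the float-rounding scale of the data are exact zeros
    ss_floor = 1e-24 * y.size * max(float(np.abs(y).max()) ** 2, 1e-300)

    ca, cb = _contrasts(a), _contrasts(b)
    eff = {
        name_a: (ss_a, a - 1, ss_sa, (a - 1) * (n - 1),
                 y.mean(axis=2) @ ca),
        name_b: (ss_b, b - 1, ss_sb, (b - 1) * (n - 1),
                 y.mean(axis=1) @ cb),
        f"{name_a}:{name_b}": (ss_ab, (a - 1) * (b - 1), ss_sab,
                               (a - 1) * (b - 1) * (n - 1),
                               y.reshape(n, a * b) @ np.kron(ca, cb)),
    }
    rows = []
    for name, (ss_e, df1, ss_err, df2, scores) in eff.items():
        ss_e = 0.0 if ss_e < ss_floor else ss_e
        ss_err = 0.0 if ss_err < ss_floor else ss_err
        ms_e, ms_err = ss_e / df1, ss_err / df2
        f_val = ms_e / ms_err if ms_err > 0 else (0.0 if ms_e == 0 else np.inf)
        eps = _gg_epsilon(scores)
        rows.append({
            "effect": name, "F": f_val, "df1": df1, "df2": df2, "eps": eps,
            "p_uncorrected": float(stats.f.sf(f_val, df1, df2)),
            "p_gg": float(stats.f.sf(f_val, eps * df1, eps * df2)),
            "partial_eta_sq": ss_e / (ss_e + ss_err) if ss_e + ss_err > 0 else 0.0,
            "ss_effect": ss_e, "ss_error": ss_err,
        })
    table = pd.DataFrame(rows)

    if not posthoc:
        return AnovaResult(anova=table, posthoc={},
                           levels={name_a: tuple(levels_a),
                                   name_b: tuple(levels_b)}, n_subjects=n)
    posthoc = {
        name_a: _tukey(y.mean(axis=2), levels_a,
                       ms_err=table.loc[0, "ss_error"] / table.loc[0, "df2"] / b,
                       df_err=int(table.loc[0, "df2"]), n_per_mean=n, alpha=alpha),
        name_b: _tukey(y.mean(axis=1), levels_b,
                       ms_err=table.loc[1, "ss_error"] / table.loc[1, "df2"] / a,
                       df_err=int(table.loc[1, "df2"]), n_per_mean=n, alpha=alpha),
        f"{name_a}:{name_b}": _tukey_cells(y, levels_a, levels_b,
                                           ms_err=ss_sab / ((a - 1) * (b - 1) * (n - 1)),
                                           df_err=(a - 1) * (b - 1) * (n - 1),
                                           alpha=alpha),
    }
    return AnovaResult(anova=table, posthoc=posthoc,
                       levels={name_a: tuple(levels_a), name_b: tuple(levels_b)},
                       n_subjects=n)


def _tukey(scores: np.ndarray, levels, ms_err: float, df_err: int,
           n_per_mean: int, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over level means of subject x level scores.

    ``ms_err`` must already be on the scale of the supplied scores (i.e. the
    effect's interaction MS divided by the number of collapsed levels)."""
    means = scores.mean(axis=0)
    k = len(levels)
    se = np.sqrt(max(ms_err, 0.0) / n_per_mean)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(stats.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        rows.append({"level_a": levels[i], "level_b": levels[j],
                     "mean_a": means[i], "mean_b": means[j],
                     "mean_diff": diff, "q": q, "p": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows)


def _tukey_cells(y: np.ndarray, levels_a, levels_b, ms_err: float,
                 df_err: int, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over all a x b cell means, using the interaction error MS."""
    n, a, b = y.shape
    cells = [(la, lb) for la in levels_a for lb in levels_b]
    means = y.mean(axis=0).reshape(-1)
    se = np.sqrt(max(ms_err, 0.0) / n)
    rows = []
    for i, j in combinations(range(len(cells)), 2):
        diff = means[i] - means[j]
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(stats.studentized_range.sf(q, len(cells), df_err)) \
            if np.isfinite(q) else 0.0
        rows.append({"cell_a": "/".join(map(str, cells[i])),
                     "cell_b": "/".join(map(str, cells[j])),
                     "mean_diff": diff, "q": q, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def rm_anova_two_way(table: pd.DataFrame, value: str = "amplitude",
                     factor_a: str = "condition", factor_b: str = "roi",
                     levels_a=CONDITIONS, levels_b=("left", "middle", "right"),
                     alpha: float = 0.05, posthoc: bool = True) -> AnovaResult:
    """Two-way within-subject ANOVA from a tidy complete balanced table."""
    y = _pivot(table, value, factor_a, factor_b, levels_a, levels_b)
    return _anova_two_way_array(y, factor_a, factor_b, levels_a, levels_b, alpha,
                                posthoc=posthoc)


def rm_anova_one_way(table: pd.DataFrame, value: str, factor: str,
                     levels, alpha: float = 0.05) -> AnovaResult:
    """One-way within-subject ANOVA (Greenhouse-Geisser corrected) + Tukey."""
    y = _pivot(table, value, factor, None, levels)
    n, k = y.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    g = y.mean()
    m_l = y.mean(axis=0)
    m_s = y.mean(axis=1)
    ss_eff = n * ((m_l - g) ** 2).sum()
    ss_err = ((y - m_s[:, None] - m_l[None, :] + g) ** 2).sum()
    ss_floor = 1e-24 * y.size * max(float(np.abs(y).max()) ** 2, 1e-300)
    ss_eff = 0.0 if ss_eff < ss_floor else ss_eff
    ss_err = 0.0 if ss_err < ss_floor else ss_err
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_e, ms_err = ss_eff / df1, ss_err / df2
    f_val = ms_e / ms_err if ms_err > 0 else (0.0 if ms_e == 0 else np.inf)
    eps = _gg_epsilon(y @ _contrasts(k))
    table_out = pd.DataFrame([{
        "effect": factor, "F": f_val, "df1": df1, "df2": df2, "eps": eps,
        "p_uncorrected": float(stats.f.sf(f_val, df1, df2)),
        "p_gg": float(stats.f.sf(f_val, eps * df1, eps * df2)),
        "partial_eta_sq": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
        "ss_effect": ss_eff, "ss_error": ss_err,
    }])
    posthoc = {factor: _tukey(y, list(levels), ms_err=ms_err, df_err=df2,
                              n_per_mean=n, alpha=alpha)}
    return AnovaResult(anova=table_out, posthoc=posthoc,
                       levels={factor: tuple(levels)}, n_subjects=n)


def tukey_hsd(table: pd.DataFrame, value: str = "amplitude",
              effect: str = "condition", levels=CONDITIONS,
              other: str | None = "roi", alpha: float = 0.05) -> pd.DataFrame:
    """Stand-alone Tukey HSD for one within-subject effect.

    Collapses over ``other`` (if given), then compares all level pairs with
    the effect's own subject-by-effect error term."""
    work = (table.groupby(["subject", effect], observed=True)[value]
            .mean().reset_index()) if other else table
    y = _pivot(work, value, effect, None, levels)
    n, k = y.shape
    m_l, m_s, g = y.mean(axis=0), y.mean(axis=1), y.mean()
    ss_err = ((y - m_s[:, None] - m_l[None, :] + g) ** 2).sum()
    df2 = (k - 1) * (n - 1)
    return _tukey(y, list(levels), ms_err=ss_err / df2, df_err=df2,
                  n_per_mean=n, alpha=alpha)


def confidence_anova(behavior: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """One-way RM ANOVA of per-subject mean confidence across pair types."""
    per = (behavior.groupby(["subject", "condition"], observed=True)["confidence"]
           .mean().reset_index())
    missing = set(CONDITIONS) - set(per["condition"])
    if missing:
        raise ValueError(f"missing conditions {sorted(missing)}")
    return rm_anova_one_way(per, "confidence", "condition", CONDITIONS, alpha)
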