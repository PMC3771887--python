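"""Repeated-measures two-tailed tmax permutation test over channel x time
families.

For a paired two-condition contrast, each subject contributes a difference
wave (condition A - condition B).  Under the null the sign of every subject's
whole wave is exchangeable, so the permutation distribution is generated by
independent whole-wave sign flips.  Each permutation records the maximum
absolute paired t over the family; the family-wise critical value is an order
statistic of that null maximum distribution, with the observed statistic
counted as one member of the reference set so the test is exact-level and
p >= 1/n_perm.  Because sign flips leave each cell's sum of squared
differences unchanged, the whole permutation scheme reduces to one matrix
product of the sign matrix with the subject-by-cell difference matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import SubjectERP

_BIG_T = 1e12  # sentinel magnitude for zero-variance cells


@dataclass
class DifferenceSet:
    """Per-subject difference waves for a paired contrast."""

    data: np.ndarray           # (n_subjects, n_channels, n_times), microvolts
    ch_names: tuple[str, ...]
    times: np.ndarray          # ms
    cond_a: str = "A"
    cond_b: str = "B"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (subjects, channels, times)")
        n, c, t = self.data.shape
        if n < 2:
            raise ValueError("need >= 2 subjects")
        if c != len(self.ch_names) or t != len(self.times):
            raise ValueError("metadata does not match data shape")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


def build_difference_set(erps: list[SubjectERP], cond_a: str, cond_b: str,
                         window_ms: tuple[float, float] = (100.0, 600.0)
                         ) -> DifferenceSet:
    """Stack per-subject (A - B) difference waves restricted to the analysis
    window (inclusive endpoints)."""
    ref = erps[0]
    mask = (ref.times >= window_ms[0]) & (ref.times <= window_ms[1])
    waves = []
    for erp in erps:
        if tuple(erp.ch_names) != tuple(ref.ch_names):
            raise ValueError("subjects have mismatched channel sets")
        waves.append(erp.data[cond_a][:, mask] - erp.data[cond_b][:, mask])
    return DifferenceSet(np.stack(waves), tuple(ref.ch_names), ref.times[mask],
                         cond_a, cond_b)


@dataclass
class MassUniResult:
    t_obs: np.ndarray          # (channels, times)
    df: int
    null_maxt: np.ndarray      # (n_perm,), observed included
    t_crit: float
    alpha_fw: float
    alpha_testwise: float
    p: np.ndarray              # (channels, times) permutation p-values
    mask: np.ndarray           # significance raster, |t_obs| >= t_crit
    ch_names: tuple[str, ...]
    times: np.ndarray
    cond_a: str = "A"
    cond_b: str = "B"
    n_perm: int = 0
    seed: int | None = None


def _t_from_signs(signs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Paired t per cell for each sign assignment.

    signs: (n_perm, n_subjects) in {-1, +1}; d: (n_subjects, n_cells).
    Sign flips leave sum(d^2) per cell invariant, so only the mean moves.
    """
    n = d.shape[0]
    ss = (d ** 2).sum(axis=0)                      # (cells,)
    m = signs @ d / n                              # (n_perm, cells)
    var = (ss[None, :] - n * m ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    zero_var = var <= (np.maximum(ss[None, :], 1.0) * 1e-30)
    if zero_var.any():
        t = np.where(zero_var & (m != 0), np.sign(m) * _BIG_T, t)
        t = np.where(zero_var & (m == 0), 0.0, t)
    return t


def compute_paired_t(diffs: DifferenceSet) -> tuple[np.ndarray, int]:
    """Observed paired t matrix (sample sd, n-1 denominator) and df = n-1.

    Zero-variance cells with a nonzero mean yield a +/-inf-like sentinel and a
    warning; the permutation ranking handles them gracefully.
    """
    n = diffs.n_subjects
    d = diffs.data.reshape(n, -1)
    t = _t_from_signs(np.ones((1, n)), d)[0]
    if np.any(np.abs(t) >= _BIG_T):
        warnings.warn("zero-variance cells: t reported as a +/-inf sentinel",
                      RuntimeWarning, stacklevel=2)
    return t.reshape(diffs.data.shape[1:]), n - 1


def testwise_alpha_from_critical_t(t_crit: float, df: int) -> float:
    """Two-tailed tail probability of the central t distribution at t_crit."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t_crit), df))


def tmax_permutation(diffs: DifferenceSet, n_perm: int = 2500,
                     alpha: float = 0.05, seed: int | None = None,
                     exhaustive: bool = False) -> MassUniResult:
    """Family-wise-corrected paired test via the tmax permutation distribution.

    Parameters
    ----------
    n_perm : total size of the reference set, observed assignment included
        (ignored when ``exhaustive``); must be >= 100.
    exhaustive : enumerate all 2**n sign assignments instead of sampling
        (exact test; n must be small).
    """
    n = diffs.n_subjects
    if n < 2:
        raise ValueError("need >= 2 subjects")
    d = diffs.data.reshape(n, -1)
    if d.shape[1] == 0:
        raise ValueError("empty comparison family")
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20")
        n_perm = 2 ** n
        bits = np.arange(n_perm)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        # bits == 0 -> all +1: the observed assignment is row 0
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if n <= 30 and n_perm > 2 ** n:
            raise ValueError(f"n_perm={n_perm} exceeds the 2^{n} distinct sign "
                             "assignments; use exhaustive mode")
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n))
        signs[0] = 1  # the observed assignment is one member of the reference set
    t_all = _t_from_signs(signs, d)
    # take the observed t from the batch itself (row 0 is the identity
    # assignment) so that it ties with its own reference-set entry bitwise
    t_obs = t_all[0]
    null_maxt = np.abs(t_all).max(axis=1)
    # Order-statistic critical value: ceil((1-alpha) * n_perm)-th smallest.
    k = int(np.ceil((1.0 - alpha) * n_perm))
    t_crit = float(np.sort(null_maxt)[k - 1])
    p = (null_maxt[:, None] >= np.abs(t_obs)[None, :]).mean(axis=0)
    # p <= alpha guards the degenerate all-tie case (e.g. identical
    # conditions, where t_crit = 0 and every cell trivially reaches it)
    mask = (np.abs(t_obs) >= t_crit) & (p <= alpha)
    shape = diffs.data.shape[1:]
    return MassUniResult(
        t_obs=t_obs.reshape(shape), df=n - 1, null_maxt=null_maxt,
        t_crit=t_crit, alpha_fw=alpha,
        alpha_testwise=testwise_alpha_from_critical_t(t_crit, n - 1),
        p=p.reshape(shape), mask=mask.reshape(shape),
        ch_names=diffs.ch_names, times=diffs.times,
        cond_a=diffs.cond_a, cond_b=diffs.cond_b,
        n_perm=n_perm, seed=seed)


def significance_raster(result: MassUniResult) -> pd.DataFrame:
    """Merge contiguous significant timepoints into per-electrode intervals.

    Returns a table (electrode, t_start_ms, t_end_ms, direction) with
    direction "positive" (A > B) or "negative" (A < B); runs of mixed sign are
    split at the sign change.
    """
    rows = []
    for ci, name in enumerate(result.ch_names):
        sig = result.mask[ci]
        sign = np.sign(result.t_obs[ci])
        start = None
        for j in range(len(sig) + 1):
            here = sig[j] if j < len(sig) else False
            if here and start is None:
                start = j
            elif start is not None and (not here or sign[j] != sign[start]):
                rows.append((name, float(result.times[start]),
                             float(result.times[j - 1]),
                             "positive" if sign[start] > 0 else "negative"))
                start = j if here else None
    return pd.DataFrame(rows, columns=["electrode", "t_start_ms", "t_end_ms",
                                       "direction"])


def simulate_null_fwer(n_experiments: int, n_subjects: int, ch_names,
                       distances: np.ndarray, n_times: int,
                       spatial_scale: float = 0.4, n_perm: int = 500,
                       alpha: float = 0.05, seed: int | None = None) -> float:
    """Empirical family-wise error rate under a global null.

    Simulates spatially correlated Gaussian difference waves with zero mean
    (squared-exponential kernel over the given channel distances, independent
    timepoints) and reports the fraction of experiments whose significance
    mask is non-empty.
    """
    kern = np.exp(-distances ** 2 / (2.0 * spatial_scale ** 2))
    chol = np.linalg.cholesky(kern + 1e-9 * np.eye(len(kern)))
    root = np.random.SeedSequence(seed)
    times = 10.0 * np.arange(n_times)
    hits = 0
    for ss in root.spawn(n_experiments):
        rng = np.random.default_rng(ss)
        white = rng.standard_normal((n_subjects, len(kern), n_times))
        d = np.einsum("ij,sjt->sit", chol, white)
        ds = DifferenceSet(d, tuple(ch_names), times)
        res = tmax_permutation(ds, n_perm=n_perm, alpha=alpha,
                               seed=int(rng.integers(2 ** 31)))
        hits += bool(res.mask.any())
    return hits / n_experiments
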