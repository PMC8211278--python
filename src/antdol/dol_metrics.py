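"""Individual- and colony-level division-of-labor summaries.

Three colony-level quantities summarize a simulation:

* mean behavior — the average task performance frequency (fraction of steps
  spent on a task) across colony members;
* behavioral variation — the standard deviation of task performance frequency
  across colony members (the "who does how much" component of DOL);
* specialization — the mean Spearman rank correlation of individuals'
  within-window task performance between consecutive time windows (the
  temporal-consistency component of DOL).

The mixing-effect statistic compares the between-type behavioral gap within
mixed colonies with the gap across pure colonies:

    effect = (Y_m - X_m) - (Y_p - X_p),

with Y the type with the higher mean behavior in pure colonies.  A
significantly negative effect is behavioral convergence, a significantly
positive one divergence, a non-rejection no effect; if the ordering
assumption Y_m > X_m fails the outcome is labelled "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from antdol.threshold_model import BatchResult, SimResult

__all__ = [
    "FrequencyTable",
    "MixingReport",
    "task_performance_frequency",
    "frequency_array",
    "mean_behavior",
    "behavioral_variation",
    "specialization",
    "specialization_by_task",
    "window_counts",
    "specialization_from_counts",
    "replicate_type_means",
    "mixing_effect",
    "classify_effect",
]

#: Tidy per-(replicate, ant, task) frequency table; see
#: :func:`task_performance_frequency` for the column layout.
FrequencyTable = pd.DataFrame


def _as_batch(result: SimResult | BatchResult) -> tuple[np.ndarray, np.ndarray, int]:
    """(task_history (R,T,n), type_labels, m) from either result type."""
    if isinstance(result, BatchResult):
        hist = result.task_history
    elif isinstance(result, SimResult):
        hist = result.task_history[None, ...]
    else:
        raise TypeError(f"expected SimResult or BatchResult, got {type(result).__name__}")
    if hist.shape[1] == 0:
        raise ValueError("empty task history")
    return hist, result.type_labels, result.config.m


def frequency_array(result: SimResult | BatchResult) -> np.ndarray:
    """Per-ant task performance frequencies as an (R, n, m) array.

    frequency[r, i, j] = (#steps ant i of replicate r spent on task j) / T.
    """
    hist, _, m = _as_batch(result)
    R, T, n = hist.shape
    freq = np.empty((R, n, m))
    for j in range(m):
        freq[:, :, j] = (hist == j).sum(axis=1) / T
    return freq


def task_performance_frequency(result: SimResult | BatchResult) -> FrequencyTable:
    """Tidy frequency table with columns (replicate, ant, type, task, frequency).

    An ant that spent 2,000 of T = 10,000 steps on task 1 and 4,000 on task 2
    has frequencies 0.2 and 0.4; frequencies plus the inactive fraction sum
    to 1 for every ant.
    """
    freq = frequency_array(result)
    _, labels, m = _as_batch(result)
    R, n, _ = freq.shape
    rep, ant, task = np.meshgrid(np.arange(R), np.arange(n), np.arange(m), indexing="ij")
    return pd.DataFrame(
        {
            "replicate": rep.ravel(),
            "ant": ant.ravel(),
            "type": np.tile(np.repeat(labels, m), R),
            "task": task.ravel(),
            "frequency": freq.ravel(),
        }
    )


def mean_behavior(freqs: FrequencyTable, group: str = "all") -> pd.Series:
    """Per-task arithmetic mean frequency over the selected ants.

    ``group`` is ``"all"`` (colony mean) or a type label.  Averages pool all
    replicates present in the table.
    """
    if group != "all":
        if group not in set(freqs["type"]):
            raise KeyError(f"unknown type label {group!r}")
        freqs = freqs[freqs["type"] == group]
    return freqs.groupby("task")["frequency"].mean()


def behavioral_variation(freqs: FrequencyTable, ddof: int = 1) -> pd.DataFrame:
    """Standard deviation of task performance frequency across colony members.

    Returns a tidy frame with columns (replicate, task, variation), using the
    sample s.d. (``ddof=1``) by default.  Requires at least two ants.
    """
    n_ants = freqs.groupby("replicate")["ant"].nunique()
    if (n_ants < 2).any():
        raise ValueError("behavioral variation requires >= 2 ants per colony")
    out = (
        freqs.groupby(["replicate", "task"])["frequency"]
        .std(ddof=ddof)
        .rename("variation")
        .reset_index()
    )
    return out


def window_counts(result: SimResult | BatchResult, window: int = 200) -> np.ndarray:
    """Within-window task-performance counts, shape (R, W, n, m).

    The history is partitioned into W = floor(T / window) consecutive
    non-overlapping windows; count[r, w, i, j] is the number of steps ant i
    spent on task j inside window w (its within-window frequency times the
    window length).
    """
    hist, _, m = _as_batch(result)
    R, T, n = hist.shape
    W = T // window
    if window <= 0 or W < 2:
        raise ValueError("window must be positive and at most T/2")
    th = hist[:, : W * window].reshape(R, W, window, n)
    counts = np.empty((R, W, n, m), dtype=np.int32)
    for j in range(m):
        counts[..., j] = (th == j).sum(axis=2)
    return counts


def specialization_from_counts(counts: np.ndarray) -> np.ndarray:
    """Mean consecutive-window Spearman correlation per replicate and task.

    ``counts`` is an (R, W, n, m) array of within-window performance counts
    (see :func:`window_counts`).  Ants are ranked within each window (average
    ranks for ties) and consecutive windows' rank vectors correlated; window
    pairs where either window has no variation across ants (undefined
    correlation) are dropped from the mean.  Returns (R, m).
    """
    counts = np.asarray(counts)
    if counts.ndim != 4:
        raise ValueError("counts must have shape (R, W, n, m)")
    R, W, n, m = counts.shape
    if W < 2:
        raise ValueError("need at least two windows")
    out = np.empty((R, m))
    for j in range(m):
        ranks = stats.rankdata(counts[..., j], axis=2)  # average ranks for ties
        a = ranks[:, :-1] - ranks[:, :-1].mean(axis=2, keepdims=True)
        b = ranks[:, 1:] - ranks[:, 1:].mean(axis=2, keepdims=True)
        num = (a * b).sum(axis=2)
        den = np.sqrt((a**2).sum(axis=2) * (b**2).sum(axis=2))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(den > 0, num / den, np.nan)  # (R, W-1)
        if np.isnan(rho).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
                out[:, j] = np.nanmean(rho, axis=1)
        else:
            out[:, j] = rho.mean(axis=1)
    return out


def _window_rank_correlations(hist: np.ndarray, m: int, window: int) -> np.ndarray:
    """specialization_from_counts on a raw (R, T, n) history."""
    R, T, n = hist.shape
    W = T // window
    if window <= 0 or W < 2:
        raise ValueError("window must be positive and at most T/2")
    th = hist[:, : W * window].reshape(R, W, window, n)
    counts = np.empty((R, W, n, m), dtype=np.int32)
    for j in range(m):
        counts[..., j] = (th == j).sum(axis=2)
    return specialization_from_counts(counts)


def specialization(result: SimResult | BatchResult, window: int = 200):
    """Colony specialization: Spearman rank correlation of ants' within-window
    task performance between consecutive non-overlapping windows, averaged
    over window pairs and then over tasks.

    Returns a scalar for a ``SimResult`` and a length-R array for a
    ``BatchResult``.  Window pairs in which either window shows no
    between-ant variation are excluded from the average.
    """
    hist, _, m = _as_batch(result)
    T = hist.shape[1]
    if window <= 0 or T // window < 2:
        raise ValueError("window must be positive and at most T/2")
    per_task = _window_rank_correlations(hist, m, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        val = np.nanmean(per_task, axis=1)  # tasks never performed carry no signal
    return val if isinstance(result, BatchResult) else float(val[0])


def specialization_by_task(result: SimResult | BatchResult, window: int = 200) -> np.ndarray:
    """Per-task specialization, shape (R, m) (R = 1 for a ``SimResult``)."""
    hist, _, m = _as_batch(result)
    return _window_rank_correlations(hist, m, window)


def replicate_type_means(result: BatchResult, label: str, task: int = 0) -> np.ndarray:
    """Per-replicate mean frequency of one type for one task, shape (R,)."""
    freq = frequency_array(result)
    mask = result.type_labels == label
    if not mask.any():
        raise KeyError(f"unknown type label {label!r}")
    return freq[:, mask, task].mean(axis=1)


@dataclass
class MixingReport:
    """Mixing-effect statistics for one pure-X / pure-Y / mixed comparison.

    X is the type with the lower mean behavior in pure colonies, Y the
    higher.  All means refer to one task (or, for tracking data, to the
    r.m.s.d.).  ``effect`` = (Y_m - X_m) - (Y_p - X_p); positive means the
    between-type gap widened under mixing.
    """

    label_x: str
    label_y: str
    x_pure: float
    y_pure: float
    x_mixed: float
    y_mixed: float
    effect: float
    effect_se: float
    t_stat: float
    p_value: float
    classification: str
    asymmetry_x: float  # |X_m - X_p|
    asymmetry_y: float  # |Y_m - Y_p|
    asymmetry_t: float = np.nan
    asymmetry_p: float = np.nan
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MixingReport({self.label_x}/{self.label_y}: "
            f"pure gap {self.y_pure - self.x_pure:+.4f}, "
            f"mixed gap {self.y_mixed - self.x_mixed:+.4f}, "
            f"effect {self.effect:+.4f} (t={self.t_stat:.2f}, p={self.p_value:.4f}) "
            f"-> {self.classification})"
        )


def classify_effect(effect: float, p_value: float, ordering_holds: bool, alpha: float = 0.05) -> str:
    """Map the effect statistic and its test to a behavioral-pattern label."""
    if not ordering_holds:
        return "other"
    if p_value < alpha:
        return "convergence" if effect < 0 else "divergence"
    return "no_effect"


def mixing_effect(
    pure_x: np.ndarray,
    pure_y: np.ndarray,
    mixed_x: np.ndarray,
    mixed_y: np.ndarray,
    *,
    labels: tuple[str, str] = ("X", "Y"),
    alpha: float = 0.05,
    equal_var: bool = False,
) -> MixingReport:
    """Mixing-effect statistic and classification from replicate-level means.

    Parameters
    ----------
    pure_x, pure_y : arrays
        Per-replicate type means in the pure arms; paired by index to form
        pure-arm between-type differences (arbitrary pairing of pure
        colonies).
    mixed_x, mixed_y : arrays
        Per-replicate means of each type within the mixed colonies; their
        difference is formed within each replicate.
    equal_var : bool
        ``False`` (default) uses Welch's t test; ``True`` Student's t.

    The types are re-oriented so Y is the one with the higher pure-colony
    mean.  The two-sided test compares the pure-arm differences Y_p - X_p
    with the mixed-arm differences Y_m - X_m across replicates.
    """
    pure_x, pure_y = np.asarray(pure_x, float), np.asarray(pure_y, float)
    mixed_x, mixed_y = np.asarray(mixed_x, float), np.asarray(mixed_y, float)
    if min(len(pure_x), len(pure_y), len(mixed_x), len(mixed_y)) < 2:
        raise ValueError("need >= 2 replicates per arm")
    if len(pure_x) != len(pure_y):
        raise ValueError("pure arms must pair replicate-by-replicate")
    lab_x, lab_y = labels
    if pure_y.mean() < pure_x.mean():
        pure_x, pure_y = pure_y, pure_x
        mixed_x, mixed_y = mixed_y, mixed_x
        lab_x, lab_y = lab_y, lab_x

    pure_diff = pure_y - pure_x
    mixed_diff = mixed_y - mixed_x
    effect = mixed_diff.mean() - pure_diff.mean()
    se = np.sqrt(mixed_diff.var(ddof=1) / len(mixed_diff) + pure_diff.var(ddof=1) / len(pure_diff))
    t_stat, p_value = stats.ttest_ind(mixed_diff, pure_diff, equal_var=equal_var)

    ordering_holds = mixed_y.mean() > mixed_x.mean()
    classification = classify_effect(effect, p_value, ordering_holds, alpha)

    asym_x = np.abs(mixed_x.mean() - pure_x.mean())
    asym_y = np.abs(mixed_y.mean() - pure_y.mean())
    asym_t, asym_p = np.nan, np.nan
    if len(mixed_x) == len(pure_x):
        # per-replicate magnitudes of the mixing-induced shift, per type
        ax = np.abs(mixed_x - pure_x)
        ay = np.abs(mixed_y - pure_y)
        asym_t, asym_p = stats.ttest_ind(ax, ay, equal_var=equal_var)

    return MixingReport(
        label_x=lab_x,
        label_y=lab_y,
        x_pure=float(pure_x.mean()),
        y_pure=float(pure_y.mean()),
        x_mixed=float(mixed_x.mean()),
        y_mixed=float(mixed_y.mean()),
        effect=float(effect),
        effect_se=float(se),
        t_stat=float(t_stat),
        p_value=float(p_value),
        classification=classification,
        asymmetry_x=float(asym_x),
        asymmetry_y=float(asym_y),
        asymmetry_t=float(asym_t),
        asymmetry_p=float(asym_p),
        alpha=alpha,
    )
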