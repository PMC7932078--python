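"""Response statistics: selection rates, Thurstone probit scores,
zero-cell correction, pairwise z tests with Bonferroni correction,
quartile summaries, and Grubbs outlier replacement.

Paired-comparison preferences are scaled the Thurstonian way: each
algorithm's per-subject score is the mean of the probit-transformed
selection ratios against its four opponents (the least-squares Case V
solution for a complete balanced design).  Extreme cells (0 or 12 of the
12 trials per pair) are shrunk to (0.5, 11.5) before the transform so
the normal quantile stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedComparisonMatrix",
    "selection_rate",
    "correct_zero_cells",
    "probit_score",
    "subject_scores",
    "pairwise_pvalues",
    "grubbs_replace",
    "summarize",
    "read_experiment_workbook",
]

ALGORITHMS = ("O", "A", "B", "C", "U")


@dataclass
class PairedComparisonMatrix:
    """Per-subject choice counts: ``counts[i][j]`` = times i beat j."""

    algorithms: tuple[str, ...] = ALGORITHMS
    trials_per_pair: int = 12
    counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        k = len(self.algorithms)
        if self.counts is None:
            self.counts = np.zeros((k, k), dtype=float)
        else:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != (k, k):
                raise ValueError("counts must be a square matrix over the algorithms")

    def record(self, winner: str, loser: str, n: int = 1) -> None:
        i = self.algorithms.index(winner)
        j = self.algorithms.index(loser)
        self.counts[i, j] += n

    def validate(self) -> None:
        k = len(self.algorithms)
        for i in range(k):
            for j in range(i + 1, k):
                if self.counts[i, j] + self.counts[j, i] != self.trials_per_pair:
                    raise ValueError(
                        f"incomplete matrix: pair ({self.algorithms[i]},"
                        f"{self.algorithms[j]}) has "
                        f"{self.counts[i, j] + self.counts[j, i]} trials"
                    )

    def complement(self) -> "PairedComparisonMatrix":
        """The matrix with every choice flipped."""
        return PairedComparisonMatrix(
            self.algorithms, self.trials_per_pair, self.counts.T.copy()
        )


def selection_rate(choices) -> float:
    """Fraction of trials in which the target stimulus was chosen."""
    choices = list(choices)
    if not choices:
        raise ValueError("choices must be non-empty")
    return sum(bool(c) for c in choices) / len(choices)


def correct_zero_cells(selected: float, not_selected: float) -> tuple[float, float]:
    """Shrink extreme count pairs so the probit transform stays finite.

    ``(0, n) -> (0.5, n-0.5)`` and symmetrically ``(n, 0) -> (n-0.5, 0.5)``
    (with n = 12 trials: (0.5, 11.5)); all other cells pass through.
    """
    if selected < 0 or not_selected < 0:
        raise ValueError("counts must be non-negative")
    total = selected + not_selected
    if selected == 0:
        return 0.5, total - 0.5
    if not_selected == 0:
        return total - 0.5, 0.5
    return selected, not_selected


def probit_score(ratio: float) -> float:
    """Standard-normal quantile of a selection ratio in (0, 1)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(
            "selection ratio must be strictly inside (0, 1); "
            "apply correct_zero_cells to extreme counts first"
        )
    return float(stats.norm.ppf(ratio))


def subject_scores(m: PairedComparisonMatrix) -> dict[str, float]:
    """Per-algorithm Thurstone scores for one subject.

    score(i) = mean over opponents j of probit(corrected wins of i over
    j / trials per pair).
    """
    m.validate()
    k = len(m.algorithms)
    scores = {}
    for i in range(k):
        vals = []
        for j in range(k):
            if i == j:
                continue
            sel, _ = correct_zero_cells(m.counts[i, j], m.counts[j, i])
            vals.append(probit_score(sel / m.trials_per_pair))
        scores[m.algorithms[i]] = float(np.mean(vals))
    return scores


def pairwise_pvalues(group_scores: pd.DataFrame) -> pd.DataFrame:
    """Bonferroni-corrected two-sample z tests between algorithm scores.

    ``group_scores``: one row per subject, one column per algorithm.
    For each pair the z statistic uses the two score populations' means
    and (unpooled) standard deviations; the two-sided p is multiplied by
    the number of pairs and capped at 1.
    """
    if len(group_scores) < 2:
        raise ValueError("need at least 2 subjects")
    algos = list(group_scores.columns)
    k = len(algos)
    n_pairs = k * (k - 1) // 2
    out = pd.DataFrame(np.ones((k, k)), index=algos, columns=algos)
    for a in range(k):
        for b in range(a + 1, k):
            xa = group_scores[algos[a]].to_numpy(dtype=float)
            xb = group_scores[algos[b]].to_numpy(dtype=float)
            se = math.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
            if se == 0.0:
                p = 1.0 if xa.mean() == xb.mean() else 0.0
            else:
                z = (xa.mean() - xb.mean()) / se
                p = 2.0 * stats.norm.sf(abs(z))
            p = min(1.0, p * n_pairs)
            out.iloc[a, b] = p
            out.iloc[b, a] = p
    return out


def grubbs_replace(values, alpha: float = 0.05) -> tuple[np.ndarray, dict]:
    """Two-sided Grubbs outlier test with mean replacement.

    The most extreme value is tested with G = max|x - mean|/sd against
    the t-based critical value at level ``alpha``; if significant it is
    replaced by the mean of the remaining values.  At most one value is
    replaced per call.  Returns ``(values', report)`` where the report
    carries the statistic, critical value, approximate p, and the index
    replaced (or None).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    report = {"replaced_index": None, "statistic": 0.0, "critical": None, "p": 1.0}
    if sd == 0.0:
        return x.copy(), report
    dev = np.abs(x - mean)
    i = int(np.argmax(dev))
    g = dev[i] / sd
    tcrit = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    gcrit = (n - 1) / math.sqrt(n) * math.sqrt(tcrit**2 / (n - 2 + tcrit**2))
    # Map G back to its t value for an approximate two-sided p.
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        p = 0.0
    else:
        tval = math.sqrt((n - 2) * n * g * g / denom)
        p = min(1.0, 2.0 * n * stats.t.sf(tval, n - 2))
    report.update(statistic=float(g), critical=float(gcrit), p=float(p))
    out = x.copy()
    if g > gcrit:
        others = np.delete(x, i)
        out[i] = others.mean()
        report["replaced_index"] = i
    return out, report


def summarize(
    group_scores: pd.DataFrame,
    constants: pd.DataFrame | None = None,
    reference: str = "O",
) -> pd.DataFrame:
    """Quartile table and "ratio of larger scores" per algorithm.

    Quartiles use linear interpolation.  The ratio for an algorithm is
    the number of subjects whose score exceeds their reference
    (still-image) score over the number of subjects whose calibrated
    constant for that algorithm is nonzero; subjects with a zero
    constant leave both numerator and denominator (their stimulus was
    effectively a still image).  ``constants`` mirrors ``group_scores``
    (row per subject, column per algorithm); if omitted all constants
    are taken as nonzero.
    """
    rows = []
    for algo in group_scores.columns:
        s = group_scores[algo].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        if algo == reference:
            ratio = None
            larger = denom = 0
        else:
            if constants is not None:
                eligible = constants[algo].to_numpy(dtype=float) != 0.0
            else:
                eligible = np.ones(len(s), dtype=bool)
            ref = group_scores[reference].to_numpy(dtype=float)
            larger = int(np.sum((s > ref) & eligible))
            denom = int(eligible.sum())
            ratio = f"{larger}/{denom}"
        rows.append(
            {
                "algorithm": algo,
                "ratio_larger": ratio,
                "n_larger": larger,
                "n_eligible": denom,
                "q1": q1,
                "median": med,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows).set_index("algorithm")


def read_experiment_workbook(path, sheet_map: dict[str, str] | None = None) -> dict[str, pd.DataFrame]:
    """Best-effort reader for a per-experiment results workbook (.xlsx).

    ``sheet_map`` maps short keys (e.g. ``"exp1"``) to sheet names; if
    omitted, every sheet is returned keyed by its own name.  Columns are
    passed through untouched — downstream mapping is the caller's job.
    """
    book = pd.read_excel(path, sheet_name=None)
    if sheet_map is None:
        return book
    out = {}
    for key, sheet in sheet_map.items():
        if sheet not in book:
            raise ValueError(f"workbook has no sheet {sheet!r} (wanted for {key!r})")
        out[key] = book[sheet]
    return out
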