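"""Accuracy tables and inferential statistics for model comparison.

Two models evaluated on the same items are compared with McNemar's test
on the discordant pairs (continuity-corrected chi-square, or the exact
two-sided binomial when fewer than 25 pairs are discordant); families of
p-values are adjusted by the Benjamini-Hochberg step-up FDR procedure;
accuracies of one model across two independent test sets are compared
with the pooled two-proportion z-test.  The test machinery is delegated
to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from bosbench.errors import ValidationError

EXACT_THRESHOLD = 25  # discordant-pair count below which the exact test is used


@dataclass(frozen=True)
class PairedOutcomes:
    """Per-item correctness of two models on the identical test set."""

    correct1: np.ndarray
    correct2: np.ndarray

    def __post_init__(self) -> None:
        c1, c2 = np.asarray(self.correct1, bool), np.asarray(self.correct2, bool)
        if c1.shape != c2.shape or c1.ndim != 1:
            raise ValidationError("correctness vectors must be equal-length 1-D")

    @property
    def b(self) -> int:
        """Items model 1 got right and model 2 wrong."""
        c1, c2 = np.asarray(self.correct1, bool), np.asarray(self.correct2, bool)
        return int((c1 & ~c2).sum())

    @property
    def c(self) -> int:
        """Items model 2 got right and model 1 wrong."""
        c1, c2 = np.asarray(self.correct1, bool), np.asarray(self.correct2, bool)
        return int((~c1 & c2).sum())


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    comparison: str = ""
    method: str = ""
    q: float | None = None          # BH-adjusted p, filled by bh_adjust
    degenerate: bool = False


def mcnemar(outcomes: PairedOutcomes | tuple[int, int],
            correction: bool = True) -> TestResult:
    """McNemar's test on the discordant counts (b, c).

    Uses the continuity-corrected chi-square ``(|b - c| - 1)^2 / (b + c)``
    when at least 25 pairs are discordant, the exact two-sided binomial
    test otherwise.  ``b + c = 0`` returns p = 1 flagged as degenerate.
    """
    if isinstance(outcomes, PairedOutcomes):
        b, c = outcomes.b, outcomes.c
    else:
        b, c = outcomes
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be nonnegative")
    if b + c == 0:
        return TestResult(statistic=0.0, p=1.0, method="degenerate",
                          degenerate=True)
    table = [[0, b], [c, 0]]
    exact = (b + c) < EXACT_THRESHOLD
    res = _sm_mcnemar(table, exact=exact, correction=correction)
    method = "exact-binomial" if exact else (
        "chi2-corrected" if correction else "chi2")
    return TestResult(statistic=float(res.statistic),
                      p=min(1.0, float(res.pvalue)), method=method)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_i = min_{j >= i} p_(j) m / j`` on the ascending order statistics,
    mapped back to the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q


def adjust_results(results: list[TestResult]) -> list[TestResult]:
    """Attach BH q-values across one family of comparisons."""
    q = bh_adjust([r.p for r in results])
    return [TestResult(statistic=r.statistic, p=r.p, comparison=r.comparison,
                       method=r.method, q=float(qi), degenerate=r.degenerate)
            for r, qi in zip(results, q)]


def two_prop_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test, two-sided.

    ``z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2))`` with the pooled
    ``p = (x1 + x2) / (n1 + n2)``.  A pooled proportion of exactly 0 or 1
    yields an infinite-z degenerate result with p = 1 (no information
    about a difference when both samples are unanimous).
    """
    if n1 < 1 or n2 < 1 or not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("invalid success/trial counts")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(statistic=np.inf if x1 / n1 >= x2 / n2 else -np.inf,
                          p=1.0, method="degenerate", degenerate=True)
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return TestResult(statistic=float(z), p=float(p), method="pooled-z")


def accuracy_table(predictions: dict[str, np.ndarray],
                   manifest: pd.DataFrame,
                   grouping: str = "none") -> pd.DataFrame:
    """Per-group accuracy of one or several models.

    ``predictions`` maps model name to hard labels in {0, 1} aligned with
    the manifest rows; ``grouping`` is ``none`` or a manifest column
    (e.g. ``gap_n``, ``fragment_code``, ``condition``).  Returns one row
    per (model, group) with n, correct count and accuracy.
    """
    from bosbench.modelzoo import labels_to_y

    y = labels_to_y(manifest["label"].to_numpy())
    if grouping != "none" and grouping not in manifest.columns:
        raise ValidationError(f"manifest lacks grouping column {grouping!r}")
    groups = (np.full(len(manifest), "all")
              if grouping == "none" else manifest[grouping].to_numpy())
    rows = []
    for name, yhat in predictions.items():
        yhat = np.asarray(yhat)
        if yhat.shape != y.shape:
            raise ValidationError("predictions misaligned with manifest")
        correct = yhat == y
        for gval in pd.unique(groups):
            sel = groups == gval
            n, k = int(sel.sum()), int(correct[sel].sum())
            if n == 0:
                raise ValidationError(f"empty group {gval!r}")
            rows.append(dict(model=name, group=gval, n=n, correct=k,
                             accuracy=k / n))
    return pd.DataFrame(rows)


def correctness(yhat: np.ndarray, labels) -> np.ndarray:
    """Boolean per-item correctness vector for McNemar pairing."""
    from bosbench.modelzoo import labels_to_y
    return np.asarray(yhat) == labels_to_y(labels)
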