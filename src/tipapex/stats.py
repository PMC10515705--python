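"""ROC/AUC analysis, cut-off selection and association tests.

The discrimination analysis follows standard clinical-score practice:
the AUC is the Mann-Whitney probability that a randomly chosen cut-out
case scores higher (after risk orientation) than a randomly chosen
non-cut-out case, its confidence interval comes from the DeLong
variance estimator, and the operating cut-off maximises the Youden
index J = sensitivity + specificity - 1.  Categorical associations use
the Pearson chi-square test, falling back to an exact
(Fisher-conditional) test when any expected cell count is below 5;
group comparisons of continuous scores use the Mann-Whitney U test.
No multiplicity correction is applied: every p-value is a per-test
univariate value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "InsufficientDataError",
    "DegenerateTableError",
    "RocResult",
    "YoudenCutoff",
    "ContingencyTable",
    "ChiSquareResult",
    "auc_mann_whitney",
    "youden_cutoff",
    "delong_auc_variance",
    "auc_confidence_interval",
    "roc_analysis",
    "chi_square_test",
    "fisher_exact_rx2",
    "mann_whitney_test",
    "proportion_summary",
    "ThresholdRiskClassifier",
]


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateTableError(ValueError):
    """Contingency table has a zero row or column margin."""


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

def _check_groups(scores_pos: Sequence[float], scores_neg: Sequence[float]):
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("both outcome groups must be non-empty")
    return pos, neg


def auc_mann_whitney(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """AUC as the Mann-Whitney pair-ordering probability.

    AUC = (#{pos > neg} + 0.5 * #{pos == neg}) / (n_pos * n_neg),
    computed via midranks in O(n log n); identical to the trapezoidal
    area under the empirical ROC curve, ties included.
    """
    pos, neg = _check_groups(scores_pos, scores_neg)
    m, n = pos.size, neg.size
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


@dataclass(frozen=True)
class YoudenCutoff:
    cutoff: float
    sensitivity: float  # fraction in [0, 1]
    specificity: float
    j: float            # Youden index at the cutoff
    degenerate: bool    # True when no cutoff separates better than chance


def youden_cutoff(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    direction: int = 1,
) -> YoudenCutoff:
    """Youden-optimal operating cut-off.

    ``direction=+1`` flags risk when score >= cutoff, ``-1`` when
    score <= cutoff.  Candidate cut-offs are midpoints between adjacent
    distinct observed values (plus one candidate beyond each extreme);
    ties in J are broken toward the more specific rule.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    pos, neg = _check_groups(scores_pos, scores_neg)
    values = np.unique(np.concatenate([pos, neg]))
    span = max(values[-1] - values[0], 1.0)
    candidates = np.concatenate(
        [[values[0] - 0.5 * span], (values[:-1] + values[1:]) / 2.0, [values[-1] + 0.5 * span]]
    )
    best: Optional[YoudenCutoff] = None
    for c in candidates:
        if direction == 1:
            sens = float(np.mean(pos >= c))
            spec = float(np.mean(neg < c))
        else:
            sens = float(np.mean(pos <= c))
            spec = float(np.mean(neg > c))
        j = sens + spec - 1.0
        better = best is None or j > best.j + 1e-12
        tie = best is not None and abs(j - best.j) <= 1e-12 and spec > best.specificity
        if better or tie:
            best = YoudenCutoff(float(c), sens, spec, j, degenerate=False)
    assert best is not None
    if best.j <= 1e-12:
        best = YoudenCutoff(best.cutoff, best.sensitivity, best.specificity, best.j, True)
    return best


def delong_auc_variance(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> tuple[float, float]:
    """(AUC, variance) by DeLong's structural-components estimator."""
    pos, neg = _check_groups(scores_pos, scores_neg)
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise InsufficientDataError("DeLong variance needs >= 2 cases per group")
    ranks_all = sps.rankdata(np.concatenate([pos, neg]))
    ranks_pos = sps.rankdata(pos)
    ranks_neg = sps.rankdata(neg)
    auc = float((ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    # Structural components: V10_i = P(pos_i beats a random neg), analogously V01.
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def auc_confidence_interval(
    scores_pos: Sequence[float],
    scores_neg: Sequence[float],
    alpha: float = 0.05,
    method: str = "delong",
) -> tuple[float, float]:
    """Two-sided (1 - alpha) CI for the AUC, clipped to [0, 1]."""
    if method != "delong":
        raise ValueError(f"unknown CI method {method!r}")
    auc, var = delong_auc_variance(scores_pos, scores_neg)
    half = sps.norm.ppf(1.0 - alpha / 2.0) * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


@dataclass
class RocResult:
    """One parameter's discrimination summary (one report-table row)."""

    parameter_name: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    cutoff: float
    cutoff_clinical: float        # cutoff snapped to the nearest integer unit
    sensitivity_pct: float
    specificity_pct: float
    n_pos: int
    n_neg: int
    direction: int                # +1: high values flag risk; -1: low values
    degenerate: bool = False
    curve: Optional[np.ndarray] = None  # columns: threshold, tpr, fpr


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    parameter_name: str = "score",
    direction: int | str = "auto",
    alpha: float = 0.05,
    with_curve: bool = True,
) -> RocResult:
    """Full ROC summary of one continuous parameter against a binary outcome.

    ``direction`` is +1 when high values flag risk (TAD-family metrics),
    -1 when low values do (ABA), or ``"auto"`` to orient by whichever
    gives AUC >= 0.5.  The reported AUC, CI and operating point refer to
    the oriented score; the cut-off stays in the parameter's own units.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask = np.isfinite(scores)
    scores, labels = scores[mask], labels[mask]
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError(
            f"{parameter_name}: needs both outcome groups non-empty "
            f"(n_pos={pos.size}, n_neg={neg.size})"
        )
    if direction == "auto":
        direction = 1 if auc_mann_whitney(pos, neg) >= 0.5 else -1
    direction = int(direction)
    auc = auc_mann_whitney(direction * pos, direction * neg)
    ci_low, ci_high = auc_confidence_interval(direction * pos, direction * neg, alpha=alpha)
    _, p_value = mann_whitney_test(pos, neg)
    yc = youden_cutoff(pos, neg, direction=direction)
    curve = None
    if with_curve:
        fpr, tpr, thr = _sk_roc_curve(labels, direction * scores)
        curve = np.column_stack([direction * thr, tpr, fpr])
    return RocResult(
        parameter_name=parameter_name,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p_value),
        cutoff=yc.cutoff,
        cutoff_clinical=float(round(yc.cutoff)),
        sensitivity_pct=100.0 * yc.sensitivity,
        specificity_pct=100.0 * yc.specificity,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        direction=direction,
        degenerate=yc.degenerate,
        curve=curve,
    )


# --------------------------------------------------------------------------
# Categorical association tests
# --------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Labelled r x c count table."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)
        if len(self.row_labels) != self.counts.shape[0] or len(self.col_labels) != self.counts.shape[1]:
            raise ValueError("label lengths must match the count matrix shape")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    method_used: str          # "pearson" or "fisher-exact"
    expected: np.ndarray


def _log_comb(n, k):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_rx2(counts: np.ndarray) -> float:
    """Exact conditional (Fisher) two-sided p for an r x 2 table.

    Complete enumeration of all tables with the observed margins; the
    two-sided p-value sums the hypergeometric probabilities of every
    table no more probable than the observed one (the standard
    definition that fisher.test also uses).
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("fisher_exact_rx2 expects an r x 2 table")
    # The conditional distribution is symmetric in the two columns;
    # enumerate over the smaller margin for speed.
    if counts[:, 0].sum() > counts[:, 1].sum():
        counts = counts[:, ::-1]
    rows = counts.sum(axis=1)
    col0 = int(counts[:, 0].sum())
    total = int(counts.sum())
    log_denom = _log_comb(total, col0)

    def table_logp(ys):
        return float(sum(_log_comb(r, y) for r, y in zip(rows, ys)) - log_denom)

    obs_logp = table_logp(counts[:, 0])
    r = len(rows)
    p_sum = 0.0

    # Depth-first enumeration of column-0 compositions with fixed margins.
    def recurse(i: int, remaining: int, acc: float) -> float:
        nonlocal p_sum
        if i == r - 1:
            if remaining <= rows[i]:
                lp = acc + float(_log_comb(rows[i], remaining)) - float(log_denom)
                if lp <= obs_logp + 1e-9:
                    p_sum += math.exp(lp)
            return p_sum
        lo = max(0, remaining - int(rows[i + 1:].sum()))
        hi = min(int(rows[i]), remaining)
        for y in range(lo, hi + 1):
            recurse(i + 1, remaining - y, acc + float(_log_comb(rows[i], y)))
        return p_sum

    recurse(0, col0, 0.0)
    return min(1.0, p_sum)


def chi_square_test(table: ContingencyTable | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square, switching to an exact test for sparse tables.

    If every expected count is >= 5 the Pearson statistic (no continuity
    correction) and its chi-square p-value are reported.  Otherwise an
    exact conditional test is used: complete enumeration for r x 2 (and
    2 x c via transposition); the Pearson statistic is still reported
    alongside the exact p so report tables stay comparable.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("table has a zero row or column margin")
    stat, p, df, expected = sps.chi2_contingency(counts, correction=False)
    method = "pearson"
    if np.any(expected < 5):
        if counts.shape[1] == 2:
            narrow = counts
        elif counts.shape[0] == 2:
            narrow = counts.T
        else:
            narrow = None
        if narrow is not None and _enumeration_size(narrow) <= 5e6:
            p = fisher_exact_rx2(narrow)
            method = "fisher-exact"
        else:
            method = "pearson-low-expected"  # exact test infeasible at this size
    return ChiSquareResult(float(stat), int(df), float(p), method, expected)


def _enumeration_size(narrow: np.ndarray) -> float:
    """Upper bound on the number of fixed-margin tables to enumerate."""
    from scipy.special import comb

    col = int(min(narrow.sum(axis=0)))
    r = narrow.shape[0]
    return float(comb(col + r - 1, r - 1))


def mann_whitney_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for small samples (combined n <= 20, no
    ties), normal approximation with tie correction otherwise.
    Returns (U for group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def proportion_summary(count: int, total: int) -> float:
    """Relative frequency in percent, rounded half-up to one decimal."""
    count, total = int(count), int(total)
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# scikit-learn estimator wrapper
# --------------------------------------------------------------------------

class ThresholdRiskClassifier(ClassifierMixin, BaseEstimator):
    """Single-threshold risk classifier fitted by the Youden index.

    Wraps the cut-off selection as a scikit-learn binary classifier so
    it composes with pipelines and cross-validation.  ``fit`` learns
    the risk orientation (unless fixed via ``direction``) and the
    Youden-optimal cut-off on one continuous feature; ``predict`` flags
    the high-risk class.

    Parameters
    ----------
    direction : {"auto", 1, -1}
        +1 flags risk for values >= cutoff (TAD-family metrics),
        -1 for values <= cutoff (axis-blade angle).

    Attributes
    ----------
    cutoff_ : float
        Fitted operating threshold, in the feature's units.
    direction_ : int
        Fitted risk orientation.
    auc_ : float
        Oriented training AUC.
    sensitivity_, specificity_ : float
        Training operating point at ``cutoff_`` (fractions).
    """

    def __init__(self, direction: int | str = "auto"):
        self.direction = direction

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("ThresholdRiskClassifier expects exactly one feature")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if not np.array_equal(self.classes_, [0, 1]):
            raise ValueError("y must contain both classes 0 and 1")
        pos, neg = X[y == 1], X[y == 0]
        if self.direction == "auto":
            self.direction_ = 1 if auc_mann_whitney(pos, neg) >= 0.5 else -1
        else:
            self.direction_ = int(self.direction)
        self.auc_ = auc_mann_whitney(self.direction_ * pos, self.direction_ * neg)
        yc = youden_cutoff(pos, neg, direction=self.direction_)
        self.cutoff_ = yc.cutoff
        self.sensitivity_ = yc.sensitivity
        self.specificity_ = yc.specificity
        self.n_features_in_ = 1
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.direction_ * (X - self.cutoff_)

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)
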