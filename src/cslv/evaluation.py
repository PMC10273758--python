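"""Decile risk stratification and feature-importance summaries.

The decile table ranks a scored test set from highest to lowest risk,
splits it into ten deciles, and reports for each decile the case/control
counts and the odds ratio against the *whole* test set:

    OR_d = (a_d / b_d) / (A / B)

with a 95% Woolf interval, exp(ln OR +/- z * sqrt(1/a + 1/b + 1/A + 1/B)).
The reference group is the entire set (decile included) — an OR of 16.8 in
the top decile reads "16.8 times more likely than the average woman".

Decile sizes: with n = 10q + r the top decile gets q members and each of
deciles 2..r+1 gets one of the r remainder members, so the top decile is
never larger than the rest (889 -> 88, 89, 89, ..., 89).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cslv.models import auc as _pair_auc

__all__ = [
    "DecileRiskTable",
    "ImportanceSummary",
    "rank_into_deciles",
    "odds_ratio_vs_overall",
    "woolf_ci",
    "decile_risk_table",
    "top_fraction",
    "importance_summary",
]

Z_95 = 1.959964


def _decile_sizes(n: int, n_bins: int = 10) -> np.ndarray:
    q, r = divmod(n, n_bins)
    sizes = np.full(n_bins, q, dtype=np.int64)
    sizes[1 : r + 1] += 1  # remainder goes to deciles 2..r+1; top stays smallest
    return sizes


def rank_into_deciles(scores, n_bins: int = 10) -> np.ndarray:
    """Assign each score a decile, 1 = highest scores.

    Stable descending sort: ties keep input order. Requires n >= n_bins so
    no decile is empty.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} scores, got {n}")
    order = np.argsort(-scores, kind="stable")
    sizes = _decile_sizes(n, n_bins)
    deciles = np.empty(n, dtype=np.int64)
    start = 0
    for d, size in enumerate(sizes, start=1):
        deciles[order[start : start + size]] = d
        start += size
    return deciles


def odds_ratio_vs_overall(a_d: float, b_d: float, A: float, B: float) -> float:
    """Decile odds ratio against the whole set: (a_d / b_d) / (A / B).

    ``b_d == 0`` yields ``inf`` (reported with a warning); ``a_d == 0``
    yields 0.
    """
    if A <= 0 or B <= 0:
        raise ValueError("totals A and B must be positive")
    if b_d == 0:
        warnings.warn("decile has zero controls; odds ratio is infinite")
        return math.inf
    return (a_d / b_d) / (A / B)


def woolf_ci(
    a_d: float, b_d: float, A: float, B: float, z: float = Z_95
) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the decile odds ratio.

    exp(ln OR +/- z * sqrt(1/a_d + 1/b_d + 1/A + 1/B)). Any zero count
    triggers the Haldane-Anscombe 0.5 correction on all four counts, with
    a warning.
    """
    if min(a_d, b_d, A, B) < 0:
        raise ValueError("counts must be non-negative")
    if min(a_d, b_d, A, B) == 0:
        warnings.warn("zero count: applying Haldane-Anscombe 0.5 correction")
        a_d, b_d, A, B = a_d + 0.5, b_d + 0.5, A + 0.5, B + 0.5
    log_or = math.log((a_d / b_d) / (A / B))
    se = math.sqrt(1 / a_d + 1 / b_d + 1 / A + 1 / B)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


@dataclass
class DecileRiskTable:
    """Per-decile counts, odds ratios vs the whole set, and 95% CIs."""

    table: pd.DataFrame  # columns: decile, n_cases, n_controls, odds_ratio, ci_low, ci_high
    n_cases_total: int
    n_controls_total: int

    def __post_init__(self) -> None:
        if int(self.table["n_cases"].sum()) != self.n_cases_total:
            raise ValueError("decile case counts do not sum to the total")
        if int(self.table["n_controls"].sum()) != self.n_controls_total:
            raise ValueError("decile control counts do not sum to the total")


def decile_risk_table(scores, labels, n_bins: int = 10) -> DecileRiskTable:
    """Rank scores into deciles and tabulate counts, ORs and Woolf CIs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    deciles = rank_into_deciles(scores, n_bins=n_bins)
    positive = labels == np.max(labels)
    A = int(positive.sum())
    B = int(len(labels) - A)
    rows = []
    for d in range(1, n_bins + 1):
        mask = deciles == d
        a_d = int(np.sum(positive & mask))
        b_d = int(np.sum(~positive & mask))
        odds = odds_ratio_vs_overall(a_d, b_d, A, B)
        low, high = woolf_ci(a_d, b_d, A, B)
        rows.append((d, a_d, b_d, odds, low, high))
    frame = pd.DataFrame(
        rows, columns=["decile", "n_cases", "n_controls", "odds_ratio", "ci_low", "ci_high"]
    )
    return DecileRiskTable(frame, n_cases_total=A, n_controls_total=B)


def top_fraction(scores, labels, fraction: float) -> tuple[int, int]:
    """(cases, total) within the top ``fraction`` of ranked scores.

    The top group holds floor(n * fraction) members (at least one),
    consistent with the top decile being the smallest when n is not a
    multiple of ten.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    k = max(1, int(math.floor(n * fraction)))
    order = np.argsort(-scores, kind="stable")[:k]
    positive = labels == np.max(labels)
    return int(positive[order].sum()), k


@dataclass
class ImportanceSummary:
    """Feature importances sorted descending.

    For tree models ``contributions`` holds the per-sample signed SHAP
    matrix (samples x features) and ``base_value`` the model's expected
    margin; ``table.importance`` is the mean |SHAP| per feature. For other
    models importances are permutation AUC drops and ``contributions`` is
    None.
    """

    table: pd.DataFrame  # columns: feature, importance
    method: str
    contributions: np.ndarray | None = None
    base_value: float | None = None

    @property
    def largest_share(self) -> float:
        """Largest single-feature share of total importance."""
        total = float(self.table["importance"].sum())
        if total == 0:
            return 0.0
        return float(self.table["importance"].max()) / total


def _tree_booster(model):
    if hasattr(model, "booster_"):
        return model.booster_
    return None


def importance_summary(
    model,
    X,
    y=None,
    feature_names=None,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceSummary:
    """Feature-importance summary for a fitted model.

    Tree models (lightgbm) get exact TreeSHAP contributions via the
    booster's ``pred_contrib``; the importance is the mean absolute signed
    contribution per feature, and per-sample contributions are retained
    for summary plotting. Other models fall back to seeded permutation
    importance: the mean drop in pair-counting AUC over ``n_repeats``
    permutations of each column (requires ``y``).
    """
    if feature_names is None:
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
        elif hasattr(model, "feature_names_in_"):
            feature_names = list(model.feature_names_in_)
    X_arr = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X_arr.shape[1])]

    booster = _tree_booster(model)
    if booster is not None:
        contrib = booster.predict(X_arr, pred_contrib=True)
        base_value = float(contrib[0, -1])
        signed = contrib[:, :-1]
        importance = np.abs(signed).mean(axis=0)
        method = "treeshap"
        contributions = signed
    else:
        if y is None:
            raise ValueError("permutation importance requires labels y")
        y = np.asarray(y)
        rng = np.random.default_rng(seed)
        baseline = _pair_auc(model.predict_proba(X_arr)[:, 1], y)
        importance = np.zeros(X_arr.shape[1])
        for j in range(X_arr.shape[1]):
            drops = []
            for _ in range(n_repeats):
                shuffled = X_arr.copy()
                shuffled[:, j] = rng.permutation(shuffled[:, j])
                drops.append(baseline - _pair_auc(model.predict_proba(shuffled)[:, 1], y))
            importance[j] = float(np.mean(drops))
        method = "permutation"
        contributions = None
        base_value = None

    table = (
        pd.DataFrame({"feature": feature_names, "importance": importance})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return ImportanceSummary(
        table=table, method=method, contributions=contributions, base_value=base_value
    )
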