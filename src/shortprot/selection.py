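"""Feature evaluation and selection.

Features are ranked by the Golub signal-to-noise statistic
F = |mu+ - mu-| / (sd+ + sd-), pruned for redundancy by Pearson
correlation (the lower-F member of each strongly correlated pair is
dropped), filtered by a minimum F, and finally by a two-group ANOVA
p-value cutoff. Propensity scores quantify per-class enrichment of
min-max-scaled features (class mean / global mean; > 1 means enriched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .seqio import ValidationError

FVALUE_CAP = 1e6  # returned when the classes have zero variance but differ


@dataclass
class SelectionResult:
    kept: List[str]
    fvalues: Dict[str, float]
    pruned_pairs: List[Tuple[str, str, float]]  # (kept, dropped, r)
    pvalues: Dict[str, float]

    def to_frame(self):
        import pandas as pd
        dropped_by = {d: k for k, d, _ in self.pruned_pairs}
        names = list(self.fvalues)
        return pd.DataFrame({
            "feature": names,
            "F": [self.fvalues[n] for n in names],
            "p": [self.pvalues.get(n, np.nan) for n in names],
            "kept": [n in set(self.kept) for n in names],
            "pruned_by": [dropped_by.get(n, "") for n in names],
        })


@dataclass
class PropensityTable:
    names: List[str]
    score_short: np.ndarray
    score_long: np.ndarray

    def enriched_short(self) -> List[str]:
        return [n for n, s in zip(self.names, self.score_short) if s > 1]


def _two_class(values, labels):
    labels = np.asarray(labels, dtype=bool)
    values = np.asarray(values, dtype=float)
    pos, neg = values[labels], values[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need >= 2 samples per class")
    return pos, neg


def fvalue(pos_values: Sequence[float], neg_values: Sequence[float],
           cap: float = FVALUE_CAP) -> float:
    """Golub signal-to-noise ratio |mu+ - mu-| / (sd+ + sd-).

    Sample (n-1) standard deviations. When both classes have zero
    variance: 0 if the means agree, else ``cap``.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need >= 2 values per class")
    num = abs(pos.mean() - neg.mean())
    den = pos.std(ddof=1) + neg.std(ddof=1)
    if den == 0.0:
        return 0.0 if num == 0.0 else cap
    return num / den


def anova_p(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """Two-group one-way ANOVA p-value (equals the pooled t-test p, F=t^2)."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need >= 2 values per class")
    if pos.std(ddof=1) == 0.0 and neg.std(ddof=1) == 0.0:
        return 1.0 if pos.mean() == neg.mean() else 0.0
    return float(stats.f_oneway(pos, neg).pvalue)


def _pearson_r_p(matrix: np.ndarray):
    """All-pairs Pearson r and two-sided p; constant columns get r = nan."""
    n, m = matrix.shape
    sd = matrix.std(axis=0, ddof=1)
    centered = matrix - matrix.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centered / (sd * np.sqrt(n - 1))
    z[:, sd == 0] = np.nan
    r = z.T @ z
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def prune_correlated(matrix: np.ndarray, names: Sequence[str],
                     fvalues: Dict[str, float], r_threshold: float = 0.5,
                     p_threshold: float = 0.001):
    """Drop the lower-F member of each strongly correlated feature pair.

    Greedy pass in descending-F order (ties broken by schema order): a
    surviving feature eliminates every not-yet-dropped feature with
    Pearson r >= r_threshold (positive correlation) and correlation
    p < p_threshold against it. Constant columns have undefined
    correlations and are never pruned on this step.

    Returns (kept_names, pruned_pairs).
    """
    matrix = np.asarray(matrix, dtype=float)
    names = list(names)
    if matrix.shape[1] != len(names):
        raise ValidationError("matrix/names width mismatch")
    if r_threshold > 1.0:
        return names, []
    r, p = _pearson_r_p(matrix)
    order = sorted(range(len(names)),
                   key=lambda i: (-fvalues[names[i]], i))
    dropped = np.zeros(len(names), dtype=bool)
    pruned_pairs: List[Tuple[str, str, float]] = []
    for i in order:
        if dropped[i]:
            continue
        for j in order:
            if j == i or dropped[j]:
                continue
            rij = r[i, j]
            if np.isnan(rij):
                continue
            if rij >= r_threshold and p[i, j] < p_threshold:
                dropped[j] = True
                pruned_pairs.append((names[i], names[j], float(rij)))
    kept = [n for n, d in zip(names, dropped) if not d]
    return kept, pruned_pairs


def select_features(matrix: np.ndarray, labels: Sequence[bool],
                    names: Sequence[str], f_min: float = 0.1,
                    p_max: float = 0.001, r_threshold: float = 0.5,
                    corr_p: float = 0.001,
                    min_keep: int = 10) -> SelectionResult:
    """Full selection pipeline: correlation pruning -> F filter -> ANOVA filter.

    ``labels`` are True for the positive (short-lived) class. If nothing
    survives the filters (possible on label-shuffled controls), the top
    ``min_keep`` features by F are kept so downstream training remains
    defined; this fallback never triggers when real signal is present.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    names = list(names)
    if labels.all() or not labels.any():
        raise ValidationError("need samples from both classes")
    pos, neg = matrix[labels], matrix[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need >= 2 samples per class")

    fvals = {n: fvalue(pos[:, i], neg[:, i]) for i, n in enumerate(names)}
    kept, pruned_pairs = prune_correlated(matrix, names, fvals,
                                          r_threshold=r_threshold,
                                          p_threshold=corr_p)
    kept = [n for n in kept if fvals[n] >= f_min]
    pvals = {}
    surviving = []
    for n in kept:
        i = names.index(n)
        p = anova_p(pos[:, i], neg[:, i])
        pvals[n] = p
        if p <= p_max:
            surviving.append(n)
    if not surviving:
        ranked = sorted(names, key=lambda n: (-fvals[n], names.index(n)))
        surviving = ranked[:min_keep]
    # preserve schema order in the kept list
    kept_set = set(surviving)
    ordered = [n for n in names if n in kept_set]
    return SelectionResult(kept=ordered, fvalues=fvals,
                           pruned_pairs=pruned_pairs, pvalues=pvals)


def minmax_scale(matrix: np.ndarray,
                 bounds: Optional[Tuple[np.ndarray, np.ndarray]] = None):
    """Min-max scale columns to [0, 1]; constant columns map to 0.

    Returns (scaled, (mins, maxs)). With ``bounds`` given, applies them
    and clips to [0, 1] (for unseen data outside the training range).
    """
    matrix = np.asarray(matrix, dtype=float)
    if bounds is None:
        mins, maxs = matrix.min(axis=0), matrix.max(axis=0)
    else:
        mins, maxs = bounds
    span = maxs - mins
    span_safe = np.where(span == 0, 1.0, span)
    scaled = np.clip((matrix - mins) / span_safe, 0.0, 1.0)
    scaled[:, span == 0] = 0.0
    return scaled, (mins, maxs)


def propensity_scores(matrix: np.ndarray, labels: Sequence[bool],
                      names: Sequence[str]) -> PropensityTable:
    """Per-class enrichment of min-max-scaled features.

    score_class = mean of the scaled feature within the class divided by
    its mean over all samples; > 1 flags enrichment in that class. A
    feature constant across samples scores 1 in both classes.
    """
    labels = np.asarray(labels, dtype=bool)
    scaled, _ = minmax_scale(matrix)
    overall = scaled.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_short = scaled[labels].mean(axis=0) / overall
        s_long = scaled[~labels].mean(axis=0) / overall
    const = overall == 0
    s_short[const] = 1.0
    s_long[const] = 1.0
    return PropensityTable(list(names), s_short, s_long)
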