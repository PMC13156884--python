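"""TEER computation and the group-comparison decision tree.

Transendothelial electrical resistance (TEER) quantifies paracellular
barrier tightness: the mean resistance of blank (cell-free) membranes is
subtracted from the raw reading and the difference is multiplied by the
membrane area (0.336 cm^2 for the filter inserts used), giving Ohm*cm^2.

Group comparisons follow a normality-driven tree:

1. Shapiro-Wilk per group at ``alpha``.
2. All groups normal, two groups: Levene's test decides between Student's
   t (equal variances) and Welch's t. More than two groups: all pairwise
   t/Welch comparisons with Holm correction.
3. Any group non-normal, two groups: Mann-Whitney U (after log transform
   when the data are log-normal, i.e. raw values fail Shapiro-Wilk but
   their logs pass); paired designs use the Wilcoxon signed-rank test.
4. Any group non-normal, more than two groups: Kruskal-Wallis followed by
   pairwise Dunn tests with Holm correction.

A single comparison is reported uncorrected; Holm's step-down adjustment
is applied whenever more than one pairwise comparison is made.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

DEFAULT_MEMBRANE_AREA_CM2 = 0.336


@dataclass
class TEERRecord:
    raw_resistance_ohm: float
    blank_resistances_ohm: list[float]
    membrane_area_cm2: float
    teer_ohm_cm2: float
    negative: bool  # flagged when the blank-corrected resistance is negative
    ratio_after_before: float | None = None


def compute_teer(raw: float, blanks: list[float],
                 area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2) -> TEERRecord:
    """Blank-corrected TEER: (raw - mean(blanks)) * membrane area.

    Negative results are permitted but flagged (they indicate a reading
    below the blank level).
    """
    if len(blanks) == 0:
        raise ValueError("need at least one blank (cell-free) resistance")
    if area_cm2 <= 0:
        raise ValueError("membrane area must be positive")
    teer = (raw - float(np.mean(blanks))) * area_cm2
    return TEERRecord(raw_resistance_ohm=raw, blank_resistances_ohm=list(blanks),
                      membrane_area_cm2=area_cm2, teer_ohm_cm2=teer,
                      negative=teer < 0)


def holm_adjust(p: list[float] | np.ndarray) -> list[float]:
    """Holm's step-down multiple-comparison adjustment.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotone non-decrease along the sorted order, cap at 1, and restore
    the input order.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def dunn_pairwise(groups: list[np.ndarray]) -> list[tuple[int, int, float]]:
    """Dunn's rank-based post-hoc z-tests for all group pairs.

    Uses pooled ranks with the tie correction; returns raw two-sided
    p-values as ``(i, j, p)`` tuples (no multiplicity adjustment here).
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        out.append((i, j, 2.0 * sps.norm.sf(abs(z))))
    return out


@dataclass
class StatResult:
    groups: list[str]
    test_used: str  # t | welch_t | mann_whitney | wilcoxon_pairwise | kruskal_wallis_dunn
    comparisons: list[tuple[str, str]]
    raw_p: list[float]
    adjusted_p: list[float]
    normality_p: dict[str, float]
    variance_test_p: float | None
    log_transformed: bool
    omnibus_p: float | None = None
    decisions: list[str] = field(default_factory=list)


def _two_sample_parametric(a, b, alpha, decisions):
    lev = sps.levene(a, b).pvalue
    if lev <= alpha:
        decisions.append(f"Levene p={lev:.3g} <= {alpha}: unequal variances, Welch's t")
        return "welch_t", sps.ttest_ind(a, b, equal_var=False).pvalue, lev
    decisions.append(f"Levene p={lev:.3g} > {alpha}: equal variances, Student's t")
    return "t", sps.ttest_ind(a, b, equal_var=True).pvalue, lev


def select_and_run_test(groups: dict[str, np.ndarray] | list[np.ndarray],
                        paired_design: bool = False,
                        alpha: float = 0.05) -> StatResult:
    """Run the normality-driven comparison tree on >= 2 groups.

    Every intermediate decision (normality, variance, transform) is
    recorded on the result. Raises for fewer than two groups or any group
    with n < 3 (Shapiro-Wilk needs at least 3 observations).
    """
    if isinstance(groups, dict):
        names = list(groups)
        data = [np.asarray(groups[k], float) for k in names]
    else:
        names = [f"group_{i}" for i in range(len(groups))]
        data = [np.asarray(g, float) for g in groups]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(names, data):
        if g.size < 3:
            raise ValueError(f"group {name!r} has n={g.size} < 3")
    decisions: list[str] = []
    norm_p = {n: float(sps.shapiro(g).pvalue) for n, g in zip(names, data)}
    all_normal = all(p > alpha for p in norm_p.values())
    decisions.append(
        f"Shapiro-Wilk per group: {', '.join(f'{k}={v:.3g}' for k, v in norm_p.items())}"
        f" -> {'all normal' if all_normal else 'non-normal'}"
    )
    log_transformed = False
    variance_p: float | None = None
    omnibus_p: float | None = None

    if all_normal:
        if paired_design:
            decisions.append("normal + paired: paired t-test per pair")
            comps, raw = [], []
            for i, j in itertools.combinations(range(len(data)), 2):
                comps.append((names[i], names[j]))
                raw.append(float(sps.ttest_rel(data[i], data[j]).pvalue))
            test = "t"
        elif len(data) == 2:
            test, p, variance_p = _two_sample_parametric(data[0], data[1], alpha, decisions)
            comps, raw = [(names[0], names[1])], [float(p)]
        else:
            decisions.append("normal, >2 groups: pairwise t/Welch with Holm correction")
            comps, raw, tests = [], [], set()
            for i, j in itertools.combinations(range(len(data)), 2):
                t_name, p, _ = _two_sample_parametric(data[i], data[j], alpha, decisions)
                comps.append((names[i], names[j]))
                raw.append(float(p))
                tests.add(t_name)
            test = "welch_t" if "welch_t" in tests else "t"
    else:
        # log-normal handling: logs of all-positive data pass Shapiro-Wilk
        if all(g.min() > 0 for g in data):
            logs = [np.log(g) for g in data]
            if all(sps.shapiro(g).pvalue > alpha for g in logs):
                decisions.append("raw non-normal but logs normal: log-transforming "
                                 "before rank tests")
                data = logs
                log_transformed = True
        if paired_design:
            decisions.append("non-normal + paired: Wilcoxon signed-rank per pair")
            test = "wilcoxon_pairwise"
            comps, raw = [], []
            for i, j in itertools.combinations(range(len(data)), 2):
                comps.append((names[i], names[j]))
                raw.append(float(sps.wilcoxon(data[i], data[j]).pvalue))
        elif len(data) == 2:
            decisions.append("non-normal, 2 groups: Mann-Whitney U")
            test = "mann_whitney"
            comps = [(names[0], names[1])]
            raw = [float(sps.mannwhitneyu(data[0], data[1],
                                          alternative="two-sided").pvalue)]
        else:
            omnibus_p = float(sps.kruskal(*data).pvalue)
            decisions.append(f"non-normal, >2 groups: Kruskal-Wallis p={omnibus_p:.3g}, "
                             "Dunn post-hoc with Holm correction")
            test = "kruskal_wallis_dunn"
            comps, raw = [], []
            for i, j, p in dunn_pairwise(data):
                comps.append((names[i], names[j]))
                raw.append(float(p))

    if len(raw) > 1:
        adjusted = holm_adjust(raw)
    else:
        decisions.append("single comparison: no multiplicity correction")
        adjusted = list(raw)
    return StatResult(groups=names, test_used=test, comparisons=comps,
                      raw_p=raw, adjusted_p=adjusted, normality_p=norm_p,
                      variance_test_p=variance_p, log_transformed=log_transformed,
                      omnibus_p=omnibus_p, decisions=decisions)
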