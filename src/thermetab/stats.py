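"""Treatment-level inference: one-way ANOVA, Tukey HSD letters, log2 fold-changes.

Each variable (a metabolite or a physiological trait) is tested across the
irrigation treatments with a classical one-way ANOVA; when groups differ,
pairwise post-hoc comparisons use the Tukey HSD studentized-range procedure
(Tukey-Kramer for unbalanced designs, e.g. sap flow measured in only two
treatments). Group separation is summarised as a compact letter display, and
metabolite responses as log2 fold-changes against the watered control,
gated by the Tukey comparison at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TreatmentComparison",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "log2_fold_change",
    "compare_treatments",
]


@dataclass
class TreatmentComparison:
    """Full per-variable treatment comparison.

    ``means``/``sems`` per group, the ANOVA F and p, the Tukey pairwise
    table, compact letters, and significance-gated log2 fold-changes vs the
    control group (NaN when no control was requested or means non-positive).
    """

    variable: str
    F: float
    p: float
    means: pd.Series
    sems: pd.Series
    letters: dict[str, str]
    pairwise: pd.DataFrame
    log2fc: pd.DataFrame | None = None


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Requires at least two groups of at least two observations each.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has < 2 observations")
    F, p = sps.f_oneway(*arrays)
    return float(F), float(p)


def tukey_hsd(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (Tukey-Kramer when unbalanced).

    ``groups`` maps group label to observations. Returns a table with one
    row per pair: mean difference, adjusted p, and a ``reject`` flag at
    ``alpha``.
    """
    labels, values = [], []
    for name, obs in groups.items():
        obs = np.asarray(obs, dtype=float)
        if obs.size < 2:
            raise ValueError(f"group {name!r} has < 2 observations")
        labels.extend([name] * obs.size)
        values.extend(obs.tolist())
    res = pairwise_tukeyhsd(np.asarray(values), np.asarray(labels), alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    out = pd.DataFrame(
        {
            "group1": table["group1"].astype(str),
            "group2": table["group2"].astype(str),
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
    return out


def compact_letter_display(
    pairwise: pd.DataFrame, group_order: list[str]
) -> dict[str, str]:
    """Compact letter display from a Tukey pairwise table.

    Greedy insert-absorb: groups sharing a letter are not significantly
    different. ``group_order`` fixes both the processing order and the
    tie-break (e.g. W, C, D).
    """
    sig = {
        frozenset((r.group1, r.group2))
        for r in pairwise.itertuples()
        if bool(r.reject)
    }
    letter_sets: list[set[str]] = []  # each set = groups sharing one letter
    for g in group_order:
        placed = False
        split_sets: list[set[str]] = []
        for s in letter_sets:
            if all(frozenset((g, other)) not in sig for other in s):
                s.add(g)
                placed = True
            else:
                # split: keep the compatible part of s together with g
                compatible = {o for o in s if frozenset((g, o)) not in sig}
                split_sets.append(compatible | {g})
        if not placed and not split_sets:
            letter_sets.append({g})
        else:
            letter_sets.extend(split_sets)
    # absorb letter sets contained in (or duplicating) another
    kept: list[set[str]] = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets) and s not in kept:
            kept.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in group_order}
    for letter, s in zip(alphabet, kept):
        for g in group_order:
            if g in s:
                out[g] += letter
    return out


def log2_fold_change(
    treatment_values,
    control_values,
    significant: bool,
) -> tuple[float, bool]:
    """Significance-gated log2 fold-change of group means.

    Returns ``(log2(mean_T / mean_C), significant)``; non-positive means make
    the fold-change undefined and raise.
    """
    m_t = float(np.mean(np.asarray(treatment_values, dtype=float)))
    m_c = float(np.mean(np.asarray(control_values, dtype=float)))
    if m_t <= 0.0 or m_c <= 0.0:
        raise ValueError("log2 fold-change undefined for non-positive means")
    return float(np.log2(m_t / m_c)), bool(significant)


def compare_treatments(
    data: pd.DataFrame,
    treatments: pd.Series,
    variable: str,
    control: str | None = None,
    alpha: float = 0.05,
    group_order: list[str] | None = None,
) -> TreatmentComparison:
    """ANOVA + Tukey + letters (+ gated log2FC vs control) for one variable.

    ``data`` holds the variable as a column; rows with missing values are
    dropped per group. When ``control`` is given, log2 fold-changes of each
    other treatment against it are computed and flagged significant only if
    the corresponding Tukey comparison rejects at ``alpha``.
    """
    y = data[variable]
    keep = y.notna()
    y, tr = y[keep], treatments[keep]
    order = group_order or sorted(tr.unique().tolist())
    order = [g for g in order if g in set(tr)]
    groups = {g: y[tr == g].to_numpy(dtype=float) for g in order}

    F, p = one_way_anova(list(groups.values()))
    pairwise = tukey_hsd(groups, alpha=alpha)
    letters = compact_letter_display(pairwise, order)

    log2fc = None
    if control is not None:
        if control not in groups:
            raise ValueError(f"control group {control!r} absent for {variable!r}")
        rows = []
        for g in order:
            if g == control:
                continue
            pair = pairwise[
                ((pairwise.group1 == g) & (pairwise.group2 == control))
                | ((pairwise.group1 == control) & (pairwise.group2 == g))
            ]
            sig = bool(pair.reject.iloc[0]) if len(pair) else False
            try:
                fc, sig = log2_fold_change(groups[g], groups[control], sig)
            except ValueError:
                fc, sig = np.nan, False
            rows.append({"treatment": g, "log2fc": fc, "significant": sig})
        log2fc = pd.DataFrame(rows)

    return TreatmentComparison(
        variable=variable,
        F=F,
        p=p,
        means=pd.Series({g: float(np.mean(v)) for g, v in groups.items()}),
        sems=pd.Series({g: float(sps.sem(v)) for g, v in groups.items()}),
        letters=letters,
        pairwise=pairwise,
        log2fc=log2fc,
    )
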