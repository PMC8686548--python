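"""Abundance comparison of lost / transferred / retained gene cohorts.

Given a table of protein abundances labelled by the evolutionary fate of
their genes (L = lost, T = transferred to the nucleus, R = retained in the
organellar genome — or a merged L+T group when nuclear genomes are
unavailable), this module runs a one-way ANOVA across groups followed by
Tukey's HSD for pairwise comparisons, and summarises the result as a
compact letter display: groups sharing a letter are not significantly
different at the chosen alpha.

Abundances span orders of magnitude, so the comparison is run on log10 ppm
by default; zeros are excluded (with a recorded count) or replaced by half
the smallest positive value in pseudo-count mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class CohortResult:
    group_means: Dict[str, float]
    group_sizes: Dict[str, int]
    f_stat: float
    p_value: float
    # pairwise results; None when compare_cohorts ran with pairwise=False
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    letters: Dict[str, str]
    alpha: float
    log_transformed: bool
    n_zero_excluded: int

    def distinct_groups(self) -> List[str]:
        """Groups whose letter set is disjoint from every other group's."""
        out = []
        for g, ls in self.letters.items():
            if all(set(ls).isdisjoint(o) for h, o in self.letters.items() if h != g):
                out.append(g)
        return out


def _letter_display(
    groups: List[str], sig_pairs: List[Tuple[str, str]]
) -> Dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Starts with all groups under one letter and splits on each significant
    pair, then drops redundant (subset) letter columns.  Two groups share a
    letter iff they were never split apart, i.e. iff they are not
    significantly different.
    """
    columns: List[set] = [set(groups)]
    for a, b in sig_pairs:
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop columns contained in another
        columns = [
            c
            for i, c in enumerate(new_columns)
            if c and not any(c < d or (c == d and i > j) for j, d in enumerate(new_columns))
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in sorted(col):
            letters[g] += letter
    return letters


def compare_cohorts(
    table: pd.DataFrame,
    alpha: float = 0.05,
    log_transform: bool = True,
    zero_policy: str = "drop",
    pairwise: bool = True,
) -> CohortResult:
    """One-way ANOVA with Tukey HSD over cohort-labelled abundances.

    ``table`` needs columns ``label`` and ``abundance_ppm``.  Requires at
    least two labels with at least two observations each.  With two labels
    the design degenerates gracefully to a two-sample comparison (the Tukey
    adjustment is then a no-op).  ``pairwise=False`` skips the Tukey step
    (which dominates the runtime) and returns only the omnibus ANOVA, with
    ``tukey`` and ``letters`` set to None.
    """
    if zero_policy not in ("drop", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if not {"label", "abundance_ppm"} <= set(table.columns):
        raise ValueError("table must have 'label' and 'abundance_ppm' columns")
    if (table["abundance_ppm"] < 0).any():
        raise ValueError("abundances must be non-negative")

    work = table[["label", "abundance_ppm"]].copy()
    n_zero = 0
    if log_transform:
        zeros = work["abundance_ppm"] <= 0
        n_zero = int(zeros.sum())
        if n_zero:
            if zero_policy == "drop":
                work = work[~zeros]
            else:
                positive_min = work.loc[~zeros, "abundance_ppm"].min()
                work.loc[zeros, "abundance_ppm"] = positive_min / 2.0
        work["value"] = np.log10(work["abundance_ppm"])
    else:
        work["value"] = work["abundance_ppm"]

    sizes = work.groupby("label")["value"].size()
    if len(sizes) < 2:
        raise ValueError("need at least two cohort labels")
    if (sizes < 2).any():
        too_small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"labels with fewer than 2 observations: {too_small}")

    groups = sorted(sizes.index)
    samples = [work.loc[work["label"] == g, "value"].to_numpy() for g in groups]
    f_stat, p_value = stats.f_oneway(*samples)

    if pairwise:
        hsd = pairwise_tukeyhsd(
            work["value"].to_numpy(), work["label"].to_numpy(), alpha=alpha
        )
        pair_labels = list(itertools.combinations(hsd.groupsunique, 2))
        tukey = pd.DataFrame(
            {
                "group1": [a for a, _ in pair_labels],
                "group2": [b for _, b in pair_labels],
                "meandiff": hsd.meandiffs,
                "p_adj": hsd.pvalues,
                "reject": hsd.reject,
            }
        )
        sig_pairs = [
            (str(r.group1), str(r.group2))
            for r in tukey.itertuples(index=False)
            if bool(r.reject)
        ]
        letters = _letter_display(groups, sig_pairs)
    else:
        tukey = None
        letters = None

    means = work.groupby("label")["value"].mean()
    return CohortResult(
        group_means={g: float(means[g]) for g in groups},
        group_sizes={g: int(sizes[g]) for g in groups},
        f_stat=float(f_stat),
        p_value=float(p_value),
        tukey=tukey,
        letters=letters,
        alpha=alpha,
        log_transformed=log_transform,
        n_zero_excluded=n_zero,
    )
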