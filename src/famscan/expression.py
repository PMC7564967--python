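"""Tissue expression profiling from an FPKM matrix, and qPCR
2^-ddCt fold-change calling.

Expression flags use the conventional inclusive thresholds: a gene is
constitutively expressed when FPKM >= 1 in every tissue, and counted as
expressed in a tissue (for Venn membership) when FPKM >= 2 there. The
three expression groups come from seeded k-means on the per-gene mean of
log2(FPKM + 1), relabeled 1..3 by descending mean FPKM. qPCR fold-changes
follow the 2^-ddCt method with a two-sided Welch t-test on replicate dCt
values; a gene is called up (down) under a treatment when the fold-change
exceeds (falls below) 1 and p <= 0.05.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

__all__ = [
    "ExpressionGroup", "FoldChangeResult", "expression_flags",
    "group_expression", "venn_membership", "ddct_fold_change",
    "all_fold_changes",
]


def expression_flags(mat: ExpressionMatrix, constitutive_min: float = 1.0,
                     expressed_min: float = 2.0,
                     venn_tissues: list[str] | None = None
                     ) -> tuple[pd.Series, dict[str, set[str]]]:
    """Per-gene constitutive flag and per-tissue expressed sets.

    Returns (constitutive, expressed_sets): a boolean Series indexed by
    gene (FPKM >= ``constitutive_min`` in every tissue) and, for each
    selected tissue, the set of genes with FPKM >= ``expressed_min``.
    """
    frame = mat.frame
    constitutive = (frame >= constitutive_min).all(axis=1)
    tissues = venn_tissues if venn_tissues is not None else mat.tissues
    missing = [t for t in tissues if t not in frame.columns]
    if missing:
        raise KeyError(f"tissues {missing} not in matrix")
    expressed = {t: set(frame.index[frame[t] >= expressed_min])
                 for t in tissues}
    return constitutive, expressed


@dataclass
class ExpressionGroup:
    label: int  # 1 (high) .. k (low)
    members: list[str]
    mean_fpkm: float


def group_expression(mat: ExpressionMatrix, k: int = 3,
                     seed: int = 0) -> list[ExpressionGroup]:
    """Partition genes into ``k`` expression-level groups.

    Seeded k-means (100 restarts) on the per-gene mean log2(FPKM+1);
    groups are relabeled 1..k by descending mean FPKM so group 1 is the
    highest-expressed. Deterministic given (matrix, seed).
    """
    frame = mat.frame
    if k > len(frame):
        raise ValueError(f"k={k} exceeds the {len(frame)} genes")
    profile = np.log2(frame.values + 1.0).mean(axis=1)
    if np.allclose(profile, profile[0]):
        warnings.warn("all genes have identical expression; returning a "
                      "single group", stacklevel=2)
        return [ExpressionGroup(1, list(frame.index),
                                float(frame.values.mean()))]
    km = KMeans(n_clusters=k, n_init=100, random_state=seed)
    labels = km.fit_predict(profile.reshape(-1, 1))
    groups = []
    for lab in range(k):
        members = list(frame.index[labels == lab])
        mean_fpkm = float(frame.loc[members].values.mean())
        groups.append((mean_fpkm, members))
    groups.sort(key=lambda t: -t[0])
    return [ExpressionGroup(i + 1, members, round(mean, 2))
            for i, (mean, members) in enumerate(groups)]


def venn_membership(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for 2-5 named sets.

    Keys are sorted tuples of the set names a region belongs to; the
    count is the number of elements in exactly those sets.
    """
    if not 2 <= len(sets) <= 5:
        raise ValueError("venn_membership supports 2-5 sets")
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names
                                  if n not in combo)) if r < len(names) \
                else set()
            counts[combo] = len(inside - outside)
    return counts


@dataclass
class FoldChangeResult:
    gene_id: str
    condition: str
    fold_change: float
    p_value: float
    call: str  # {"up", "down", "ns"}


def ddct_fold_change(records: pd.DataFrame, gene: str, condition: str,
                     control: str = "control",
                     p_cutoff: float = 0.05) -> FoldChangeResult:
    """2^-ddCt fold-change of one gene under one treatment vs control.

    Per replicate dCt = Ct(target) - Ct(reference); ddCt = mean dCt of
    the treatment minus mean dCt of the control; p from a two-sided Welch
    t-test on the replicate dCt values.
    """
    sub = records[records.gene_id == gene]
    treat = sub[sub.condition == condition]
    ctrl = sub[sub.condition == control]
    if len(ctrl) < 2:
        raise ValueError(f"{gene}: missing or underreplicated control "
                         f"measurements ({len(ctrl)})")
    if len(treat) < 2:
        raise ValueError(f"{gene}: fewer than 2 replicates for "
                         f"{condition!r}")
    dct_t = (treat.ct_target - treat.ct_reference).to_numpy()
    dct_c = (ctrl.ct_target - ctrl.ct_reference).to_numpy()
    ddct = dct_t.mean() - dct_c.mean()
    fold = 2.0 ** (-ddct)
    if np.allclose(dct_t, dct_t[0]) and np.allclose(dct_c, dct_c[0]) \
            and np.isclose(dct_t[0], dct_c[0]):
        p = 1.0
    else:
        p = float(stats.ttest_ind(dct_t, dct_c, equal_var=False).pvalue)
        if np.isnan(p):  # zero variance in both groups, distinct means
            p = 0.0
    if p <= p_cutoff and fold > 1.0:
        call = "up"
    elif p <= p_cutoff and fold < 1.0:
        call = "down"
    else:
        call = "ns"
    return FoldChangeResult(gene, condition, fold, p, call)


def all_fold_changes(records: pd.DataFrame, control: str = "control",
                     p_cutoff: float = 0.05) -> list[FoldChangeResult]:
    out = []
    for gene in sorted(records.gene_id.unique()):
        conds = sorted(set(records[records.gene_id == gene].condition)
                       - {control})
        for cond in conds:
            out.append(ddct_fold_change(records, gene, cond, control,
                                        p_cutoff))
    return out
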