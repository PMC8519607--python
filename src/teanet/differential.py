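"""Differentially accumulated metabolites (DAMs) between two sample groups.

The decision rule is the standard two-gate call: fold change above 2
(equivalently |log2FC| > 1, strict) and Benjamini-Hochberg FDR below 0.05
(strict).  Fold change is the ratio of group arithmetic means on the raw
intensity scale (a geometric-mean mode is available); the p-value comes from
Welch's t-test on log10 intensities by default, with a Wilcoxon rank-sum
alternative — count-model tools (DESeq-style negative binomials) are not
appropriate for continuous positive LC-MS intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError, ParameterError
from .profiling import GroupAssignment
from .tables import AbundanceMatrix

__all__ = ["DamResult", "dam_test", "bh_adjust", "volcano_table"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("pvalues must be a non-empty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DamResult:
    """Per-feature differential-accumulation statistics for one group pair.

    ``table`` is indexed by feature id with columns ``log2_fc`` (log2 of the
    mean ratio A/B), ``p``, ``q`` and ``is_dam``.
    """

    pair: tuple[int, int]
    test: str
    fc_gate: float
    fdr_gate: float
    table: pd.DataFrame

    @property
    def dam_features(self) -> list[str]:
        return list(self.table.index[self.table["is_dam"]])

    def counts(self) -> dict:
        up = int(((self.table["log2_fc"] > 0) & self.table["is_dam"]).sum())
        down = int(((self.table["log2_fc"] < 0) & self.table["is_dam"]).sum())
        return {"pair": list(self.pair), "n_dam": up + down, "up_in_a": up, "up_in_b": down}


def _group_values(matrix: AbundanceMatrix, groups, label) -> pd.DataFrame:
    if isinstance(groups, GroupAssignment):
        labels = groups.labels
    else:
        labels = pd.Series(groups)
    members = labels.index[labels == label]
    bio = matrix.biological()
    members = bio.index.intersection(members)
    return bio.loc[members]


def dam_test(
    matrix: AbundanceMatrix,
    groups,
    pair: tuple[int, int],
    test: str = "welch",
    fc_gate: float = 2.0,
    fdr_gate: float = 0.05,
    fold_mode: str = "arithmetic",
) -> DamResult:
    """Call DAMs between ``pair = (A, B)``.

    log2FC is ``log2(mean_A / mean_B)`` on raw intensities (``fold_mode=
    "geometric"`` uses geometric means, i.e. mean log difference); the
    two-sided p comes from Welch's t or Wilcoxon on log10 intensities; q is
    BH across all features; ``is_dam`` requires ``|log2FC| > log2(fc_gate)``
    and ``q < fdr_gate``, both strict.  Features whose test statistic is
    undefined (identical constant values in both groups) get p = 1.
    """
    if test not in ("welch", "wilcoxon"):
        raise ParameterError(f"test must be welch or wilcoxon, got {test!r}")
    if fold_mode not in ("arithmetic", "geometric"):
        raise ParameterError(f"fold_mode must be arithmetic or geometric, got {fold_mode!r}")
    a, b = pair
    va = _group_values(matrix, groups, a)
    vb = _group_values(matrix, groups, b)
    if va.shape[0] < 3 or vb.shape[0] < 3:
        raise InsufficientDataError(
            f"each group needs >= 3 biological samples (got {va.shape[0]}, {vb.shape[0]})"
        )
    xa, xb = va.to_numpy(), vb.to_numpy()
    la, lb = np.log10(xa), np.log10(xb)
    if fold_mode == "arithmetic":
        log2_fc = np.log2(np.nanmean(xa, axis=0) / np.nanmean(xb, axis=0))
    else:
        log2_fc = (np.nanmean(la, axis=0) - np.nanmean(lb, axis=0)) / np.log10(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "welch":
            res = stats.ttest_ind(la, lb, axis=0, equal_var=False, nan_policy="omit")
        else:
            res = stats.mannwhitneyu(la, lb, axis=0, alternative="two-sided", nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance identical groups: no evidence
    q = bh_adjust(p)
    is_dam = (np.abs(log2_fc) > np.log2(fc_gate)) & (q < fdr_gate)
    table = pd.DataFrame(
        {"log2_fc": log2_fc, "p": p, "q": q, "is_dam": is_dam},
        index=pd.Index(va.columns, name="feature_id"),
    )
    return DamResult(pair=(a, b), test=test, fc_gate=fc_gate, fdr_gate=fdr_gate, table=table)


def volcano_table(dam: DamResult) -> pd.DataFrame:
    """Volcano-plot coordinates: one row per feature.

    Columns ``feature_id, log2_fc, neg_log10_q, is_dam``; q = 1 maps to 0 on
    the y axis.  Plot rendering is left to the CLI layer.
    """
    q = dam.table["q"].to_numpy()
    return pd.DataFrame(
        {
            "feature_id": dam.table.index,
            "log2_fc": dam.table["log2_fc"].to_numpy(),
            "neg_log10_q": -np.log10(np.maximum(q, 1e-300)),
            "is_dam": dam.table["is_dam"].to_numpy(),
        }
    ).reset_index(drop=True)
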