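"""Detection-system stability from pooled-QC injections.

A pooled QC extract injected periodically should give near-identical
profiles; pairwise Pearson correlation between QC injections near 1
(conventionally >= 0.99) indicates a stable run.  Correlation is computed on
log10 intensities, matching the multiplicative nature of LC-MS drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .tables import AbundanceMatrix

__all__ = ["QCReport", "qc_stability"]


@dataclass
class QCReport:
    """Pairwise QC correlations and the pass/fail verdict at a threshold."""

    qc_sample_ids: list[str]
    pcc: pd.DataFrame  # symmetric, unit diagonal
    min_pcc: float
    threshold: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "qc_sample_ids": self.qc_sample_ids,
            "min_pcc": self.min_pcc,
            "threshold": self.threshold,
            "passed": self.passed,
            "pcc": {
                a: {b: float(self.pcc.loc[a, b]) for b in self.qc_sample_ids}
                for a in self.qc_sample_ids
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def qc_stability(matrix: AbundanceMatrix, threshold: float = 0.99) -> QCReport:
    """Pearson correlation between every pair of pooled-QC injections.

    The run passes when the minimum pairwise PCC (log10 intensities) meets
    ``threshold``.  Requires at least two samples flagged ``is_qc``.
    """
    qc_vals = matrix.qc()
    if qc_vals.shape[0] < 2:
        raise InsufficientDataError(
            f"need >= 2 QC samples, found {qc_vals.shape[0]}"
        )
    log_vals = np.log10(qc_vals.to_numpy())
    corr = np.corrcoef(log_vals)
    ids = list(qc_vals.index)
    pcc = pd.DataFrame(corr, index=ids, columns=ids)
    off = corr[~np.eye(len(ids), dtype=bool)]
    min_pcc = float(off.min())
    return QCReport(
        qc_sample_ids=ids,
        pcc=pcc,
        min_pcc=min_pcc,
        threshold=threshold,
        passed=bool(min_pcc >= threshold),
    )
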