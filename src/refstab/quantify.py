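"""Ct to relative-quantity transform (the delta-Ct / geNorm convention).

Each gene is re-expressed as Q = E**(minCt - Ct) where E is the assay's
amplification factor (2.0 at 100% efficiency) and minCt the gene's minimum
mean Ct over the analysis samples, so the most-expressed sample has Q = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_io import AggregatedCt

EFFICIENCY_MIN = 1.5
EFFICIENCY_MAX = 2.2


@dataclass
class QuantityMatrix:
    """Per-gene relative quantities in (0, 1], calibrated to the most-expressed sample.

    ``q`` is a genes x samples frame; ``efficiency`` the per-gene amplification
    factor used in the transform.
    """

    q: pd.DataFrame
    efficiency: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)

    def to_sample_matrix(self) -> pd.DataFrame:
        """Samples x genes orientation for the estimator API."""
        return self.q.T


def _efficiency_series(efficiency, genes: list[str]) -> pd.Series:
    if np.isscalar(efficiency):
        eff = pd.Series(float(efficiency), index=genes)
    else:
        eff = pd.Series(efficiency, dtype=float).reindex(genes)
        if eff.isna().any():
            missing = list(eff.index[eff.isna()])
            raise ValueError(f"no efficiency supplied for gene(s): {missing}")
    bad = eff[(eff < EFFICIENCY_MIN) | (eff > EFFICIENCY_MAX)]
    if len(bad):
        raise ValueError(
            f"amplification factor out of [{EFFICIENCY_MIN}, {EFFICIENCY_MAX}] "
            f"for gene(s): {list(bad.index)}"
        )
    return eff


def relative_quantities(agg: AggregatedCt, efficiency=2.0) -> QuantityMatrix:
    """Transform aggregated Ct into relative quantities Q = E**(minCt - Ct).

    Requires a complete matrix; run :func:`refstab.ct_io.build_analysis_set`
    first to obtain complete-case data for an analysis set.
    """
    if agg.mean_ct.isna().any().any():
        raise ValueError(
            "aggregated Ct matrix contains missing wells; "
            "use build_analysis_set to obtain a complete-case analysis set first"
        )
    eff = _efficiency_series(efficiency, agg.genes)
    min_ct = agg.mean_ct.min(axis=1)
    exponent = agg.mean_ct.rsub(min_ct, axis=0)
    q = pd.DataFrame(
        np.power(eff.to_numpy()[:, None], exponent.to_numpy()),
        index=agg.mean_ct.index,
        columns=agg.mean_ct.columns,
    )
    return QuantityMatrix(q=q, efficiency=eff)


def log2_expression(qm: QuantityMatrix) -> pd.DataFrame:
    """Elementwise log2 of the relative quantities (max 0 per gene)."""
    if (qm.q <= 0).any().any():
        raise ValueError("relative quantities must be strictly positive")
    return np.log2(qm.q)
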