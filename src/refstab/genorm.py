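"""geNorm reference-gene stability: M values, iterative elimination, V(n/n+1).

The stability measure M of a candidate gene is the mean, over all other
candidates, of the sample SD of the pairwise log2 expression ratio.  The
least stable gene (largest M) is eliminated and M recomputed until two genes
remain, yielding a stability ranking.  The normalisation factor NF_n is the
per-sample geometric mean of the n most stable genes' relative quantities,
and V(n/n+1) — the SD over samples of log2(NF_n / NF_{n+1}) — decides how
many reference genes are needed: the smallest n with V below a cut-off
(0.15 by convention) suffices.

All statistics use the n-1 (sample) SD and are invariant to per-gene scaling
of the quantities, so any positive expression matrix may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .quantify import QuantityMatrix

DEFAULT_V_THRESHOLD = 0.15
DEFAULT_M_THRESHOLD = 1.0


def _as_quantity_array(X) -> tuple[np.ndarray, list[str]]:
    """Validate a samples x genes positive matrix, returning (array, gene names)."""
    if isinstance(X, pd.DataFrame):
        genes = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples x genes matrix")
        genes = [f"g{i}" for i in range(arr.shape[1])]
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x genes matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError("expression matrix contains non-finite values")
    if np.any(arr <= 0):
        raise ValueError("relative quantities must be strictly positive")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names in input")
    return arr, genes


def _pairwise_sd(L: np.ndarray) -> np.ndarray:
    """Matrix of sample SDs of log-ratio columns: V[j, k] = SD_s(L[s,j] - L[s,k])."""
    diffs = L[:, :, None] - L[:, None, :]
    return diffs.std(axis=0, ddof=1)


class GeNorm(TransformerMixin, BaseEstimator):
    """geNorm stability ranking and reference-gene count selection.

    Fit on a samples x genes matrix of strictly positive relative quantities
    (a DataFrame supplies gene names).  ``transform`` divides each sample by
    its normalisation factor, i.e. returns quantities normalised by the
    geometric mean of the selected reference genes.

    Parameters
    ----------
    v_threshold : float, default 0.15
        Pairwise-variation cut-off below which adding another reference gene
        is considered unnecessary.
    m_threshold : float, default 1.0
        M value below which a gene is called stable in a heterogeneous
        sample set.
    n_select : int or None
        Number of reference genes used by ``transform``; ``None`` defers to
        the fitted ``optimal_n_`` (or, if no V drops below the threshold, to
        the advisory minimum-V position).

    Attributes
    ----------
    genes_ : list of str
    elimination_order_ : list of str, least stable first.
    final_ranking_ : list of str, most stable first; the first two are tied.
    ranks_ : dict gene -> rank (competition ranking, the top pair both rank 1).
    m_values_ : pd.Series, each gene's M at the iteration of its elimination
        (for the final pair: their M in the two-gene set).
    m_trace_ : list of pd.Series, M of every active gene per iteration.
    stable_genes_ : list of genes with ``m_values_`` <= ``m_threshold``.
    v_series_ : list of (n, V(n/n+1)) for n = 2 .. K-1.
    optimal_n_ : int or None, smallest n with V < v_threshold.
    min_v_n_ : int, the n with the smallest V (advisory when optimal_n_ is None).
    tie_events_ : list of str, deterministic tie-breaks taken at elimination.
    """

    def __init__(
        self,
        v_threshold: float = DEFAULT_V_THRESHOLD,
        m_threshold: float = DEFAULT_M_THRESHOLD,
        n_select: int | None = None,
    ):
        self.v_threshold = v_threshold
        self.m_threshold = m_threshold
        self.n_select = n_select

    def fit(self, X, y=None):
        if self.v_threshold <= 0 or self.m_threshold <= 0:
            raise ValueError("thresholds must be positive")
        arr, genes = _as_quantity_array(X)
        n_samples, n_genes = arr.shape
        if n_genes < 3:
            raise ValueError("geNorm ranking requires at least 3 genes")
        if n_samples < 2:
            raise ValueError("geNorm requires at least 2 samples")

        L = np.log2(arr)
        active = list(range(n_genes))
        elimination: list[int] = []
        m_trace: list[pd.Series] = []
        headline_m: dict[str, float] = {}
        tie_events: list[str] = []

        while len(active) > 2:
            V = _pairwise_sd(L[:, active])
            M = V.sum(axis=1) / (len(active) - 1)
            m_trace.append(pd.Series(M, index=[genes[i] for i in active]))
            m_max = M.max()
            worst = [active[i] for i in range(len(active)) if M[i] == m_max]
            if len(worst) > 1:
                # deterministic tie-break: lexicographically last symbol goes first
                victim = max(worst, key=lambda i: genes[i])
                tie_events.append(
                    f"elimination tie at M={m_max:.6g} among "
                    f"{sorted(genes[i] for i in worst)}; removed {genes[victim]}"
                )
            else:
                victim = worst[0]
            headline_m[genes[victim]] = float(M[active.index(victim)])
            elimination.append(victim)
            active.remove(victim)

        pair_m = float(_pairwise_sd(L[:, active])[0, 1])
        m_trace.append(pd.Series(pair_m, index=[genes[i] for i in active]))
        for i in active:
            headline_m[genes[i]] = pair_m

        top_pair = sorted(genes[i] for i in active)
        self.genes_ = genes
        self.n_features_in_ = n_genes
        self.elimination_order_ = [genes[i] for i in elimination]
        self.final_ranking_ = top_pair + [genes[i] for i in reversed(elimination)]
        self.ranks_ = {g: (1 if g in top_pair else r + 1) for r, g in enumerate(self.final_ranking_)}
        self.m_values_ = pd.Series(headline_m).loc[self.final_ranking_]
        self.m_trace_ = m_trace
        self.stable_genes_ = [g for g in self.final_ranking_ if headline_m[g] <= self.m_threshold]
        self.tie_events_ = tie_events

        gene_col = {g: i for i, g in enumerate(genes)}
        order = [gene_col[g] for g in self.final_ranking_]
        # log2 NF_n is the running mean of the ranked genes' log2 quantities
        cum = np.cumsum(L[:, order], axis=1)
        log_nf = cum / np.arange(1, n_genes + 1)
        v_series = []
        for n in range(2, n_genes):
            v = float((log_nf[:, n - 1] - log_nf[:, n]).std(ddof=1))
            v_series.append((n, v))
        self.v_series_ = v_series
        below = [n for n, v in v_series if v < self.v_threshold]
        self.optimal_n_ = below[0] if below else None
        self.min_v_n_ = min(v_series, key=lambda t: t[1])[0]
        return self

    def _selected_n(self) -> int:
        if self.n_select is not None:
            n = int(self.n_select)
            if not 2 <= n <= self.n_features_in_:
                raise ValueError(f"n_select must lie in [2, {self.n_features_in_}]")
            return n
        return self.optimal_n_ if self.optimal_n_ is not None else self.min_v_n_

    def normalization_factors(self, X, n: int | None = None) -> np.ndarray:
        """Per-sample NF_n: geometric mean of the n top-ranked genes' quantities."""
        arr, genes = _as_quantity_array(X)
        n = self._selected_n() if n is None else int(n)
        if not 2 <= n <= len(self.final_ranking_):
            raise ValueError(f"n must lie in [2, {len(self.final_ranking_)}]")
        name_to_col = {g: i for i, g in enumerate(genes)}
        try:
            cols = [name_to_col[g] for g in self.final_ranking_[:n]]
        except KeyError as exc:
            raise ValueError(f"gene {exc.args[0]!r} not present in X") from None
        return np.exp2(np.log2(arr[:, cols]).mean(axis=1))

    def transform(self, X):
        """Divide each sample's quantities by its fitted normalisation factor."""
        arr, _ = _as_quantity_array(X)
        nf = self.normalization_factors(X)
        out = arr / nf[:, None]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


@dataclass
class GeNormResult:
    """Full output of the geNorm ranking and reference-count analysis."""

    elimination_order: list[str]
    m_trace: list[pd.Series]
    final_ranking: list[str]
    ranks: dict[str, int]
    m_values: pd.Series
    stable_genes: list[str]
    v_series: list[tuple[int, float]]
    optimal_n: int | None
    min_v_n: int
    threshold: float = DEFAULT_V_THRESHOLD
    m_threshold: float = DEFAULT_M_THRESHOLD
    tie_events: list[str] = field(default_factory=list)

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.final_ranking,
                "rank": [self.ranks[g] for g in self.final_ranking],
                "m_value": [self.m_values[g] for g in self.final_ranking],
                "stable": [g in set(self.stable_genes) for g in self.final_ranking],
            }
        )

    def v_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [n for n, _ in self.v_series],
                "v": [v for _, v in self.v_series],
                "below_threshold": [v < self.threshold for _, v in self.v_series],
            }
        )


def pairwise_variation(qm: QuantityMatrix, gene_j: str, gene_k: str) -> float:
    """Sample SD over samples of log2(q_j / q_k), symmetric in its arguments."""
    if len(qm.samples) < 2:
        raise ValueError("pairwise variation needs at least 2 samples")
    ratio = np.log2(qm.q.loc[gene_j] / qm.q.loc[gene_k])
    return float(ratio.std(ddof=1))


def m_values(qm: QuantityMatrix, active_genes: list[str] | None = None) -> pd.Series:
    """M_j = mean over other active genes k of the pairwise variation V_jk."""
    genes = list(qm.genes) if active_genes is None else list(active_genes)
    if len(genes) < 2:
        raise ValueError("M values need at least 2 genes")
    L = np.log2(qm.q.loc[genes].T.to_numpy(dtype=float))
    V = _pairwise_sd(L)
    return pd.Series(V.sum(axis=1) / (len(genes) - 1), index=genes)


def rank_genes(
    qm: QuantityMatrix,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    m_threshold: float = DEFAULT_M_THRESHOLD,
) -> GeNormResult:
    """Run the full geNorm analysis on a quantity matrix."""
    est = GeNorm(v_threshold=v_threshold, m_threshold=m_threshold)
    est.fit(qm.to_sample_matrix())
    return GeNormResult(
        elimination_order=est.elimination_order_,
        m_trace=est.m_trace_,
        final_ranking=est.final_ranking_,
        ranks=est.ranks_,
        m_values=est.m_values_,
        stable_genes=est.stable_genes_,
        v_series=est.v_series_,
        optimal_n=est.optimal_n_,
        min_v_n=est.min_v_n_,
        threshold=v_threshold,
        m_threshold=m_threshold,
        tie_events=est.tie_events_,
    )


def normalization_factor(qm: QuantityMatrix, ranking: list[str], n: int) -> pd.Series:
    """NF_n per sample: geometric mean of the n top-ranked genes' quantities."""
    if not 2 <= n <= len(ranking):
        raise ValueError(f"n must lie in [2, {len(ranking)}]")
    top = ranking[:n]
    log_nf = np.log2(qm.q.loc[top]).mean(axis=0)
    return np.exp2(log_nf).rename(f"NF_{n}")


def v_series_and_optimal_n(
    qm: QuantityMatrix,
    ranking: list[str],
    threshold: float = DEFAULT_V_THRESHOLD,
) -> tuple[list[tuple[int, float]], int | None]:
    """V(n/n+1) for n = 2 .. K-1 and the smallest n with V below the cut-off."""
    K = len(ranking)
    if K < 3:
        raise ValueError("the V series needs at least 3 ranked genes")
    series = []
    for n in range(2, K):
        ratio = np.log2(normalization_factor(qm, ranking, n) / normalization_factor(qm, ranking, n + 1))
        series.append((n, float(ratio.std(ddof=1))))
    below = [n for n, v in series if v < threshold]
    return series, (below[0] if below else None)
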