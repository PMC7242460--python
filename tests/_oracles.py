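"""Independent brute-force oracles, written straight from the definitions.

These deliberately use plain Python loops and the statistics module rather
than the package's vectorised code paths, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math
import statistics


def brute_pairwise_v(q: dict[str, list[float]], j: str, k: str) -> float:
    """Sample SD of the per-sample log2 ratio of two genes' quantities."""
    ratios = [math.log2(a / b) for a, b in zip(q[j], q[k])]
    return statistics.stdev(ratios)


def brute_m(q: dict[str, list[float]], active: list[str]) -> dict[str, float]:
    """M_j as the plain average of pairwise variations with every other gene."""
    out = {}
    for j in active:
        vs = [brute_pairwise_v(q, j, k) for k in active if k != j]
        out[j] = sum(vs) / len(vs)
    return out


def brute_elimination(q: dict[str, list[float]]) -> tuple[list[dict[str, float]], list[str]]:
    """Full elimination trace by direct recomputation at every step.

    Tie rule: the lexicographically last symbol among maximal-M genes goes
    first.  Returns (per-iteration M maps, elimination order).
    """
    active = list(q)
    trace, order = [], []
    while len(active) > 2:
        m = brute_m(q, active)
        trace.append(dict(m))
        m_max = max(m.values())
        victim = max([g for g in active if m[g] == m_max])
        order.append(victim)
        active.remove(victim)
    pair_v = brute_pairwise_v(q, active[0], active[1])
    trace.append({active[0]: pair_v, active[1]: pair_v})
    return trace, order


def brute_nf(q: dict[str, list[float]], genes: list[str]) -> list[float]:
    """Per-sample geometric mean of the listed genes' quantities."""
    n_samples = len(next(iter(q.values())))
    return [
        math.exp2(sum(math.log2(q[g][s]) for g in genes) / len(genes))
        for s in range(n_samples)
    ]


def brute_v_series(q: dict[str, list[float]], ranking: list[str]) -> list[tuple[int, float]]:
    series = []
    for n in range(2, len(ranking)):
        nf_n = brute_nf(q, ranking[:n])
        nf_n1 = brute_nf(q, ranking[: n + 1])
        ratios = [math.log2(a / b) for a, b in zip(nf_n, nf_n1)]
        series.append((n, statistics.stdev(ratios)))
    return series


def brute_best_pair(d_hat, sigma2, tau2, n_g):
    """Exhaustive pair enumeration from the fitted components.

    ``d_hat`` and ``sigma2`` map gene -> list over groups; ``n_g`` is the list
    of group sizes.
    """
    genes = list(d_hat)
    best, best_val = None, math.inf
    for a, b in itertools.combinations(genes, 2):
        rhos = []
        for gi, n in enumerate(n_g):
            d = (d_hat[a][gi] + d_hat[b][gi]) / 2.0
            s = (sigma2[a][gi] + sigma2[b][gi]) / 4.0
            if tau2 == 0.0:
                rhos.append(0.0)
                continue
            w = tau2 / (tau2 + s / n)
            rhos.append(abs(d * w) + math.sqrt((s / n) * w))
        val = sum(rhos) / len(rhos)
        if val < best_val:
            best, best_val = (a, b), val
    return best, best_val
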