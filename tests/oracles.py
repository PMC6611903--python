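"""Independent naive recomputations used to cross-check the implementation.

Everything here is written with explicit loops straight from the definitions,
deliberately sharing no code with the package.
"""

import math

import numpy as np


def sd(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def v_matrix_naive(log2rq: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    genes = list(log2rq)
    out = {}
    for j in genes:
        for k in genes:
            if j == k:
                out[(j, k)] = 0.0
            else:
                out[(j, k)] = sd([a - b for a, b in zip(log2rq[j], log2rq[k])])
    return out


def m_values_naive(log2rq: dict[str, list[float]]) -> dict[str, float]:
    v = v_matrix_naive(log2rq)
    genes = list(log2rq)
    return {j: sum(v[(j, k)] for k in genes if k != j) / (len(genes) - 1) for j in genes}


def v_n_naive(rq_ranked: list[list[float]], n: int) -> float:
    """V(n/n+1) from first principles: SD of log2(NF_n / NF_{n+1})."""
    n_samples = len(rq_ranked[0])
    diffs = []
    for s in range(n_samples):
        nf_n = math.prod(rq_ranked[g][s] for g in range(n)) ** (1.0 / n)
        nf_n1 = math.prod(rq_ranked[g][s] for g in range(n + 1)) ** (1.0 / (n + 1))
        diffs.append(math.log2(nf_n / nf_n1))
    return sd(diffs)


def bestkeeper_index_naive(cq: dict[str, list[float]]) -> list[float]:
    genes = list(cq)
    n = len(cq[genes[0]])
    return [math.prod(cq[g][s] for g in genes) ** (1.0 / len(genes)) for s in range(n)]


def pearson_naive(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def gm_rank_naive(ranks: list[float]) -> float:
    return math.prod(ranks) ** (1.0 / len(ranks))


def delta_ct_naive(cq: dict[str, list[float]]) -> dict[str, float]:
    genes = list(cq)
    out = {}
    for j in genes:
        sds = [sd([a - b for a, b in zip(cq[j], cq[k])]) for k in genes if k != j]
        out[j] = sum(sds) / len(sds)
    return out


def two_way_residual_variance_naive(y: np.ndarray) -> list[float]:
    """Per-row residual variance of the double-centered matrix (n-1 denominator)."""
    k, n = y.shape
    out = []
    for i in range(k):
        resid = []
        for j in range(n):
            r = y[i, j] - y[i, :].mean() - y[:, j].mean() + y.mean()
            resid.append(r)
        out.append(sum(x**2 for x in resid) / (n - 1))
    return out
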