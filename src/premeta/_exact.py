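"""Exact conditional test for 2 x K contingency tables.

Used by the category-composition comparison, where the table has two rows
(inside / outside a gene set) and up to four columns (the roll-up marker
categories).  The p-value is the Fisher-style sum of the probabilities of
all tables with the observed margins whose multivariate hypergeometric
probability does not exceed the observed table's.

Enumeration runs over compositions of the first-row total across columns
(bounded by the column margins); the last two free coordinates are
vectorised.  When the composition space is too large for exact enumeration a
seeded Monte Carlo estimate over margin-preserving tables is returned
instead (flagged in the result).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["exact_2xk_test"]

_TIE_TOL = 1e-9
_MAX_EXACT_WORK = 2e7
_MC_SAMPLES = 200_000


def _log_choose(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def exact_2xk_test(row1, row2, rng: np.random.Generator | None = None) -> dict:
    """Exact test of homogeneity for a 2 x K table.

    Parameters
    ----------
    row1, row2 : sequences of non-negative ints (the two rows)
    rng : Generator used only if the Monte Carlo fallback triggers.

    Returns a dict with ``p``, ``method`` ('exact' or 'montecarlo') and the
    (zero-margin-dropped) table.  Columns whose margin is zero are dropped;
    with fewer than two remaining columns, or an empty row, ``p`` is 1.
    """
    r1 = np.asarray(row1, dtype=np.int64)
    r2 = np.asarray(row2, dtype=np.int64)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rows must be equal-length 1-d count vectors")
    if (r1 < 0).any() or (r2 < 0).any():
        raise ValueError("counts must be non-negative")
    m = r1 + r2
    keep = m > 0
    r1, r2, m = r1[keep], r2[keep], m[keep]
    k = len(m)
    total = int(m.sum())
    r_tot = int(r1.sum())
    result_table = np.vstack([r1, r2])
    if k < 2 or r_tot == 0 or r_tot == total:
        return {"p": 1.0, "method": "degenerate", "table": result_table}

    log_denom = _log_choose(total, r_tot)
    obs_logp = float(_log_choose(m, r1).sum() - log_denom)

    # feasible value counts per column bound the enumeration
    caps = np.minimum(m, r_tot)
    work = float(np.prod(caps[:-1] + 1.0)) if k > 1 else 1.0
    if work > _MAX_EXACT_WORK:
        return _montecarlo(m, r_tot, obs_logp, result_table, rng)

    # per-column log C(m_j, r) lookup for r = 0..caps[j]
    tables = [_log_choose(m[j], np.arange(caps[j] + 1)) for j in range(k)]

    passing: list[np.ndarray] = []

    def recurse(j: int, remaining: int, acc: float) -> None:
        lo = max(0, remaining - int(m[j + 1 :].sum()))
        hi = min(int(caps[j]), remaining)
        if lo > hi:
            return
        if j == k - 2:
            r = np.arange(lo, hi + 1)
            last = remaining - r
            ok = last <= m[k - 1]
            r = r[ok]
            last = last[ok]
            logp = acc + tables[j][r] + tables[k - 1][last] - log_denom
            sel = logp <= obs_logp + _TIE_TOL
            if sel.any():
                passing.append(logp[sel])
            return
        for r in range(lo, hi + 1):
            recurse(j + 1, remaining - r, acc + tables[j][r])

    recurse(0, r_tot, 0.0)
    p = float(np.exp(logsumexp(np.concatenate(passing))))
    return {"p": min(p, 1.0), "method": "exact", "table": result_table}


def _montecarlo(m, r_tot, obs_logp, table, rng) -> dict:
    if rng is None:
        rng = np.random.default_rng(0)
    k = len(m)
    n = _MC_SAMPLES
    draws = np.empty((n, k), dtype=np.int64)
    remaining = np.full(n, r_tot, dtype=np.int64)
    pool = int(m.sum())
    for j in range(k - 1):
        pool -= int(m[j])
        draws[:, j] = rng.hypergeometric(m[j], pool, remaining)
        remaining -= draws[:, j]
    draws[:, -1] = remaining
    logp = _log_choose(m[None, :], draws).sum(axis=1) - _log_choose(int(m.sum()), r_tot)
    p = float((logp <= obs_logp + _TIE_TOL).mean())
    return {"p": max(p, 1.0 / n), "method": "montecarlo", "table": table}
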