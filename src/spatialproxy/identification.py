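"""Numeric check of the row-deletion factor-identification condition.

The loading matrix ``Lambda = alpha_wu @ Sigma^{1/2}`` (``p x q``) must,
after deletion of any single row, still contain two disjoint row subsets
each of numerical rank ``q``.  This is the classic Anderson-Rubin
sufficient condition for identification of a factor model up to rotation;
a practical rule of thumb is that every factor needs at least three
informative proxies.
"""

from __future__ import annotations

import dataclasses

import numpy as np

MAX_P = 16  # exhaustive bipartition search is exponential in p


@dataclasses.dataclass
class Assumption5Result:
    satisfied: bool
    detail: dict

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.satisfied


def check_assumption5(alpha_wu, sigma_u=None, tol: float = 1e-8) -> Assumption5Result:
    """Check the row-deletion rank condition on ``Lambda = alpha_wu Sigma^{1/2}``.

    Parameters
    ----------
    alpha_wu
        ``p x q`` loading matrix.
    sigma_u
        Optional factor covariance (diagonal or full, ``q x q``); identity
        when omitted.
    tol
        Relative singular-value tolerance for numerical rank.
    """
    A = np.atleast_2d(np.asarray(alpha_wu, dtype=float))
    if A.ndim != 2:
        raise ValueError("alpha_wu must be a p x q matrix")
    p, q = A.shape
    if sigma_u is not None:
        S = np.asarray(sigma_u, dtype=float)
        if S.ndim == 1:
            S = np.diag(S)
        w, V = np.linalg.eigh(S)
        if np.any(w < -tol):
            raise ValueError("sigma_u must be positive semidefinite")
        lam = A @ (V * np.sqrt(np.clip(w, 0, None))) @ V.T
    else:
        lam = A
    if p < 2 * q + 1:
        return Assumption5Result(False, {"reason": f"p={p} < 2q+1={2*q+1}: condition unsatisfiable"})
    if p > MAX_P:
        raise ValueError(f"exhaustive check limited to p <= {MAX_P}")

    scale = max(np.abs(lam).max(), tol)
    rank_of = {}
    for mask in range(1, 1 << p):
        rows = [i for i in range(p) if mask >> i & 1]
        if len(rows) < q:
            rank_of[mask] = len(rows) and int(np.linalg.matrix_rank(lam[rows], tol=tol * scale))
            continue
        rank_of[mask] = int(np.linalg.matrix_rank(lam[rows], tol=tol * scale))

    full = (1 << p) - 1
    detail = {}
    ok = True
    for d in range(p):
        remaining = full & ~(1 << d)
        found = None
        sub = remaining
        # iterate over nonempty proper submasks of `remaining`
        s = remaining
        while s:
            comp = remaining & ~s
            if comp and rank_of.get(s, 0) >= q and rank_of.get(comp, 0) >= q:
                found = ([i for i in range(p) if s >> i & 1],
                         [i for i in range(p) if comp >> i & 1])
                break
            s = (s - 1) & remaining
        detail[d] = found
        if found is None:
            ok = False
    return Assumption5Result(ok, detail)
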