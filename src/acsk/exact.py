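"""Brute-force oracles for k-mismatch longest common prefixes and exact
λ_k arrays.

These are the ground truth the heuristics are measured against.  The
per-pair walk (`lcp_k_walk`) is a direct character comparison; the full
λ_k computation scans every alignment diagonal of the X×Y comparison
matrix with vectorized mismatch bookkeeping, so exact values at
desk scale (|X|·|Y| up to ~10^7) are cheap.  The published sub-quadratic
exact algorithm is intentionally not implemented here.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .errors import BoundsError, ParameterError, SizeError
from .seqio import SequenceRecord

#: Default cap on character comparisons for the quadratic oracle.
ORACLE_CAP = 10_000_000


def lcp_k_walk(x: SequenceRecord, y: SequenceRecord, i: int, j: int, k: int) -> int:
    """Longest common prefix of X_i and Y_j allowing at most *k* mismatches.

    0-based *i*, *j*.  Walks both strings until the (k+1)-th mismatch or
    either end; the returned length never exceeds min(|X|-i, |Y|-j).
    """
    if k < 0:
        raise ParameterError("mismatch budget k must be >= 0")
    xs, ys = x.residues, y.residues
    if not 0 <= i < len(xs):
        raise BoundsError(f"position i={i} out of range for |X|={len(xs)}")
    if not 0 <= j < len(ys):
        raise BoundsError(f"position j={j} out of range for |Y|={len(ys)}")
    budget = k
    length = 0
    limit = min(len(xs) - i, len(ys) - j)
    while length < limit:
        if xs[i + length] != ys[j + length]:
            if budget == 0:
                break
            budget -= 1
        length += 1
    return length


def _lambda_many(x: SequenceRecord, y: SequenceRecord, ks: Iterable[int],
                 cap: int = ORACLE_CAP) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Exact λ_k values and smallest-j witnesses for several budgets at once.

    One pass over the |X|+|Y|-1 alignment diagonals: on each diagonal the
    mismatch positions are found vectorized, and for every start offset the
    k-mismatch length is the distance to the (k+1)-th following mismatch (or
    the diagonal end).  Diagonals are visited in ascending j-i order with
    strictly-greater updates, which makes each witness the smallest attaining
    j.  Returns {k: (values, witnesses)}; witness -1 where λ_k = 0.
    """
    ks = sorted(set(int(k) for k in ks))
    if any(k < 0 for k in ks):
        raise ParameterError("mismatch budget k must be >= 0")
    m, ny = len(x.residues), len(y.residues)
    if m * ny > cap:
        raise SizeError(
            f"|X|*|Y| = {m * ny} exceeds the oracle cap of {cap} character "
            "comparisons; use one of the heuristic methods instead"
        )
    xa = np.frombuffer(x.residues.encode("latin-1"), dtype=np.uint8)
    ya = np.frombuffer(y.residues.encode("latin-1"), dtype=np.uint8)
    vals = {k: np.zeros(m, dtype=np.int64) for k in ks}
    wits = {k: np.full(m, -1, dtype=np.int64) for k in ks}
    for d in range(-(m - 1), ny):
        i0 = max(0, -d)
        j0 = i0 + d
        length = min(m - i0, ny - j0)
        if length <= 0:
            continue
        neq = xa[i0 : i0 + length] != ya[j0 : j0 + length]
        mis = np.nonzero(neq)[0]
        before = np.cumsum(neq) - neq  # mismatches strictly before each offset
        offs = np.arange(length)
        for k in ks:
            if len(mis) == 0:
                lam = length - offs
            else:
                idx = before + k
                inside = idx < len(mis)
                lam = np.where(inside,
                               mis[np.minimum(idx, len(mis) - 1)] - offs,
                               length - offs)
            v = vals[k][i0 : i0 + length]
            w = wits[k][i0 : i0 + length]
            better = lam > v
            w[better] = (offs + j0)[better]
            v[better] = lam[better]
    return {k: (vals[k], wits[k]) for k in ks}


def exact_lambda(x: SequenceRecord, y: SequenceRecord, k: int,
                 cap: int = ORACLE_CAP):
    """Exact λ_k array of *x* against *y* with smallest-j witnesses.

    Returns a :class:`~acsk.heuristics.LambdaApprox` tagged ``method="exact"``.
    Raises :class:`SizeError` when |X|·|Y| exceeds *cap*.
    """
    from .heuristics import LambdaApprox  # local import: avoids a cycle

    values, witnesses = _lambda_many(x, y, [k], cap=cap)[k]
    return LambdaApprox(method="exact", k=int(k), values=values,
                        witnesses=witnesses, options=None,
                        diagnostics={"oracle": "diagonal-scan"})
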