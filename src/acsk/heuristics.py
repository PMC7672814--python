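"""λ_k approximation heuristics: kmacs, ALFRED-G, and the two-phase
forward/backward extension method (adyar).

All three estimate, for every position i of X, the length of the longest
common substring starting at X_i that matches somewhere in Y with at most k
mismatches (λ_k(i)), from which the k-mismatch average common substring
ACS_k follows as the positional mean.

* **kmacs** anchors on the longest exact match from i and extends it forward
  through k mismatches.
* **ALFRED-G** anchors on the longest 1-mismatch match (computed here by the
  exact quadratic oracle) and extends forward through the remaining budget.
* **adyar** extends every maximal exact anchor both forward and backward,
  splitting the mismatch budget between the two directions, credits each of
  the k+1 resulting start positions, and finishes with a left-to-right pass
  propagating the fact that dropping the first character of a valid match
  leaves a valid match one shorter.

With the LCP-0 fallback disabled, every reported value is the length of a
genuine ≤k-mismatch common substring (a lower bound on exact λ_k) with a
verifiable witness position in Y.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import BoundsError, ParameterError, ValidationError
from .exact import ORACLE_CAP, _lambda_many, lcp_k_walk
from .index import GeneralizedIndex, MatchingStatistics
from .seqio import SequenceRecord

METHODS = ("adyar", "kmacs", "alfredg", "exact")


@dataclass(frozen=True)
class Options:
    """Heuristic evaluation options.

    tie_policy
        ``"all"`` extends every maximal anchor position and keeps the longest
        result (the default); ``"first"`` uses only the smallest attaining j,
        emulating single-anchor behaviour.
    fallback
        When True, positions whose exact anchor LCP is 0 inherit the estimate
        of the following position (a right-to-left pass).  This mirrors the
        production pipeline but the inherited values carry no witness.
    anchor_limit
        Optional cap on the anchors enumerated per position (ascending j).
    guarded_phase2
        Restrict the propagation pass to positions that are not the mismatch
        character of the preceding match (fidelity experiments only; the
        default unguarded pass is never unsound).
    lcp_policy
        ``"walk"`` | ``"rmq"`` | ``"hybrid"`` — internal LCP evaluation route;
        never changes any returned value.
    """

    tie_policy: str = "all"
    fallback: bool = True
    anchor_limit: int | None = None
    guarded_phase2: bool = False
    lcp_policy: str = "hybrid"

    def __post_init__(self) -> None:
        if self.tie_policy not in ("all", "first"):
            raise ParameterError(f"unknown tie policy {self.tie_policy!r}")


@dataclass
class LambdaApprox:
    """A per-position λ_k estimate for one method.

    ``values[i]`` estimates λ_k(i) (0-based i).  ``witnesses[i]`` is a start
    position in Y from which a ≤k-mismatch match of at least ``values[i]``
    characters begins, or -1 when no witness is tracked (λ=0, or a value
    inherited by the fallback pass).
    """

    method: str
    k: int
    values: np.ndarray
    witnesses: np.ndarray | None
    options: Options | None
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


class PairContext:
    """Shared per-pair state: forward/reverse indexes and matching statistics.

    Build once per ordered (X, Y) pair and hand to several heuristic calls to
    avoid re-indexing.  The reverse index is built lazily (kmacs never needs
    it).
    """

    def __init__(self, x: SequenceRecord, y: SequenceRecord,
                 anchor_limit: int | None = None) -> None:
        self.x = x
        self.y = y
        self.fwd = GeneralizedIndex(x, y, orientation="forward")
        self._rev: GeneralizedIndex | None = None
        self.ms: MatchingStatistics = self.fwd.matching_statistics(anchor_limit=anchor_limit)

    @property
    def rev(self) -> GeneralizedIndex:
        if self._rev is None:
            self._rev = GeneralizedIndex(self.x, self.y, orientation="reverse")
        return self._rev


# ----------------------------------------------------------------- chains


def forward_chain(index_f: GeneralizedIndex, i: int, j: int, k: int,
                  policy: str = "hybrid") -> np.ndarray:
    """Greedy forward extension lengths L_f[0..k] from anchor (i, j).

    L_f[0] is the exact LCP of X_i and Y_j; L_f[m] extends L_f[m-1] through
    one more mismatch (one skipped character plus the following exact LCP),
    truncating at either sequence end — a mismatch is never charged past an
    end.  L_f is nondecreasing.
    """
    if index_f.orientation != "forward":
        raise ValidationError("forward_chain requires a forward index")
    if k < 0:
        raise ParameterError("mismatch budget k must be >= 0")
    nx, ny = index_f.nx, index_f.ny
    if not 0 <= i < nx:
        raise BoundsError(f"position i={i} out of range for |X|={nx}")
    if not 0 <= j < ny:
        raise BoundsError(f"position j={j} out of range for |Y|={ny}")
    lengths = np.empty(k + 1, dtype=np.int64)
    cur = index_f.lcp_xy(i, j, policy=policy)
    lengths[0] = cur
    for m in range(1, k + 1):
        if i + cur >= nx or j + cur >= ny:  # exhausted: nothing left to skip
            lengths[m] = cur
            continue
        cur += 1  # skip the mismatch character
        if i + cur < nx and j + cur < ny:
            cur += index_f.lcp_xy(i + cur, j + cur, policy=policy)
        lengths[m] = cur
    return lengths


def backward_chain(index_r: GeneralizedIndex, i: int, j: int, k: int,
                   policy: str = "hybrid") -> np.ndarray:
    """Greedy backward extension lengths L_r[0..k] from anchor (i, j).

    Identical chain semantics applied to the reversed strings, measuring
    characters strictly *before* positions i and j; L_r[m] <= min(i, j).
    """
    if index_r.orientation != "reverse":
        raise ValidationError("backward_chain requires a reverse index")
    nx, ny = index_r.nx, index_r.ny
    if not 0 <= i < nx:
        raise BoundsError(f"position i={i} out of range for |X|={nx}")
    if not 0 <= j < ny:
        raise BoundsError(f"position j={j} out of range for |Y|={ny}")
    if k < 0:
        raise ParameterError("mismatch budget k must be >= 0")
    if i == 0 or j == 0:
        return np.zeros(k + 1, dtype=np.int64)
    # char X[i-1] is position nx-i of the reversed X (likewise for Y)
    return forward_chain_on_reverse(index_r, nx - i, ny - j, k, policy)


def forward_chain_on_reverse(index_r: GeneralizedIndex, ri: int, rj: int, k: int,
                             policy: str = "hybrid") -> np.ndarray:
    """Forward chain evaluated inside a reverse-orientation index."""
    nx, ny = index_r.nx, index_r.ny
    lengths = np.empty(k + 1, dtype=np.int64)
    cur = index_r.lcp_xy(ri, rj, policy=policy)
    lengths[0] = cur
    for m in range(1, k + 1):
        if ri + cur >= nx or rj + cur >= ny:
            lengths[m] = cur
            continue
        cur += 1
        if ri + cur < nx and rj + cur < ny:
            cur += index_r.lcp_xy(ri + cur, rj + cur, policy=policy)
        lengths[m] = cur
    return lengths


# ------------------------------------------------------------------ kmacs


def _anchors(ms: MatchingStatistics, i: int, options: Options) -> list[int]:
    js = ms.match_positions[i]
    if options.tie_policy == "first":
        return js[:1]
    return js


def _apply_fallback(values: np.ndarray, witnesses: np.ndarray, lam0: np.ndarray) -> None:
    """Right-to-left pass: positions with exact anchor LCP 0 inherit the
    estimate of the next position (no witness)."""
    for i in range(len(values) - 2, -1, -1):
        if lam0[i] == 0 and values[i + 1] > values[i]:
            values[i] = values[i + 1]
            witnesses[i] = -1


def kmacs_lambda(x: SequenceRecord, y: SequenceRecord, k: int,
                 options: Options = Options(),
                 ctx: PairContext | None = None) -> LambdaApprox:
    """kmacs estimate: exact anchor λ(i), then k greedy forward extensions.

    Realizes λ(i) + 1 + |LCP_{k-1}| iterated over the budget; with
    tie_policy="all", every maximal anchor is extended and the longest result
    kept.  k=0 reduces to the exact matching statistics.
    """
    if k < 0:
        raise ParameterError("mismatch budget k must be >= 0")
    if ctx is None:
        ctx = PairContext(x, y, anchor_limit=options.anchor_limit)
    ms = ctx.ms
    m = ctx.fwd.nx
    values = np.zeros(m, dtype=np.int64)
    witnesses = np.full(m, -1, dtype=np.int64)
    if k == 0:
        values[:] = ms.lam
        witnesses[:] = ms.mu
    else:
        for i in range(m):
            for j in _anchors(ms, i, options):
                lf_k = forward_chain(ctx.fwd, i, j, k, policy=options.lcp_policy)[k]
                if lf_k > values[i]:
                    values[i] = lf_k
                    witnesses[i] = j
    if options.fallback:
        _apply_fallback(values, witnesses, ms.lam)
    return LambdaApprox(method="kmacs", k=k, values=values, witnesses=witnesses,
                        options=options,
                        diagnostics={"mean_multiplicity": ms.mean_multiplicity})


# ---------------------------------------------------------------- ALFRED-G


def alfredg_lambda(x: SequenceRecord, y: SequenceRecord, k: int,
                   options: Options = Options(),
                   cap: int = ORACLE_CAP) -> LambdaApprox:
    """ALFRED-G estimate: exact 1-mismatch anchor λ_1(i), one skipped
    mismatch, then a (k-2)-budget walk.

    The λ_1 anchor comes from the quadratic oracle, so this method is
    restricted to oracle-cap-sized inputs.  Requires k >= 2.
    """
    if k < 2:
        raise ParameterError("ALFRED-G requires a mismatch budget k >= 2")
    lam1, mu1 = _lambda_many(x, y, [1], cap=cap)[1]
    m, ny = len(x.residues), len(y.residues)
    values = np.zeros(m, dtype=np.int64)
    witnesses = np.full(m, -1, dtype=np.int64)
    for i in range(m):
        l1 = int(lam1[i])
        j = int(mu1[i])
        if j < 0:
            continue
        ni, nj = i + l1, j + l1
        if ni >= m or nj >= ny:  # anchor ran into an end: nothing to skip
            total = l1
        else:
            total = l1 + 1
            if ni + 1 < m and nj + 1 < ny:
                total += lcp_k_walk(x, y, ni + 1, nj + 1, k - 2)
        values[i] = total
        witnesses[i] = j
    return LambdaApprox(method="alfredg", k=k, values=values,
                        witnesses=witnesses, options=options,
                        diagnostics={"anchor": "exact-lambda1"})


# ------------------------------------------------------------------ adyar


def adyar_phase1(x: SequenceRecord, y: SequenceRecord, k: int,
                 options: Options = Options(),
                 ctx: PairContext | None = None) -> LambdaApprox:
    """Phase 1: forward/backward chains from every maximal exact anchor.

    For each anchored position i and anchor j, the forward chain L_f and
    backward chain L_r share one mismatch pool: splitting the budget as t
    backward + (k-t) forward yields, for every t, a genuine ≤k-mismatch match
    of length L_r[t] + L_f[k-t] starting at position i - L_r[t] (and at
    j - L_r[t] in Y).  Each of the k+1 candidate start positions keeps its
    running maximum.  Positions never updated hold 0.
    """
    if k < 0:
        raise ParameterError("mismatch budget k must be >= 0")
    if ctx is None:
        ctx = PairContext(x, y, anchor_limit=options.anchor_limit)
    ms = ctx.ms
    m = ctx.fwd.nx
    values = np.zeros(m, dtype=np.int64)
    witnesses = np.full(m, -1, dtype=np.int64)
    fwd, rev = ctx.fwd, ctx.rev
    policy = options.lcp_policy
    for i in range(m):
        anchors = _anchors(ms, i, options)
        if not anchors:
            continue
        for j in anchors:
            lf = forward_chain(fwd, i, j, k, policy=policy)
            lr = backward_chain(rev, i, j, k, policy=policy)
            for t in range(k + 1):
                back = int(lr[t])
                s = i - back
                cand = back + int(lf[k - t])
                if cand > values[s]:
                    values[s] = cand
                    witnesses[s] = j - back
    return LambdaApprox(method="adyar", k=k, values=values, witnesses=witnesses,
                        options=options,
                        diagnostics={"mean_multiplicity": ms.mean_multiplicity,
                                     "phase": 1})


def adyar_phase2(partial: LambdaApprox, x: SequenceRecord | None = None,
                 y: SequenceRecord | None = None) -> LambdaApprox:
    """Phase 2: one left-to-right pass values[i] = max(values[i], values[i-1]-1).

    The unguarded update is always sound: removing the first character of a
    ≤k-mismatch match leaves a ≤k-mismatch match one character shorter.  With
    ``guarded_phase2`` set (and the sequences supplied), the update is skipped
    when position i is the mismatch character of the preceding witnessed
    match.
    """
    values, witnesses = partial.values, partial.witnesses
    guarded = bool(partial.options and partial.options.guarded_phase2)
    if guarded and (x is None or y is None):
        raise ValidationError("guarded phase 2 needs the sequence pair")
    for i in range(1, len(values)):
        cand = values[i - 1] - 1
        if cand <= values[i]:
            continue
        if guarded:
            w = int(witnesses[i - 1])
            if w < 0 or w + 1 >= len(y.residues) or x.residues[i] != y.residues[w + 1]:
                continue
        values[i] = cand
        witnesses[i] = witnesses[i - 1] + 1 if witnesses[i - 1] >= 0 else -1
    partial.diagnostics["phase"] = 2
    return partial


def adyar_lambda(x: SequenceRecord, y: SequenceRecord, k: int,
                 options: Options = Options(),
                 ctx: PairContext | None = None) -> LambdaApprox:
    """Two-phase forward/backward extension estimate of λ_k.

    Phase 1 credits all k+1 budget splits of every maximal anchor; phase 2
    propagates left-to-right; with fallback on, positions without any exact
    anchor (λ(i)=0) then inherit the estimate of the following position.
    """
    if ctx is None:
        ctx = PairContext(x, y, anchor_limit=options.anchor_limit)
    approx = adyar_phase1(x, y, k, options=options, ctx=ctx)
    approx = adyar_phase2(approx, x, y)
    if options.fallback:
        _apply_fallback(approx.values, approx.witnesses, ctx.ms.lam)
    return approx


# --------------------------------------------------------------- dispatch


def compute_lambda(x: SequenceRecord, y: SequenceRecord, k: int, method: str,
                   options: Options = Options(),
                   cap: int = ORACLE_CAP) -> LambdaApprox:
    """Compute a λ_k array by name: adyar | kmacs | alfredg | exact."""
    if method == "adyar":
        return adyar_lambda(x, y, k, options=options)
    if method == "kmacs":
        return kmacs_lambda(x, y, k, options=options)
    if method == "alfredg":
        return alfredg_lambda(x, y, k, options=options, cap=cap)
    if method == "exact":
        from .exact import exact_lambda

        return exact_lambda(x, y, k, cap=cap)
    raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")


def write_lambda_tsv(approx: LambdaApprox, path: str | Path) -> None:
    """Per-position dump: position (1-based), method, k, value, witness
    (1-based start in Y, or '-' when untracked)."""
    with open(path, "w") as fh:
        fh.write("position\tmethod\tk\tvalue\twitness\n")
        wit = approx.witnesses
        for i, v in enumerate(approx.values):
            w = "-" if wit is None or wit[i] < 0 else str(int(wit[i]) + 1)
            fh.write(f"{i + 1}\t{approx.method}\t{approx.k}\t{int(v)}\t{w}\n")
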