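"""Generalized suffix-array index over a sequence pair, with LCP/RMQ queries
and exact matching statistics.

The index is built over the sentinel-joined concatenation ``X $1 Y $2`` (or
the reversed residues of both sequences) and replaces a generalized suffix
tree: a suffix array (prefix-doubling), the Kasai LCP array, and a sparse
table answering range-minimum queries give constant-time longest-common-
prefix queries between arbitrary suffixes.  Both sentinels compare smaller
than every residue and occur exactly once, so no reported common prefix ever
crosses a sequence boundary.

Two LCP evaluation policies exist — walking the text and querying the RMQ —
selectable per query; they always return the same value (the default walks
and falls back to the RMQ once the walk exceeds a threshold).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, ValidationError
from .seqio import SENTINEL_1, SENTINEL_2, SequenceRecord

#: Walk length at which the default hybrid policy switches to the RMQ.
WALK_THRESHOLD = 1024

_POLICIES = ("walk", "rmq", "hybrid")


def _suffix_array(text: np.ndarray) -> np.ndarray:
    """Manber–Myers prefix doubling on a uint8 text; O(n log n) with numpy sorts."""
    n = len(text)
    rank = text.astype(np.int64)
    step = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if step < n:
            key2[: n - step] = rank[step:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa
        step *= 2


def _kasai_lcp(text: bytes, sa: np.ndarray, inverse: np.ndarray) -> np.ndarray:
    """Kasai's algorithm: lcp[r] = LCP of suffixes ranked r-1 and r (lcp[0]=0)."""
    n = len(text)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = inverse[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


class _SparseTableRMQ:
    """Static range-minimum structure over an integer array; O(1) queries."""

    def __init__(self, values: np.ndarray) -> None:
        n = len(values)
        self._log = np.zeros(n + 1, dtype=np.int64)
        for i in range(2, n + 1):
            self._log[i] = self._log[i // 2] + 1
        levels = [values]
        length = 1
        while 2 * length <= n:
            prev = levels[-1]
            levels.append(np.minimum(prev[: n - 2 * length + 1], prev[length : n - length + 1]))
            length *= 2
        self._levels = levels

    def min(self, lo: int, hi: int) -> int:
        """Minimum of values[lo..hi] inclusive; requires lo <= hi."""
        span = hi - lo + 1
        lev = self._log[span]
        block = self._levels[lev]
        return int(min(block[lo], block[hi - (1 << lev) + 1]))


@dataclass
class MatchingStatistics:
    """Per-position exact longest-match lengths of X against Y.

    ``lam[i]`` is the 0-mismatch λ(i): the length of the longest common prefix
    between the suffix of X at i and any suffix of Y.  ``match_positions[i]``
    lists *all* start positions in Y attaining λ(i), ascending (empty when
    λ(i)=0); ``mu[i]`` is the smallest such position, -1 when undefined.
    All coordinates are 0-based.
    """

    lam: np.ndarray
    match_positions: list[list[int]]
    mu: np.ndarray

    @property
    def mean_multiplicity(self) -> float:
        """Mean number of maximal match positions over anchored positions
        (the multiplicity that governs the all-anchors tie policy's cost)."""
        counts = [len(p) for p, l in zip(self.match_positions, self.lam) if l > 0]
        return float(np.mean(counts)) if counts else 0.0


class GeneralizedIndex:
    """Suffix array + LCP + RMQ over ``X $1 Y $2``.

    Parameters
    ----------
    x, y
        The sequence pair.  Neither may contain the reserved sentinels.
    orientation
        ``"forward"`` indexes the residues as given; ``"reverse"`` indexes the
        character-reversed residues of both sequences (the backward-extension
        index).
    """

    def __init__(self, x: SequenceRecord, y: SequenceRecord,
                 orientation: str = "forward") -> None:
        if orientation not in ("forward", "reverse"):
            raise ValidationError(f"unknown orientation {orientation!r}")
        xs, ys = x.residues, y.residues
        if not xs or not ys:
            raise ValidationError("both sequences must be non-empty")
        for label, s in (("x", xs), ("y", ys)):
            if SENTINEL_1 in s or SENTINEL_2 in s:
                raise ValidationError(f"sequence {label} contains a reserved sentinel")
        if orientation == "reverse":
            xs, ys = xs[::-1], ys[::-1]
        self.orientation = orientation
        self.nx = len(xs)
        self.ny = len(ys)
        self.boundary = self.nx              # position of $1
        self.y_offset = self.nx + 1          # text position of Y[0]
        self.text = (xs + SENTINEL_1 + ys + SENTINEL_2).encode("latin-1")
        arr = np.frombuffer(self.text, dtype=np.uint8)
        self.suffix_array = _suffix_array(arr)
        self.inverse_array = np.empty_like(self.suffix_array)
        self.inverse_array[self.suffix_array] = np.arange(len(arr))
        self.lcp_array = _kasai_lcp(self.text, self.suffix_array, self.inverse_array)
        self.rmq = _SparseTableRMQ(self.lcp_array)
        # which suffix-array ranks start inside Y
        sa = self.suffix_array
        self._is_y_rank = (sa > self.boundary) & (sa < self.boundary + 1 + self.ny)

    # ------------------------------------------------------------------ LCP

    def _check_pos(self, p: int) -> None:
        if not 0 <= p < len(self.text):
            raise BoundsError(f"text position {p} out of range [0, {len(self.text)})")

    def _walk_lcp(self, a: int, b: int, limit: int | None = None) -> int:
        """Chunked character walk; returns -1 if *limit* is exceeded first."""
        t = self.text
        maxl = len(t) - max(a, b)
        length = 0
        chunk = 32
        while length < maxl:
            c = min(chunk, maxl - length)
            if t[a + length : a + length + c] == t[b + length : b + length + c]:
                length += c
                chunk = min(chunk * 2, 4096)
                if limit is not None and length > limit:
                    return -1
                continue
            sa_, sb_ = t[a + length : a + length + c], t[b + length : b + length + c]
            for off in range(c):
                if sa_[off] != sb_[off]:
                    return length + off
        return maxl

    def _rmq_lcp(self, a: int, b: int) -> int:
        ra, rb = int(self.inverse_array[a]), int(self.inverse_array[b])
        if ra > rb:
            ra, rb = rb, ra
        return self.rmq.min(ra + 1, rb)

    def lcp_query(self, a: int, b: int, policy: str = "hybrid") -> int:
        """Length of the longest common prefix of the suffixes at text
        positions *a* and *b* (never extending across a sentinel).

        *policy* selects the evaluation route ("walk" | "rmq" | "hybrid");
        the returned value is policy-invariant.
        """
        self._check_pos(a)
        self._check_pos(b)
        if a == b:
            raise BoundsError("lcp_query requires two distinct positions")
        if policy not in _POLICIES:
            raise ValidationError(f"unknown LCP policy {policy!r}")
        if policy == "rmq":
            return self._rmq_lcp(a, b)
        limit = WALK_THRESHOLD if policy == "hybrid" else None
        length = self._walk_lcp(a, b, limit=limit)
        if length < 0:  # hybrid: walk gave up, finish with the O(1) query
            return self._rmq_lcp(a, b)
        return length

    def lcp_xy(self, i: int, j: int, policy: str = "hybrid") -> int:
        """LCP between the suffix of X at *i* and the suffix of Y at *j*
        (0-based sequence coordinates)."""
        return self.lcp_query(i, self.y_offset + j, policy=policy)

    # ---------------------------------------------------- matching statistics

    def matching_statistics(self, anchor_limit: int | None = None) -> MatchingStatistics:
        """Exact matching statistics of X against Y.

        For every position i of X, λ(i) is found from the nearest Y-suffixes
        in suffix-array order (range-minimum LCP queries), then every Y start
        attaining λ(i) is enumerated by scanning outward while the running
        minimum stays at λ(i).  *anchor_limit* caps the enumerated positions
        per i (ascending j), guarding the worst case where one substring has
        very many maximal matches.
        """
        sa, inv, lcp = self.suffix_array, self.inverse_array, self.lcp_array
        is_y = self._is_y_rank
        n = len(sa)
        # nearest Y-suffix rank at-or-before / at-or-after each rank
        idx = np.arange(n)
        prev_y = np.where(is_y, idx, -1)
        np.maximum.accumulate(prev_y, out=prev_y)
        next_y = np.where(is_y, idx, n)
        next_y = np.minimum.accumulate(next_y[::-1])[::-1]

        lam = np.zeros(self.nx, dtype=np.int64)
        mu = np.full(self.nx, -1, dtype=np.int64)
        match_positions: list[list[int]] = []
        yoff = self.y_offset
        for i in range(self.nx):
            r = int(inv[i])
            best = 0
            if prev_y[r] >= 0:
                best = self.rmq.min(int(prev_y[r]) + 1, r)
            if next_y[r] < n:
                best = max(best, self.rmq.min(r + 1, int(next_y[r])))
            lam[i] = best
            if best == 0:
                match_positions.append([])
                continue
            js: list[int] = []
            cur = np.inf
            rr = r
            while rr > 0:  # scan toward smaller ranks
                cur = min(cur, lcp[rr])
                if cur < best:
                    break
                rr -= 1
                if is_y[rr]:
                    js.append(int(sa[rr]) - yoff)
            cur = np.inf
            rr = r
            while rr + 1 < n:  # scan toward larger ranks
                cur = min(cur, lcp[rr + 1])
                if cur < best:
                    break
                rr += 1
                if is_y[rr]:
                    js.append(int(sa[rr]) - yoff)
            js.sort()
            if anchor_limit is not None:
                js = js[:anchor_limit]
            match_positions.append(js)
            mu[i] = js[0]
        return MatchingStatistics(lam=lam, match_positions=match_positions, mu=mu)


def build_index(x: SequenceRecord, y: SequenceRecord,
                orientation: str = "forward") -> GeneralizedIndex:
    """Build the generalized suffix-array index for a sequence pair."""
    return GeneralizedIndex(x, y, orientation=orientation)


def matching_statistics(x: SequenceRecord, y: SequenceRecord,
                        anchor_limit: int | None = None,
                        index: GeneralizedIndex | None = None) -> MatchingStatistics:
    """Matching statistics of *x* against *y*; builds the forward index unless
    a prebuilt one is supplied."""
    if index is None:
        index = GeneralizedIndex(x, y, orientation="forward")
    elif index.orientation != "forward":
        raise ValidationError("matching statistics require a forward index")
    return index.matching_statistics(anchor_limit=anchor_limit)
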