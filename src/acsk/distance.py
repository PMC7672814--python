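"""ACS_k values, pairwise distances, distance matrices, accuracy metrics,
and PHYLIP matrix I/O.

The average common substring of X with respect to Y is the positional mean
of λ_k; the pair distance combines both directed ACS values with a
logarithmic normalization and subtracts the self-match terms, so identical
sequences score (slightly below) zero:

    d(X, Y) = 1/2 (log|Y| / ACS_k(X,Y) + log|X| / ACS_k(Y,X))
              - (log|X| / |X| + log|Y| / |Y|)
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError, ValidationError
from .exact import ORACLE_CAP, _lambda_many
from .heuristics import LambdaApprox, Options, PairContext, adyar_lambda, \
    alfredg_lambda, compute_lambda, kmacs_lambda
from .seqio import SequenceRecord

_LOG = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over a named sequence set."""

    names: list[str]
    values: np.ndarray
    k: int = 0
    method: str = ""

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValidationError("taxon names must be unique")
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match names")

    @property
    def size(self) -> int:
        return len(self.names)


def acs_from_lambda(lam: LambdaApprox | np.ndarray, x_length: int | None = None) -> float:
    """ACS_k of X w.r.t. Y: the arithmetic mean of the λ_k array.

    Direction-dependent — ACS_k(X, Y) != ACS_k(Y, X) in general.
    """
    values = lam.values if isinstance(lam, LambdaApprox) else np.asarray(lam)
    if len(values) == 0:
        raise ValidationError("cannot average an empty lambda array")
    if x_length is not None and len(values) != x_length:
        raise ValidationError(
            f"lambda array length {len(values)} does not match |X|={x_length}"
        )
    return float(np.mean(values))


def acs_distance(x_len: int, y_len: int, acs_xy: float, acs_yx: float,
                 log_base: str = "e") -> float:
    """Pair distance from the two directed ACS values.

    Symmetric in its arguments.  When either ACS is 0 the distance is
    positive infinity (with a warning): no finite value exists.  The log
    base rescales all distances by a constant factor and therefore cannot
    change any neighbor-joining topology; natural log is the default.
    """
    if log_base not in _LOG:
        raise ParameterError(f"log base must be one of {sorted(_LOG)}")
    if x_len < 2 or y_len < 2:
        raise ValidationError("sequence lengths must be >= 2")
    if acs_xy < 0 or acs_yx < 0:
        raise ValidationError("ACS values must be nonnegative")
    if acs_xy == 0 or acs_yx == 0:
        warnings.warn("ACS of 0: no common substring credit; distance is infinite")
        return math.inf
    base = _LOG[log_base]
    lx, ly = math.log(x_len, base), math.log(y_len, base)
    return 0.5 * (ly / acs_xy + lx / acs_yx) - (lx / x_len + ly / y_len)


def directed_acs(x: SequenceRecord, y: SequenceRecord, k: int, method: str,
                 options: Options = Options(), cap: int = ORACLE_CAP) -> float:
    """ACS_k(X, Y) for one ordered pair by the named method."""
    return acs_from_lambda(compute_lambda(x, y, k, method, options=options, cap=cap))


def distance_matrix(records: list[SequenceRecord], k: int, method: str,
                    options: Options = Options(), log_base: str = "e",
                    clamp_negative: bool = False,
                    cap: int = ORACLE_CAP) -> DistanceMatrix:
    """Full symmetric distance matrix: both directed λ_k arrays per pair,
    then ACS_k and the pair distance.  Diagonal forced to zero; negative
    entries preserved unless *clamp_negative* (downstream NJ tolerates small
    negatives)."""
    if len(records) < 2:
        raise ValidationError("need at least two sequences")
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate sequence names in input set")
    n = len(records)
    values = np.zeros((n, n), dtype=float)
    for a in range(n):
        for b in range(a + 1, n):
            x, y = records[a], records[b]
            acs_xy = directed_acs(x, y, k, method, options=options, cap=cap)
            acs_yx = directed_acs(y, x, k, method, options=options, cap=cap)
            d = acs_distance(len(x), len(y), acs_xy, acs_yx, log_base=log_base)
            if clamp_negative and d < 0:
                d = 0.0
            values[a, b] = values[b, a] = d
    return DistanceMatrix(names=names, values=values, k=k, method=method)


def mean_error_percent(approx: list[float] | np.ndarray,
                       exact: list[float] | np.ndarray) -> float:
    """Mean of |approx - exact| / exact * 100 over paired entries."""
    a = np.asarray(approx, dtype=float)
    e = np.asarray(exact, dtype=float)
    if a.shape != e.shape or a.size == 0:
        raise ValidationError("approx and exact must be equal-length and nonempty")
    if np.any(e <= 0):
        raise ValidationError("exact values must be positive")
    return float(np.mean(np.abs(a - e) / e) * 100.0)


# ------------------------------------------------------------- PHYLIP I/O


def write_phylip(matrix: DistanceMatrix, path: str | Path,
                 dialect: str = "strict") -> None:
    """Write a square PHYLIP distance matrix.

    ``strict`` pads/truncates names to 10 characters (raising on a collision
    after truncation); ``relaxed`` writes full names followed by whitespace.
    Values are written to 6 decimals.
    """
    if dialect not in ("strict", "relaxed"):
        raise ParameterError(f"unknown PHYLIP dialect {dialect!r}")
    names = matrix.names
    if dialect == "strict":
        short = [n[:10] for n in names]
        if len(set(short)) != len(short):
            raise ValidationError(
                "names collide after truncation to 10 characters; "
                "use the relaxed dialect"
            )
        labels = [s.ljust(10) for s in short]
    else:
        labels = list(names)
    with open(path, "w") as fh:
        fh.write(f"{matrix.size}\n")
        for label, row in zip(labels, matrix.values):
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (either dialect; names must not
    contain whitespace)."""
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as err:
        raise FormatError(f"{path}: first line must be the taxon count") from err
    rows = lines[1:]
    if len(rows) != n:
        raise FormatError(f"{path}: expected {n} rows, found {len(rows)}")
    names: list[str] = []
    values = np.zeros((n, n), dtype=float)
    for r, line in enumerate(rows):
        parts = line.split()
        if len(parts) != n + 1:
            raise FormatError(
                f"{path}: row {r + 1} has {len(parts) - 1} values, expected {n} "
                "(non-square matrix?)"
            )
        names.append(parts[0])
        values[r] = [float(v) for v in parts[1:]]
    return DistanceMatrix(names=names, values=values)


def write_matrix_tsv(matrix: DistanceMatrix, path: str | Path) -> None:
    """Tab-separated export with a header row of taxon names."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(matrix.names) + "\n")
        for name, row in zip(matrix.names, matrix.values):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
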