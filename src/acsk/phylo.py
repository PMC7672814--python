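"""Neighbor-joining tree construction, Newick I/O, and Robinson–Foulds
comparison.

Trees are dendropy objects throughout; NJ itself is implemented here because
deterministic tie-breaking (lowest index pair on equal Q) and the treatment
of negative branch-length estimates (clamped to zero, deficit moved to the
sibling edge) are part of this package's output contract.  Unrooted trees
are serialized with a trifurcating root, the convention PHYLIP-compatible
tools expect.
"""
from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .distance import DistanceMatrix
from .errors import FormatError, ValidationError

Tree = dendropy.Tree

_SYMMETRY_TOL = 1e-9


def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Classic Saitou–Nei agglomeration on a symmetric distance matrix.

    At each step the pair minimizing Q_ij = (n-2) d_ij - R_i - R_j is merged;
    on ties the lexicographically smallest index pair wins, so the output is
    bit-reproducible.  Negative branch-length estimates are clamped to zero
    with the deficit transferred to the sibling edge (their sum, d_ij, is
    preserved).  Requires at least three taxa; the final three lineages are
    resolved as a trifurcating root.
    """
    n = matrix.size
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    d = np.array(matrix.values, dtype=float)
    if np.max(np.abs(d - d.T)) > _SYMMETRY_TOL:
        raise ValidationError("distance matrix is asymmetric beyond 1e-9")
    clades = [_quote(name) for name in matrix.names]
    while len(clades) > 3:
        m = len(clades)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        flat = np.argmin(q[iu])  # row-major: lowest (i, j) among ties
        i, j = int(iu[0][flat]), int(iu[1][flat])
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        bj = d[i, j] - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        merged = f"({clades[i]}:{bi:.6f},{clades[j]}:{bj:.6f})"
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [t for t in range(m) if t not in (i, j)]
        d2 = np.empty((m - 1, m - 1), dtype=float)
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        clades = [clades[t] for t in keep] + [merged]
    # resolve the last three lineages around a trifurcating root
    b0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    b2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    b0, b1, b2 = (max(b, 0.0) for b in (b0, b1, b2))
    newick = (f"({clades[0]}:{b0:.6f},{clades[1]}:{b1:.6f},"
              f"{clades[2]}:{b2:.6f});")
    return read_newick(newick)


def write_newick(tree: Tree, path: str | Path | None = None) -> str:
    """Serialize to Newick (branch lengths, quoted labels as needed); writes
    to *path* when given and always returns the string."""
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       preserve_spaces=True, unquoted_underscores=True).strip()
    if not s.endswith(";"):
        s += ";"
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


def read_newick(source: str | Path) -> Tree:
    """Parse one Newick tree from a string or file path."""
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "(" not in source and Path(source).exists()):
        data = Path(source).read_text()
    else:
        data = str(source)
    try:
        tree = dendropy.Tree.get(data=data, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as err:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {err}") from err
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in Newick tree")
    tree.is_rooted = False
    return tree


def leaf_labels(tree: Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: |B1 \\ B2| + |B2 \\ B1| over nontrivial
    bipartitions (PHYLIP treedist convention, unnormalized).

    Both trees must cover the same leaf set; 0 means topologically identical.
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        missing = sorted(l1 ^ l2)
        raise ValidationError(f"leaf sets differ; offending labels: {missing}")
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                          taxon_namespace=ns, preserve_underscores=True)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                          taxon_namespace=ns, preserve_underscores=True)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
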