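"""The three lambda_k estimators: extension chains, kmacs, ALFRED-G, and the
two-phase forward/backward method, with their soundness, dominance and
reduction properties."""
import itertools

import numpy as np
import pytest

from acsk import (DNA, ParameterError, SequenceRecord, adyar_lambda,
                  adyar_phase1, adyar_phase2, alfredg_lambda, backward_chain,
                  exact_lambda, forward_chain, kmacs_lambda, lcp_k_walk,
                  matching_statistics)
from acsk.heuristics import LambdaApprox, Options, PairContext

NOFB = Options(fallback=False)


# ------------------------------------------------------------------ chains

def test_forward_chain_worked_example(worked_pair):
    ctx = PairContext(*worked_pair)
    assert forward_chain(ctx.fwd, 3, 1, 2).tolist() == [2, 5, 7]


def test_forward_chain_self_pair_never_skips():
    x = SequenceRecord("x", "ACGTACG")
    ctx = PairContext(x, x)
    for i in (0, 3):
        assert forward_chain(ctx.fwd, i, i, 3).tolist() == [len(x) - i] * 4


def test_forward_chain_truncates_at_ends():
    x = SequenceRecord("x", "GA")
    y = SequenceRecord("y", "GT")
    ctx = PairContext(x, y)
    # last characters differ: the single mismatch consumes the end
    assert forward_chain(ctx.fwd, 1, 1, 1).tolist() == [0, 1]
    # nothing left at all once both are exhausted
    assert forward_chain(ctx.fwd, 1, 1, 3).tolist() == [0, 1, 1, 1]


def test_backward_chain_worked_example(backward_pair):
    ctx = PairContext(*backward_pair)
    assert backward_chain(ctx.rev, 3, 10, 1).tolist() == [0, 3]


def test_backward_chain_boundaries(backward_pair):
    ctx = PairContext(*backward_pair)
    assert backward_chain(ctx.rev, 0, 5, 2).tolist() == [0, 0, 0]
    assert backward_chain(ctx.rev, 5, 0, 2).tolist() == [0, 0, 0]


def test_backward_chain_self_pair():
    x = SequenceRecord("x", "ACGTACG")
    ctx = PairContext(x, x)
    assert backward_chain(ctx.rev, 4, 4, 2).tolist() == [4, 4, 4]


def test_chains_match_lcp_k_walk(random_pairs):
    """Every chain entry is the greedy maximal <=m-mismatch walk length."""
    for x, y in random_pairs(3, 50, seed=17):
        ctx = PairContext(x, y)
        xr = SequenceRecord("xr", x.residues[::-1])
        yr = SequenceRecord("yr", y.residues[::-1])
        for i in (0, 10, 25):
            for j in (0, 7, 30):
                lf = forward_chain(ctx.fwd, i, j, 3)
                lr = backward_chain(ctx.rev, i, j, 3)
                for m in range(4):
                    assert lf[m] == lcp_k_walk(x, y, i, j, m)
                    if i and j:
                        assert lr[m] == lcp_k_walk(xr, yr, len(x) - i,
                                                   len(y) - j, m)
                assert np.all(np.diff(lf) >= 0) and np.all(np.diff(lr) >= 0)


# ------------------------------------------------------------------ kmacs

def test_kmacs_worked_example(worked_pair):
    assert kmacs_lambda(*worked_pair, 2, NOFB).values[3] == 7


def test_kmacs_misses_backward_only_match(backward_pair):
    # forward-only anchoring stops at 6 where the true value is 7
    assert kmacs_lambda(*backward_pair, 1, NOFB).values[0] == 6


def test_kmacs_k0_reduces_to_matching_statistics(random_pairs):
    for x, y in random_pairs(3, 120, seed=23):
        assert np.array_equal(kmacs_lambda(x, y, 0, NOFB).values,
                              matching_statistics(x, y).lam)


# ---------------------------------------------------------------- ALFRED-G

def test_alfredg_requires_k_at_least_2(worked_pair):
    with pytest.raises(ParameterError):
        alfredg_lambda(*worked_pair, 1)


def test_alfredg_self_pair_is_exact():
    x = SequenceRecord("x", "ACGTTGCA")
    for k in (2, 3):
        assert alfredg_lambda(x, x, k).values.tolist() == \
            list(range(len(x), 0, -1))


def test_alfredg_is_sound_lower_bound(random_pairs):
    for x, y in random_pairs(3, 90, seed=29):
        for k in (2, 3, 4):
            approx = alfredg_lambda(x, y, k)
            exact = exact_lambda(x, y, k).values
            assert np.all(approx.values <= exact)
            for i, (v, w) in enumerate(zip(approx.values, approx.witnesses)):
                if w >= 0:
                    assert lcp_k_walk(x, y, i, int(w), k) >= v


# ------------------------------------------------------------------ adyar

def test_phase1_credits_backward_extension(backward_pair):
    partial = adyar_phase1(*backward_pair, 1, NOFB)
    assert partial.values[0] >= 7
    assert partial.witnesses[0] == 7


def test_phase1_self_pair_full_length():
    x = SequenceRecord("x", "GATTACAG")
    assert adyar_phase1(x, x, 2, NOFB).values[0] == len(x)


def test_phase2_propagation_arithmetic():
    partial = LambdaApprox("adyar", 1, np.array([7, 0, 0, 4, 0]),
                           np.array([2, -1, -1, 9, -1]), NOFB)
    out = adyar_phase2(partial)
    assert out.values.tolist() == [7, 6, 5, 4, 3]
    assert out.witnesses.tolist() == [2, 3, 4, 9, 10]


def test_phase2_fixpoint():
    vals = np.array([5, 4, 4, 3, 2])
    partial = LambdaApprox("adyar", 1, vals.copy(), np.full(5, -1), NOFB)
    assert adyar_phase2(partial).values.tolist() == vals.tolist()


def test_phase2_postcondition_holds(random_pairs):
    for x, y in random_pairs(3, 100, seed=37):
        vals = adyar_lambda(x, y, 2, NOFB).values
        assert np.all(vals[1:] >= vals[:-1] - 1)


def test_adyar_recovers_backward_only_match(backward_pair):
    assert adyar_lambda(*backward_pair, 1, NOFB).values[0] == 7


def test_adyar_k0_equals_exact(random_pairs):
    for x, y in random_pairs(5, 150, seed=41):
        assert np.array_equal(adyar_lambda(x, y, 0, NOFB).values,
                              matching_statistics(x, y).lam)


def test_adyar_self_pair(random_pairs):
    x, _ = random_pairs(1, 60, seed=43)[0]
    for k in (0, 2):
        assert adyar_lambda(x, x, k, NOFB).values.tolist() == \
            list(range(len(x), 0, -1))


def test_soundness_and_dominance_exhaustive_binary():
    """All ordered binary-alphabet pairs at length 4: kmacs <= adyar <= exact
    pointwise, for every budget."""
    seqs = ["".join(p) for p in itertools.product("AC", repeat=4)]
    for xs in seqs:
        x = SequenceRecord("x", xs)
        for ys in seqs:
            y = SequenceRecord("y", ys)
            ctx = PairContext(x, y)
            for k in (0, 1, 2):
                km = kmacs_lambda(x, y, k, NOFB, ctx=ctx).values
                ad = adyar_lambda(x, y, k, NOFB, ctx=ctx).values
                ex = exact_lambda(x, y, k).values
                assert np.all(km <= ad) and np.all(ad <= ex), (xs, ys, k)


def test_soundness_dominance_and_witnesses_random(random_pairs):
    for x, y in random_pairs(5, 200, seed=47):
        ctx = PairContext(x, y)
        for k in (1, 3, 5):
            km = kmacs_lambda(x, y, k, NOFB, ctx=ctx)
            ad = adyar_lambda(x, y, k, NOFB, ctx=ctx)
            ex = exact_lambda(x, y, k).values
            assert np.all(km.values <= ad.values)
            assert np.all(ad.values <= ex)
            for approx in (km, ad):
                for i, (v, w) in enumerate(zip(approx.values, approx.witnesses)):
                    if w >= 0:
                        assert lcp_k_walk(x, y, i, int(w), k) >= v


def test_lcp_policy_never_changes_values(random_pairs):
    x, y = random_pairs(1, 150, seed=53)[0]
    results = []
    for policy in ("walk", "rmq", "hybrid"):
        opts = Options(fallback=False, lcp_policy=policy)
        results.append((kmacs_lambda(x, y, 3, opts).values,
                        adyar_lambda(x, y, 3, opts).values))
    for a, b in results[1:]:
        assert np.array_equal(a, results[0][0])
        assert np.array_equal(b, results[0][1])


def test_fallback_inherits_at_zero_anchor_positions():
    # X_3 = 'T' does not occur in Y: lambda(3)=0, fallback copies the right
    # neighbour's estimate; the final zero-anchor position stays put.
    x = SequenceRecord("x", "ACTGG")
    y = SequenceRecord("y", "ACAGG")
    ms = matching_statistics(x, y)
    assert ms.lam[2] == 0
    off = adyar_lambda(x, y, 1, Options(fallback=False))
    on = adyar_lambda(x, y, 1, Options(fallback=True))
    assert on.values[2] >= on.values[3]
    assert np.all(on.values >= off.values)


def test_tie_policy_first_uses_smallest_anchor(random_pairs):
    x, y = random_pairs(1, 100, seed=59)[0]
    allv = kmacs_lambda(x, y, 2, Options(fallback=False, tie_policy="all")).values
    first = kmacs_lambda(x, y, 2, Options(fallback=False, tie_policy="first")).values
    assert np.all(first <= allv)


def test_guarded_phase2_is_never_above_unguarded(random_pairs):
    x, y = random_pairs(1, 100, seed=61)[0]
    unguarded = adyar_lambda(x, y, 2, NOFB).values
    guarded = adyar_lambda(x, y, 2,
                           Options(fallback=False, guarded_phase2=True)).values
    assert np.all(guarded <= unguarded)
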