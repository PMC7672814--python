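# Methods

## The measure and its estimators

For a pair of sequences X, Y over an alphabet Σ, LCP_k(X_i, Y_j) is the
longest common prefix of the suffixes X_i and Y_j allowing at most k
mismatched positions; λ_k(i) = max_j |LCP_k(X_i, Y_j)| and μ_k(i) is a
position attaining it.  ACS_k(X, Y) is the mean of λ_k over i = 1..|X|
(direction-dependent), and the pair distance is

    d(X, Y) = ½ (log|Y|/ACS_k(X,Y) + log|X|/ACS_k(Y,X))
              − (log|X|/|X| + log|Y|/|Y|).

Identical sequences of length n have ACS_0 = (n+1)/2 and therefore
d = −2·ln n / (n(n+1)), slightly below zero; this closed form is asserted
to 1e−12 in the tests.

Exact λ_k is expensive, so three linear-time estimators are provided.  All
anchor on maximal *exact* matches found from matching statistics:

* **kmacs**: from each maximal anchor (i, j), a forward chain
  L_f[m] = L_f[m−1] + 1 + LCP after skipping one mismatch, m = 1..k; the
  estimate is L_f[k], maximized over anchors.
* **ALFRED-G**: the anchor is the longest *1-mismatch* match (λ_1, μ_1,
  computed here by the exact oracle), then one skipped mismatch and a
  (k−2)-budget walk.  Requires k ≥ 2 and oracle-cap-sized inputs.
* **adyar** (two-phase forward/backward extension, the default): for each
  anchor both the forward chain L_f and the backward chain L_r (computed on
  the reversed strings, measuring characters strictly before the anchor) are
  evaluated.  The two directions share a single mismatch pool: for every
  split t = 0..k, a genuine ≤k-mismatch match of length L_r[t] + L_f[k−t]
  starts at position i − L_r[t], and that position keeps the running
  maximum.  Phase 2 is one left-to-right pass
  values[i] ← max(values[i], values[i−1] − 1), sound because removing the
  first character of any ≤k-mismatch match leaves one a character shorter.

Soundness and dominance follow by construction and are enforced by tests:
with the fallback off, kmacs ≤ adyar ≤ exact pointwise, every positive
value has a witness position in Y verifiable by a direct k-mismatch walk,
and all three reduce to the exact matching statistics at k = 0.  Because
the estimators bracket the truth from below, the pointwise dominance also
orders their mean ACS_k error percentages deterministically.

### Design choices in the two-phase method

* **Phase-2 guard.** The propagation pass is applied *unconditionally* by
  default.  A guarded variant (skip positions that are the mismatch
  character of the preceding witnessed match) exists behind
  `Options(guarded_phase2=True)` for fidelity experiments; the unguarded
  pass is never unsound and never worse as a lower bound.
* **Tie policy.** When several Y positions attain a maximal anchor, all of
  them are extended and the longest result kept (`tie_policy="all"`,
  the default); `"first"` keeps only the smallest j, emulating
  single-anchor greedy behavior.  `anchor_limit` caps the enumeration
  (ascending j) as a safety valve against the O(n²k) worst case of highly
  repetitive pairs; it defaults to unlimited.
* **Zero-LCP fallback.** Positions whose exact anchor LCP is 0 (their first
  character does not occur in Y at all) get no anchor.  With
  `fallback=True` (the pipeline default) such positions inherit the
  estimate of the following position in a right-to-left pass.  The inherited
  value is an estimate, not a witnessed match, so property tests run with
  the fallback off.  The pass takes the maximum of the inherited and the
  already-computed value rather than overwriting: phase 1 can legitimately
  credit a zero-anchor position through a backward extension, and a
  witnessed match is never discarded for a copied guess.  This also keeps
  the phase-2 postcondition values[i] ≥ values[i−1] − 1 intact.
* **Combination semantics.** The anchor segment is counted once, inside
  L_f; the backward budget t and forward budget k−t therefore total at most
  k mismatches for every candidate.

## Index layer

The generalized suffix tree is replaced by a generalized suffix array over
the sentinel-joined text `X $1 Y $2` (and over the reversed residues for
backward chains).  The sentinels are two reserved control characters
smaller than every residue with $1 < $2, each occurring once, so no common
prefix ever crosses a sequence boundary.  Construction is Manber–Myers
prefix doubling on numpy sorts (O(n log n)); the LCP array is Kasai's
algorithm; range minima use a sparse table.  Matching statistics come from
the nearest Y-suffix above and below each X-suffix in rank order, and the
full set of maximal match positions is enumerated by scanning outward while
the running LCP minimum stays at λ(i).

LCP queries can be answered by walking the text (chunked byte comparison)
or by an O(1) range-minimum query.  Following the observation that short
LCPs make walking faster in practice on cached memory, the default policy
walks and switches to the RMQ once a walk exceeds 1024 characters.  The
policy is internal: tests assert it never changes a reported value.

Coordinates are 0-based half-open internally; user-facing reports (TSV
dumps, documentation examples) use the field's 1-based convention.

## Exact oracle

`exact_lambda` scans every alignment diagonal j − i of the comparison
matrix: mismatch positions on a diagonal are found vectorized, and for each
start offset the k-mismatch length is the distance to the (k+1)-th
following mismatch or the diagonal end.  Diagonals are visited in ascending
j − i with strictly-greater updates, making every witness the smallest
attaining j.  The cost is Θ(|X|·|Y|) character comparisons, capped at 10⁷
by default (the cap counts comparisons, not lengths, and can be raised
explicitly).  `lcp_k_walk` is the independent per-pair walk used to verify
witnesses; the diagonal scan and the walk are cross-checked in the tests.
The known sub-quadratic exact algorithm is intentionally out of scope: the
oracle exists to validate the estimators at desk scale, not to compete with
them.

## Distances and trees

Distance matrices evaluate both directed λ_k arrays per unordered pair
(sharing nothing between pairs), apply the ACS mean and the pair distance,
and force a zero diagonal.  The logarithm base (e, 2, 10) rescales all
distances by a constant and cannot change a neighbor-joining topology;
natural log is the default.  Slightly negative distances between
near-identical sequences are preserved by default (NJ tolerates them) and
clamped to zero only on request.  PHYLIP square matrices are written in the
strict 10-character-name dialect (truncation collisions are an error) or a
relaxed full-name dialect; values round-trip to 6 decimals.

Neighbor joining is the classic Saitou–Nei agglomeration with the
Q-criterion.  Ties on Q are broken toward the lexicographically smallest
index pair, making trees bit-reproducible; negative branch-length estimates
are clamped to zero with the deficit moved to the sibling edge (preserving
their sum), and the last three lineages are resolved as a trifurcating
root, the convention PHYLIP-compatible tools expect.  Newick I/O and the
Robinson–Foulds count (raw symmetric difference of nontrivial bipartitions,
unnormalized and unhalved) are delegated to dendropy; tests cross-check RF
against a manual bipartition enumeration and NJ against additivity
(patristic distances of the output tree reproduce an additive input
matrix exactly).

## Synthetic data

The generator emulates the divergence regime in which matching-statistics
distances are informative: i.i.d. uniform sequences over the core alphabet
(4 DNA or 20 amino-acid symbols), per-site substitutions at a controllable
rate where a mutated site becomes a uniformly chosen *different* symbol,
and clock-style trees built by successive random pair-joins with one
per-branch substitution probability that also serves as branch length.  All
generators are pure functions of their seeds.

What this does **not** emulate: indels, rate heterogeneity across sites or
branches, base-composition bias, repeats, and horizontal transfer.  Passing
tests therefore demonstrate correctness of the algorithms and the
qualitative accuracy ordering of the estimators under a clean substitution
model — not robustness to the full messiness of real genomes.

## Problem sizes and defaults

The shipped test and acceptance workloads use pair lengths of 200 (50
seeded pairs for pointwise reduction/soundness/dominance with witness
verification), 1000 (10 pairs at substitution rates 0.05–0.20 for the
k = 1..5 accuracy comparison of the estimators against the exact oracle),
and an end-to-end run of 8 taxa × 5000 bp at per-branch rate 0.02 (distance
method adyar, k = 2) whose NJ tree matches the generating topology
(RF = 0).  These sizes were chosen so that the quadratic oracle remains
comfortably below its comparison cap while the sequences are long enough
for the estimators' error differences to be stable across seeds.

Key defaults: `k` has no default (it is the scientific choice);
`method=adyar`; `tie_policy=all`; `fallback=on` in the CLI pipeline and off
wherever lower-bound guarantees are being tested; natural logarithm;
oracle cap 10⁷ comparisons; walk→RMQ switch at 1024 characters.

## Known limitations

* ALFRED-G inherits the quadratic oracle's cap through its λ_1 anchor.
* The estimators handle substitutions only; an indel shifts the alignment
  diagonal and truncates every match that spans it.
* The `all` tie policy can degrade toward O(n²k) on pathologically
  repetitive inputs; use `anchor_limit` or `tie_policy="first"` there.
* Matching statistics and chain evaluation are pure Python over a numpy
  index; genome-scale inputs (hundreds of megabases) are out of scope.
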