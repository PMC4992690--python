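# Methods

## Similarity model

Molecules are encoded as MACCS structural-key fingerprints: 166 predefined
substructure patterns, bit k set when pattern k occurs in the molecule.
Toolkits emit a 167-position vector whose index 0 is permanently-unset
padding; this package stores only keys 1–166, mapped to vector indices 0–165.
That convention makes the `fps_csv` interchange format (`id,mw,class,bits`
with a 166-character 0/1 string, key 1 first) bit-portable between runs and
machines. Fingerprinting itself is delegated to RDKit; the package's own
contribution starts at the pairwise count algebra.

For a pair (A, B), with A the interrogatory (query) molecule and B the
interrogated (target) molecule, the overlap is summarized by the triple
(a, b, c): keys on only in A, only in B, and in both. The Tversky similarity
is

    Tv(A, B; α, β) = c / (α·a + β·b + c),    α, β ≥ 0.

Properties the implementation guarantees and the suite asserts:

- **Range** 0 ≤ Tv ≤ 1 (the denominator is never smaller than c).
- **Special cases, exactly**: α = β = 1 is Tanimoto c/(a+b+c); α = β = 0.5 is
  Dice 2c/(a+b+2c). Both identities hold to machine precision because all
  variants are computed from the same integer counts in double precision.
- **Exchange symmetry** Tv(A,B;α,β) = Tv(B,A;β,α); asymmetric otherwise.
- **Monotonicity**: strictly decreasing in α when a > 0 and in β when b > 0.
- **Substructure limit**: if B's keys are a subset of A's (b = 0, c > 0),
  Tv = 1 at α = 0 for any β. Small α therefore reads "B as substructure of
  A", large α the converse.

Several published variants of the Tversky index exist; this package
implements exactly the form above and no other.

**Degenerate denominators.** Whenever c = 0 — both-empty fingerprints
included, and the α = 0, b = 0 case where the denominator itself vanishes —
the similarity is defined as 0.0, and an empty fingerprint triggers a
once-per-run warning. Rationale: no shared key is no evidence of similarity,
and a single convention keeps NaN out of every downstream ranking.

## Bit counting

Pair counts use word-packed popcounts (`numpy.packbits` +
`numpy.bitwise_count`); collection-level counts use one integer matrix
product of the 0/1 fingerprint matrices (c = Q·Tᵀ, with a and b recovered
from the row/column popcounts). Both routes are verified against a naive
per-position loop oracle in the suite. Profiles are computed in a streaming
row-block pass (256 queries at a time) unless full matrices are requested, so
a 2,000 × 10,000 sweep holds at most one block in memory.

## Parameter grids

Sweeps hold the sum α + β fixed: the `sum1` family spans α ∈ [0, 1] and
`sum2` spans α ∈ [0, 2] (the Tanimoto point α = β = 1 lies on `sum2`).
Default grid: 11 evenly spaced points. Grid values are generated from
integer ratios and rounded at 12 decimals so labels like `a0.3_b0.7`
round-trip exactly through file names and tables.

## Aggregate statistics and conventions

- **Max profile**: per query, the largest similarity over all targets plus
  the achieving target id. Ties — and ties everywhere else — are broken by
  target input-file order, making runs reproducible across platforms.
- **Cumulative rank curve**: the profile sorted descending against rank
  fraction rank/N ∈ (0, 1].
- **Threshold exceedance** uses a strict ">" (fraction of queries whose best
  hit is *greater than* t, i.e. 1 − ECDF(t)); **named hits** use an inclusive
  "≥" cutoff (default 0.85). The two conventions are deliberate and
  documented rather than unified.
- **Self-comparison** of a collection against itself keeps the self-pair by
  default; `--exclude-self` masks targets sharing the query's id (a query
  whose only target is itself reports 0.0 and an empty best-target id).

## Structure handling

Inputs parse as given; for multi-fragment inputs (salts) the largest fragment
by heavy-atom count is kept before fingerprinting, and the action is logged.
Counter-ion bits would otherwise distort class comparisons. Unparseable
structures are excluded with a logged reason and surfaced on the collection's
rejection list — never silently dropped and never fatal, since large
collections always contain a few bad records. Molecular weight is the average
atomic mass of the kept fragment. No tautomer or protonation-state
enumeration is attempted, and no fingerprint dialects beyond MACCS166 and the
synthetic test dialect are offered.

## MW-matched subsampling

Binary-key similarity is confounded by molecular size, and compound classes
differ systematically in molecular weight. The matcher histograms all classes
on a shared Da grid spanning the union MW range (default bin width 50 Da — a
compromise between within-bin mismatch and per-bin sample counts), sets each
bin's quota to the minimum count across classes (the unique rule that
equalizes histograms exactly without replacement; an explicit reference class
can restrict quotas further), and draws uniformly without replacement. Bins
where any class is empty get quota 0, which clips the heavy tail of
wide-ranged classes. The draw is fully determined by the plan's mandatory
seed (classes visited in sorted-label order, bins in ascending order), and
the plan serializes to JSON so a matched comparison is reproducible from the
run's own outputs. Post-sampling per-bin counts are identical across classes
by construction; the residual distribution mismatch is bounded by within-bin
variation and shrinks with bin width (asserted on synthetic classes at 200,
100 and 50 Da).

## Synthetic data

Two generators drive the test suite and the acceptance script:

- `construct_pair` plants an exact (a, b, c) overlap at seed-randomized bit
  positions, giving pairs whose similarity under any (α, β) is known in
  closed form.
- `random_collection` draws independent Bernoulli(density) fingerprints
  (default density 0.3, roughly the on-bit density of drug-like molecules
  under MACCS keys) with synthetic ids and uniform stand-in molecular weights
  in 100–600 Da for the MW-matching tests.

Synthetic fingerprints model only the bit-count algebra: bits are independent,
whereas real MACCS keys are strongly correlated (hierarchical patterns,
ring-system co-occurrence), and real MW distributions are not uniform.
Passing tests on synthetic data therefore validate the computational
contract — counting, similarity algebra, ranking, threshold statistics,
subsampling — not any chemical claim; chemical behavior is exercised by the
embedded five-molecule set, whose SMILES come from standard references and
were verified by molecular formula and weight, and whose MACCS vectors are
frozen in the suite as a regression oracle.

## Problem sizes

The suite's largest standing computation is a full 11-point sum1 sweep over
1,400 × 1,100 synthetic fingerprints (≈17 M pair similarities), chosen as a
realistic desk-scale drug-vs-metabolite comparison; it completes in seconds
on one CPU via the matrix-product route. The acceptance script's profiling
runs use 200 queries against libraries of a few hundred molecules with a
planted exceedance fraction, large enough that the reported percentages are
exact by construction.

## Known limitations

- Only the MACCS166 encoding is supported; conclusions about other
  fingerprint types (path-based, circular, pharmacophore) do not follow.
- Similarity values depend on the toolkit's MACCS definitions: independent
  toolkits are known to disagree on a few keys, so cross-toolkit bit-exact
  agreement is not guaranteed (hence the frozen reference vectors).
- No statistical testing of similarity differences is performed, and no
  clustering or embedding of the similarity matrices is offered.
- The MW matcher uses hard binning; no propensity-score or kernel
  reweighting alternative is provided.
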