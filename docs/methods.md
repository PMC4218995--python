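# Methods

## The census procedure

A census run is defined by four numbers: the subsample size `m` (reads per
iteration), the iteration count `i`, the presence threshold `p ∈ [0, 1]`,
and the tax-slim depth `d`.  Each iteration

1. draws `m` reads uniformly at random from the dataset's record-offset
   index, *without* replacement within the iteration (iterations are
   independent, so the same read may recur across iterations);
2. maps each read to at most one reference subject (best hit: identity ≥
   90%, e-value ≤ 1e-6 by default);
3. resolves each subject to a taxid through the local subject→taxid table
   and projects the taxid onto the taxonomy at depth `d` (deeper nodes are
   reported through their ancestor at exactly depth `d`);
4. tallies reads per slim node; reads with no qualifying hit are counted
   *unaligned* and hits whose subject is absent from the table
   *unresolved*, so each iteration's tallies sum exactly to `m` (enforced
   at run time).

After `i` iterations a node is retained iff its presence count (iterations
with ≥ 1 read) strictly exceeds `p·i`.  Statistics — min, max, mean,
median, sd, and mean ± 1.96·sd truncated to [0, 1] — are computed over all
`i` per-iteration fractions with zeros for absent iterations.  Including
the zeros makes the mean identical to the pooled estimator `T/(m·i)` whose
error the design calculator quantifies; restricting to present iterations
would bias abundances upward for borderline clades.

Per-iteration presence is defined as *at least one read*.  The retention
comparison is strict (`presence_count > p·i`), so with `i = 5, p = 0.8` a
node present in 4 of 5 iterations is filtered.  Both modules obtain the
boundary from one shared helper that also snaps floating-point dust
(`0.8 × 50 = 40.000000000000006`) back onto the integer, so the strict
inequality is exact at the boundary.

Iteration `j` of a run with master seed `s` uses the seed
`blake2b("s:j") mod 2^31`, making each iteration's subsample independent
of execution order; results are bit-reproducible from the configuration
alone.  The picker itself uses numpy's `RandomState` (Mersenne Twister
MT19937).

## Design calculator

Under the perfect-alignment model (every sampled read maps to its true
source taxon) the per-iteration presence probability of a taxon at
proportion `q` is `π = 1 − (1−q)^m`, presences across iterations are
`X ~ Binomial(i, π)`, and detection power is the exact tail `P(X > p·i)`.
The pooled estimator's mean absolute error `E|T/(m·i) − q|`,
`T ~ Binomial(m·i, q)`, is computed by full pmf summation for
`m·i ≤ 10^7`; beyond that the function refuses and points to the
Monte-Carlo path.  `recommend_subsample_size` finds the smallest `m`
reaching a target power by doubling followed by bisection (power is
non-decreasing in `m` for fixed `q, i, p`).

Cross-clade misalignment is deliberately outside this model: with real
references, reads from one organism can best-hit a close relative, which
splits counts at deep taxonomic levels.  The calculator's numbers are
therefore an optimistic bound for real data.

Power is **not** monotone in `i`.  When `π > p` more iterations help; when
`π < p` the law of large numbers concentrates `X/i` around `π` below the
threshold and power decays to zero as `i` grows.  That is the filter
working as intended — it suppresses taxa whose presence rate sits under
the threshold — and the property tests assert both regimes separately.

The across-iteration confidence interval (mean ± 1.96·sd of the `i`
fractions, truncated to [0, 1]) is a pragmatic normal approximation; it is
echoed in `log.txt` and its expected margin can be simulated
(`simulate_design` reports it), but it is not an exact interval and is
biased narrow for small `i`.

## Alignment backends

The `naive` backend is an ungapped, substitution-only aligner built for
hermetic testing: candidate placements come from exact 11-mers shared
between the read (either strand) and the reference; each candidate is
verified by exact Hamming counting and the placement with the fewest
mismatches wins.  Ties break by subject id, then forward strand, then
offset.  Its e-value is a monotone surrogate (score +2 per match, −3 per
mismatch; `evalue = L·2^−score`) adequate only for thresholding.  Reads
shorter than 11 bases fall back to an exhaustive offset scan.  Because
candidates need one intact 11-mer, a read whose substitutions are spaced
more tightly than 11 bases apart everywhere can be missed; at the error
rates the generator produces (≤ ~5%) this is negligible, and the test
suite compares the backend against an exhaustive-scan oracle.  Indels are
out of scope: the generator never produces them.

The `external` backend runs
`blastn -task megablast -evalue 1e-6 -max_target_seqs 1 -perc_identity 90`
with 12-column tabular output and keeps the first HSP per query.  Its
availability is probed at run time; absence raises an error naming the
naive fallback.  Note megablast's 28-base word can miss short error-bearing
reads the naive backend still places, so backend agreement is judged on
reads both backends hit.

Host depletion maps every read to the host genome and removes those where
some alignment covers ≥ 80% of the read length with mismatches ≤ 10% of
the *aligned* length (for the full-length naive placements this reduces to
the mismatch bound).  The census then runs on the remainder and the
removed fraction is logged.

## Synthetic data generator

The generator emulates a mixed community sequenced single-end with
substitution errors.  Defaults: six members at proportions
0.50/0.20/0.20/0.07/0.02/0.01 — a dominant member, two mid-range, and a
1% member sitting exactly at the design point the retention filter is
tuned for — 50 bp reads, 1% uniform substitution rate, 3 kb genomes, and
50 000 reads for desk-scale runs.  Genomes are uniform-random sequences so
that truth is unambiguous and the perfect-alignment assumption is
realizable; a rejection check regenerates any genome with a read-length
window matching another genome at ≥ 90% identity (candidates located via
shared 11-mers, verified by Hamming counting — an ungapped ≥90% match over
50 bp without a shared 11-mer is combinatorially implausible for random
sequence).  The toy taxonomy gives each genome the lineage root → domain
(2 shared nodes) → family → genus → species, so the default slim depth 3
resolves every member to a distinct genus node while still exercising
ancestor projection.

Reads carry their source genome id in the definition line, giving ground
truth for every accuracy test.  FASTQ qualities are a constant Phred
character matching the error rate.  What the generator does *not* emulate:
indels, quality-profile-dependent errors, chimeras, GC bias, shared
sequence between community members.  Passing tests therefore demonstrate
correctness of the census machinery under its stated model, not robustness
to cross-mapping between related real genomes — the known failure mode at
deep taxonomic levels.

## Numerical and scale choices

* Exact binomial tails and pmfs come from `scipy.stats.binom`; the MAE
  summation is vectorised over the full support.
* Monte-Carlo design checks use 1e5 replicates (3-SE agreement bands);
  the acceptance script adds a 1e6-draw check of the pooled-estimator
  error, simulating `T` directly since the estimator depends on the reads
  only through `T`.
* End-to-end recovery checks run 20 seeds of a 50 000-read community at
  `m = 250, i = 50` — large enough that the pool composition's own
  sampling noise is small against the 4·√(q(1−q)/(m·i)) acceptance band.
* Statistics use the sample standard deviation (ddof = 1); a single
  iteration reports sd 0.
* FASTA output is unwrapped; FASTQ is strict 4-line.  Records written to
  FASTQ without qualities get the constant placeholder 'I', noted in
  `log.txt`.

## Known limitations

* The naive backend is ungapped; a single indel shifts the frame and the
  read is scored as heavily mismatched.
* Merged or deleted taxids are rejected at load, not remapped.
* Rank-based slims (species/genus by rank rather than depth) are not
  implemented; depth counting starts at the supplied tree's root, so the
  effective meaning of "depth 3" depends on the tree given.
* The confidence interval is approximate (see above); for small `i` it
  undercovers.
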