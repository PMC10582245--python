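# Methods

## The discrimination statistic

A sample's sequencing run is reduced to sets of *canonical read-pair
keys*. For a pair with mate sequences `r1`, `r2`, let
`fwd = r1 + '#' + r2` and `rev = revcomp(r2) + '#' + revcomp(r1)`; the key
is the lexicographic minimum of the two. Folding at key construction is
equivalent to searching both orientations at query time — if two fragments
match up to reverse complement, their folded keys are equal — and turns
every downstream operation into plain set algebra. Identity is
whole-pair: both mates must match over their full length, so pairs of
different post-filter lengths never match, and mates are never matched
independently. `N` is a literal character with `complement(N) = N`.

Per PCR duplicate *j* of sample *i*, the multiset of keys is counted
(orientations pooled by default). The high-quality set is
HQ(*i*, *j*) = {*k* : count ≥ 11} — "more than 10" identical copies,
read strictly. The sample's super-high-quality reference is
SHQ(*i*) = ∩ⱼ HQ(*i*, *j*), and its comprehensive set Comp(*i*) is the
union of all keys observed at least once in any duplicate. Two
independent PCR duplicates are required by default; single-duplicate mode
exists but must be enabled explicitly, since it removes the replication
check that separates true sequence from PCR/sequencing artifacts.

Similarity is the exact matching rate to the **target**:
*s*(*q*, *t*) = |SHQ(*t*) ∩ Comp(*q*)| / |SHQ(*t*)|. Because the
denominator is the target's, the matrix is asymmetric; rows are queries,
columns targets (transposition is a rendering option). The diagonal is
1.0 by construction (SHQ ⊆ Comp for the same sample) and serves as the
definitional anchor. A target with an empty SHQ is an *error*, not
similarity 0: "no reference" and "no overlap" must not be conflated, or
group means would be corrupted. Group summaries (all / same-cultivar /
different-cultivar / named cultivar pair) average **ordered** off-diagonal
entries — the natural choice for an asymmetric statistic — and report the
sample (n−1) standard deviation, 0.0 when only one pair exists.

## The stringent filter

Checks run in a fixed order — barcode mismatch, barcode quality, adapter,
window quality — and each removed pair is counted once under its first
failing check, giving the conservation identity
`input = kept + Σ removed`. Defaults: 0 barcode mismatches (stricter than
the usual 1-mismatch demultiplexing), barcode minimum QV 30 enforced
per base, sliding windows of exactly 4 bases (step 1, full-length windows
only; reads shorter than the window are judged on their single full-length
window) with mean ≥ QV 30. Windows follow Trimmomatic's SLIDINGWINDOW
semantics, but failing pairs are **removed**, not trimmed: whole-length
exact matching makes a trimmed read useless anyway. Adapter screening
accepts a full adapter anywhere in a mate or an adapter prefix of
≥ 8 bases anchored at the 3′ end (read-through truncated by the end of the
read); the full seed-and-palindrome model of dedicated trimmers is out of
scope. Adapter sequences are a required user input — they depend on the
library kit. Head/tail cropping is available but defaults to 0; it
belongs to SNP-calling workflows, not to exact matching. Only Phred+33
quality encoding is accepted; characters below `'!'` are a fatal error
rather than a silently misdecoded Phred+64 file.

When no separate index FASTQ exists, the barcode is taken from the read
header (the token after the last `':'`), with index qualities assumed
QV 40 and a logged warning — real index qualities are unavailable in that
dialect, so the barcode-quality filter is effectively bypassed.

## The synthetic cohort generator

The simulator emulates the *structure* of a multiplexed
reduced-representation cohort of clonally propagated cultivars: a
genealogy (parent-first tree with per-branch per-base substitution
probabilities) relating clones (divergence 0), bud mutants (~1e-4),
distinct lines (~1e-3) and separate cultivars (≥ 5e-3); one or more
samples per cultivar; two PCR duplicates per sample.

Reads are **locus-anchored**: each of `n_loci` loci yields the identical
fragment pre-error (mate 1 = first `r1_len` bases, mate 2 = reverse
complement of the last `r2_len` bases), which is what makes an
11-identical-copy threshold attainable, exactly as for primer-anchored
amplicons. There is no random shearing. Per-locus, per-duplicate depth
is negative-binomial with mean `depth_mean` and dispersion
`depth_dispersion` (amplicon depth is overdispersed; `inf` gives the
Poisson limit). Locus dropout is decided once per sample (shared by its
duplicates), with optional extra per-duplicate dropout. Substitution
errors arrive i.i.d. per base at `seq_error_rate`; erroneous bases carry
`base_qv_low`, clean bases `base_qv_high` — a two-level quality model,
sufficient to exercise QV-threshold filters but not a learned
instrument profile. A fraction `flip_prob` of pairs is emitted
mate-swapped and reverse-complemented to exercise strand folding, and
adapter read-through is appended (in sequencing orientation, after any
flip) with probability `adapter_contam_prob`.

Defaults, chosen once as realistic desk-scale study conditions: 75+75-base
pairs of 150-base loci (a 150-cycle paired kit), `depth_mean` 20,
dispersion 5, error rate 0.001, dropout 0.02, 8-base barcodes,
`flip_prob` 0.2, adapter contamination 0.01, QV 40/14. Test and
acceptance scenarios override only what their scenario states (e.g. zero
error and zero dropout for clone-recovery checks; depth 50 and 2,000 loci
for the closed-form comparison).

Randomness is hierarchical: every library draws from substreams derived
deterministically from `(rng_seed, sample_id, duplicate_id)` (crc32 seed
words), so any single file regenerates identically in isolation; and
structural draws (dropout, depth) use a different substream from per-read
draws (error, flip, adapter), so changing the error or flip settings
leaves the locus/depth realization untouched — this is what makes
strand-flip invariance testable read-set against read-set.

What the generator does **not** model — and hence what passing tests do
not certify about real data: heterozygosity and polyploidy (loci are
haploid strings), index hopping and chimeric fragments, primer
thermodynamics and amplification bias between loci, position-dependent
quality profiles, and indels (divergence is substitution-only; an indel
would shift the whole fragment and simply register as a non-match, which
is also how the real statistic treats it).

The closed-form oracle `expected_pair_similarity(d, r1_len, r2_len) =
(1 − d)^(r1_len + r2_len)` gives the asymptotic similarity between two
cultivars at per-base divergence *d* under no error, no dropout and
saturating depth; simulations converge on it as depth grows.

## Numerical and design choices

- "More than 10" is implemented as ≥ 11, exposed as `min_copies` for
  sensitivity analysis.
- High-quality sets are computed **per duplicate**, then intersected.
  Pooling duplicates before thresholding would make the subsequent
  intersection vacuous; per-library thresholds are the reading under
  which the reference-construction step is meaningful.
- Orientation pooling before thresholding is the default (a fragment's
  forward and reverse-complement observations are the same molecule);
  `strand_pool=False` is a documented dialect in which a key's
  multiplicity is that of its best single orientation, so copy thresholds
  apply per orientation. In that dialect the total-pairs conservation
  identity intentionally does not hold.
- Similarities are exact rational counts divided at the end; no floating
  accumulation. TSVs round to 6 decimals and carry the integer numerator
  (`n_matched`) and denominator (`n_target_shq`) so every rate is
  recomputable from the file.
- Set files serialize as sorted key lists with a small header; all
  pipeline outputs are byte-identical across reruns on identical inputs.
- Exit codes: 0 success, 2 configuration/manifest error, 3 data-quality
  error (empty SHQ reference).

## Problem sizes used in the shipped checks

Unit fixtures are in-memory and trivial. Simulated scenarios use 25–400
loci at depth 15–30 for behavioural checks; the closed-form comparison
uses 2,000 loci at depth 50 (two cultivars at 1% divergence, tolerance
±0.03 around 0.99¹⁵⁰ ≈ 0.2215, ~3 binomial standard errors); the
divergence-ordering check uses 20 replicates of 300 loci at depth 20 and
requires the bud-mutant > line > distant ranking in ≥ 19 of 20. These
sizes were chosen to give the assertions clear statistical margins while
keeping the whole suite fast on a single CPU.

## Limitations

- Exact whole-pair matching is deliberately brittle to read-length
  changes: libraries sequenced at different read lengths are not
  comparable without re-filtering to a common length (the toolkit never
  assumes a fixed length, but it also never harmonizes lengths).
- The similarity has no error model attached; it is a descriptive
  statistic, and thresholds for declaring "same cultivar" should be
  calibrated per study from clone pairs, as the group summaries support.
- Approximate (≤ *k*-mismatch) matching, k-mer sketches and locus/SNP
  calling are out of scope by design.
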