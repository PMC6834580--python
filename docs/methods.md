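# Methods

## Target prediction model

A gene is a predicted target of a miRNA when its representative 3′UTR
contains at least one exact Watson–Crick reverse complement of the
miRNA's 7-nt seed (nucleotides 2–8, 1-based from the 5′ end of the
mature strand). The representative 3′UTR is the longest annotated
isoform UTR; ties on maximum length are broken by a seeded uniform
random draw, and genes without any annotated UTR are excluded. Scanning
is exact-match on the UTR sense strand in DNA space (U→T normalised),
overlapping occurrences all reported, coordinates 0-based half-open.

Site classes follow standard nomenclature: a 2–8 match is a 7mer-m8,
upgraded to 8mer when target position t1 (the base immediately 3′ of the
match on the UTR) is adenosine. Target status collapses all enabled
classes (any site ⇒ target). The 7mer-1A class (2–7 match plus t1-A) is
implemented but disabled by default, because the operative criterion is
full seed complementarity; enabling it is a config switch
(`include_7mer_1a`). No context scoring, conservation filtering or
thermodynamics: the predictor is deliberately the bare seed-match rule
whose length-dependence the rest of the pipeline must confront.

## Small-RNA quantification

Reads are split at the first occurrence of the 8-base adapter prefix
(default `TGGAATTC`, the start of the TruSeq small-RNA 3′ adapter);
absent the prefix, the read is kept whole and flagged untrimmed.
Qualities are discarded (FASTQ→FASTA). An insert is counted for a mature
miRNA iff it is an exact substring of the (U→T) mature sequence — a
0-edit, 0-gap short-query match — and its length lies in the window
[18, 26] nt, chosen to exclude degradation fragments below and the 30-nt
2S-rRNA class above; both bounds are configurable, as the window is an
implementation decision, not a biological constant. Multi-matching
inserts increment every matching miRNA by default; `multimap="fractional"`
splits the count 1/k. Both policies are exposed because short inserts can
legitimately match several paralogous matures and neither convention
dominates in practice.

## Expression preparation

Per comparison, TPM is averaged over replicates within condition
(tables must be rectangular), zero-abundance genes are dropped, a
pseudocount c = 1 is added and log2FC = log₂((meanB + c)/(meanA + c))
with B = mated, A = virgin fixed by convention and recorded in the output
metadata. Zero filtering defaults to *per-comparison* scope (drop only
when both condition means are zero): per-condition dropping would break
the pairing the fold change needs, so under `per-condition` scope a gene
is removed from the comparison whenever either condition mean is zero.
The pseudocount bounds |log2FC| ≤ log₂(1 + TPM/c) and shrinks
low-abundance ratios toward zero; antisymmetry under condition swap and
the c→∞ null limit are exact and tested.

## Length confound and its diagnosis

For i.i.d. uniform sequence the expected chance-site count of one seed in
a UTR of length L is (L − 6)·4⁻⁷, so site counts — and hence target
status — rise with UTR length. The diagnosis repeats prediction with
randomly generated seeds (default 401, of length 7, matching the size of
the fly mature-miRNA seed set) and reports per-gene total counts, the
Spearman rank correlation of count with length (the original
demonstration of this effect was visual, via cumulative plots; the
correlation is this package's quantitative summary and is labelled as
such), and ECDF tables stratified by fold-change class for plotting.
Counting uses a per-UTR k-mer table (one pass per UTR rather than one
per seed); equality with the site scanner is asserted in tests. With
constant lengths or constant counts the correlation is undefined and the
report carries a `degenerate` flag instead of a number.

## Matched resampling tests

Lengths of target and non-target genes are binned [0, 200), [200, 400), …
with the final bin closed at the global maximum. Within each bin the
larger group is subsampled **without replacement** to the smaller's
count (without-replacement preserves the minority group's empirical
distribution exactly; bins missing either group contribute nothing).
Matched totals are equal by construction — asserted on every draw. On
the matched vectors:

* **KS**: one-sided two-sample statistic D⁺ = sup(F_target − F_nontarget)
  for alternative `greater` (up-regulated miRNA ⇒ targets repressed ⇒
  target ECDF above), mirrored for `less`; p = exp(−2D²nm/(n+m)), capped
  at 1 — the one-sided asymptotic form. An exact permutation p
  (complete enumeration of pooled splits) is available for n + m ≲ 14 and
  anchors the oracle tests; at the matched sample sizes this pipeline
  produces (hundreds per group) the asymptotic form is accurate.
* **Fisher**: one-sided (`greater`) exact test on
  {target, non-target} × {opposite-direction DE, not}, where *opposite*
  means DOWN-regulated mRNAs for an UP-regulated miRNA and vice versa;
  gene identifiers, not fold changes, are matched for this test. DE
  labels are inputs (or synthetic-truth-derived), never computed here.

Each test is repeated n_reps = 100 times; repetition r uses the
counter-based child stream `default_rng([master_seed, r])`, so runs are
reproducible and repetitions independent. The **arithmetic mean** of the
repetition p-values is the reported summary, BH-adjusted at FDR 0.05
across the non-NA test family (NA results — no targets, or no bin
containing both groups — are excluded from the family and propagated as
NA rows with a reason, never exceptions).

**Caveat**: the mean of p-values over correlated subsample repetitions is
not itself a valid p-value. Because the minority group (usually the
targets) survives matching intact in every repetition, repetitions share
most of their data; the mean concentrates near the dataset's central p,
which makes the summary *conservative* under the null — measured here at
≈1% of null datasets below 0.05 instead of the nominal 5% (single
repetitions are correctly calibrated at ≈5%). The procedure is
reproduced literally because it is the procedure under study; median p
and the per-repetition rejection fraction are reported alongside as
better-behaved diagnostics.

Pairwise combination tests take, for each unordered pair of
same-direction DE miRNAs, the intersection of the two target sets as
targets and genes targeted by **neither** as non-targets (genes targeted
by exactly one are excluded as ambiguous), then proceed identically.

## Synthetic data generator

The generator emulates the statistical structure the analysis is
sensitive to, with one master seed driving named child streams so that
identical configs give byte-identical outputs:

* **UTR lengths**: log-normal, median 500 nt, σ_log = 1.0, truncated by
  resampling at 30 nt — a heavy-tailed law of the kind seen in
  metazoan UTR annotations, giving the length heterogeneity the confound
  machinery needs. Sequences are i.i.d. uniform {A,C,G,T}; chance seed
  matches are expected and intentionally kept.
* **Implants**: per designated miRNA, a `target_fraction` (default 0.3)
  subset of genes receives one exact seed-complement spliced in place
  (7 nt overwritten at a uniform position, never overlapping a previous
  implant), preserving length so matching is exercised honestly.
* **Expression**: baseline log₂TPM ~ Normal(5, 2); the condition effect
  (−`repression_delta` log2 units for targets of up miRNAs,
  +delta for targets of down miRNAs; default delta 1) is applied on the
  log2 scale before multiplicative log-normal replicate noise with
  CV = `replicate_cv` (default 0.2, mean-1 corrected), two replicates per
  condition as in a minimal paired design. No TPM distribution is claimed
  for any real dataset; log-normal is a stand-in.
* **Reads**: each mature miRNA (21–23 nt, mode 22–23) is emitted
  `abundance` times with the 3′ adapter appended and padded/truncated to
  a 50-nt read.

`simulate_statistical` is a sequence-free mode for large Monte-Carlo
studies: lengths from the same law, predicted-target status = implanted
subset ∪ Bernoulli chance matches with p = 1 − (1 − 4⁻⁷)^(L−6) (the
exact chance-match law for one random 7-mer), repression applied to
implants only so chance matches dilute the signal as they do at sequence
level. Calibration and power studies (hundreds of 2,000–4,000-gene
datasets) use this mode; the sequence-level path is exercised by the
oracle, confound and closure tests.

What the generator does **not** emulate: sequencing error, isomiRs,
non-uniform base composition, correlated gene expression, library-size
effects, and real UTR sequence structure (repeats, conservation).
Passing tests therefore demonstrate correctness and statistical behaviour
of the *procedure* under a clean generative model, not recovery of any
particular biological result.

## Numerical and design notes

* RNG: numpy `default_rng` throughout; list-form seeding
  (`[master, stream, …]`) provides independent named streams.
* KS D is computed by ECDF evaluation over the pooled points
  (searchsorted); ties are handled by right-continuous ECDFs.
* Fisher p delegates to `scipy.stats.fisher_exact`; BH to
  `statsmodels.multipletests` (NaN-excluding wrapper). Both are verified
  against exhaustive enumeration in the test suite.
* Problem sizes in tests and the acceptance script (10⁴ oracle
  instances, 200–400 Monte-Carlo datasets of 2,000 genes, 100 of 4,000)
  were chosen to give stable rates at desk scale.
* Degenerate inputs: empty samples raise; unmatched stratifications
  return NA results with reasons; all-zero expression tables come back
  empty with a logged warning.

## Known limitations

* The mean-p summary's null conservatism (above) means borderline
  q-values should be read with care; the rejection-fraction diagnostic is
  the more interpretable number.
* Exact-substring quantification cannot distinguish a mature miRNA from
  a co-linear fragment of another transcript; with real libraries a
  dedicated aligner's report should be preferred when ambiguity matters.
* The one-sided asymptotic KS p is anti-conservative for very small
  matched samples (n + m < ~20); such tests should use the exact option.
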