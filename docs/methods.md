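# Methods

## Model and procedure

A sequencing library is modelled as a finite pool of target molecules,
each ligated to one random barcode before any amplification, so that
every read descends from exactly one (molecule, barcode) pair. Reads have
the 5′ structure `[5-bp sample index][barcode tag][spacer][target]`.
Because read errors strike the barcode region like any other, the
observed tag set is a mixture of true tags (many reads each) and
erroneous tags (few reads each, and — when indels dominate — the wrong
length). The pipeline estimates the boundary between those two
populations from the data itself rather than from a fixed read-count
cutoff, because a fixed cutoff leaves a residue of erroneous tags that
grows indefinitely with sequencing depth while the adaptive threshold
yields a depth-stable molecule count.

Stages, with the constants that govern them:

| stage | rule | default |
|---|---|---|
| demultiplex | exact 5-mer index match | — |
| tag extraction | spacer located by edit distance ≤ 2 within a start window of tag lengths 9–16 (12-bp scheme) | window ±4 |
| read filter | spacer+target length must exceed 70 bases | 70 |
| alignment | semi-global affine (match +1, mismatch −5, open −2, extend −1), free end gaps on the read | — |
| mapping filter | soft-clipped ends ≤ 10% of the aligned payload; identity ≥ 50% | 0.10 / 0.50 |
| tag cleanup | discard tags < 9 bp; merge single-indel 11/13-bp variants into 12-bp parents | — |
| histogram | 2-read bins: bin *k* covers reads-per-tag {2k−1, 2k} | — |
| smoothing | centred 11-bin moving average of per-bin correct-tag proportions | window 11 |
| threshold *M* | lower read bound (2k−1) of the first bin with smoothed proportion ≥ 90% | 0.90 |
| consensus | ≤ 50 longest reads; alternative called only above 80% of covering reads; output quality Q57 | 50 / 0.80 |
| calling | region-level Poisson tail, positive iff P ≤ α | α = 10⁻³; ER 10⁻⁵ (consensus) / 5×10⁻⁴ (raw reads) |

All coordinates are 0-based half-open internally and 1-based inclusive in
reports. Known germline SNP positions can be masked per region; masked
positions count in neither the error-rate numerator nor denominator, and
λ uses the effective (unmasked) region length so that it matches the
positions actually tallied in *n*.

## Numerical choices

* **Poisson tail.** P is evaluated with the scipy survival function; in
  the deep upper tail (P < 10⁻⁸ with n > λ), where the
  incomplete-gamma route loses relative accuracy, it switches to a
  direct log-space summation of the pmf from k = n, which is
  cancellation-free and decreasing there. Tails below the double-precision
  floor are reported as 0.
* **Smoothing of sparse histograms.** The 11-bin moving average weights
  each non-empty bin by its tag count. On densely occupied histograms
  this coincides with the plain mean of bin proportions; on sparse ones
  it estimates P(correct | tag in window) instead of letting a bin that
  happens to hold one or two tags outvote a bin holding hundreds. Empty
  bins contribute nothing (they are not zeros). Edge bins average over
  the bins that exist.
* **Threshold scan.** The first qualifying bin wins; a `strict` flag
  additionally requires every later non-empty bin to qualify. If no bin
  qualifies the run aborts with advice to sequence deeper — at low
  depth the true and erroneous reads-per-tag distributions genuinely
  overlap and no threshold is defensible.
* **Merge ties.** An 11/13-bp variant with several candidate 12-bp
  parents joins the parent with most reads; ties go to the
  lexicographically smaller tag. 12-bp tags never merge with each other,
  and 9–10-bp or ≥14-bp tags survive as their own (erroneous) families.
* **Consensus ties.** The ">80%" rule is evaluated against reads
  covering the position (reads need not span the whole target). With
  more than 50 reads the 50 longest are kept, ties resolved by input
  order, making output invariant to read order otherwise. A consensus
  deletion is an eligible alternative symbol; insertions relative to the
  reference are counted per read and reported separately, never entering
  per-position substitution tallies. Base-change counts *n* for the
  Poisson test are substitutions only, with deletions reported alongside.
* **Alignment.** Targets are short (~60–130 bp) and known, so payloads
  are aligned with a dedicated affine-gap Gotoh kernel (JIT-compiled)
  against every region reference; the reference must be consumed in
  full, read ends are free. Reference positions consumed only by
  terminal deletion runs are treated as uncovered, so truncated reads do
  not fabricate deletion calls. Identical payloads are aligned once
  (cached) — on realistic libraries about half of all reads are
  error-free copies of their molecule's template.

## The simulator

`simlib` emulates the statistical structure the pipeline assumes:

* molecules draw barcodes with replacement from the scheme space
  (4¹² ≈ 1.7×10⁷ for N₁₂; 3¹⁵ for BDHV₁₅), so collisions occur at the
  birthday rate;
* reads per molecule follow a truncated lognormal, default
  μ = ln 60, σ = 0.6 (mean ≈ 72 reads/tag). The real distribution's
  family is not identifiable from published figures; a right-peaked,
  heavy-left-tailed lognormal reproduces its qualitative shape and the
  parameters are exposed in the config;
* per-base errors are independent with configurable rate (default
  5×10⁻³) and indel share (default 0.92 for the Ion profile, 0.05 for
  Illumina); indels are single-base, insertion/deletion equiprobable,
  substitutions uniform over the three alternatives;
* erroneous tags arise only implicitly, from errors falling inside the
  barcode region of individual reads — there is no separate "tag error"
  channel;
* a fixed fraction of molecules carries a configured point mutation;
* FASTQ qualities are constant placeholders (the pipeline never reads
  input qualities and assigns Q57 on output).

What the simulator does **not** model: PCR errors shared by all reads of
a molecule (an optional channel, default off — relevant only to
double-strand labelling designs), ligation-efficiency differences between
molecules, flow-space/homopolymer error structure, chimeric reads, and
read-quality degradation along the read. Passing tests therefore
demonstrate that the algorithms behave as specified under the stated
error model, not that real libraries meet that model; in particular,
absolute error rates on patient libraries are outside what simulation
can certify.

## Problem sizes used in the test suite

Simulated conditions were chosen to exercise each behaviour at the
smallest scale where its statistics are clean: ~2,000 molecules at mean
~72 reads/tag (≈1.4×10⁵ reads) for thresholding and quantitation; 800
molecules at mean ~300 reads/tag for deep-coverage properties (consensus
error suppression; the removed-error-free bound, whose precondition is
mean reads/tag ≫ 2M); 1,500 BDHV molecules at mean ~200 reads/tag for
the saturation contrast, where a substitution-dominant profile is used
because recurrent identical substitutions are what push erroneous tags
across a fixed 1–2-read cutoff as depth grows (single indels are
reabsorbed by the merge step and cannot). The type-I-error check draws
per-run error counts as Binomial(l·m, ER) — a mechanism deliberately
different from the Poisson model under test — across 2,000 mutation-free
runs.

## Known limitations

* Single-strand consensus only; duplex (double-strand) consensus is out
  of scope.
* Single-end reads, one orientation; no quality trimming (none is
  needed — consensus absorbs random read error).
* No sequence-similarity clustering between same-length tags
  (directional-network UMI collapsing); the method distinguishes tags by
  read-count statistics and length/design violations only, so two true
  barcodes one substitution apart are deliberately kept separate.
* The region-level test assumes independent errors across molecules and
  positions; systematic, position-specific artefacts would violate the
  Poisson model and are only mitigated by the clustered/scattered
  annotation.
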