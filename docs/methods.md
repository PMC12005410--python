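# Methods

## The problem

Ultrashort RNAs (roughly 5–20 nt, e.g. the product RNAs — pRNAs —
transcribed from bacterial 6S RNA) ligate poorly to 3' adapters and are
therefore underrepresented in standard small-RNA-seq libraries.  An
alternative is enzymatic 3'-homonucleotide tailing (polyA, polyC or polyU)
before reverse transcription.  Tailing, however, creates blind spots: if
the RNA's own 3' end continues with one or more bases identical to the
tailing nucleotide, trimming the tail from a read also removes those
genuine bases.  All reads ending inside a maximal run of the tail base in
the target — or at the *anchor*, the first non-tail base 5' of the run —
become indistinguishable and are counted at the anchor.  `tailend`
implements the computational side of this protocol: tail trimming, anchored
3'-end profiling, and the numerical merge of two libraries tailed with
*different* bases, whose blind spots do not coincide, into one fully
resolved 3'-end distribution.

## Trimming

A tailed read is cut at the first run of `run_len = 5` consecutive tail
bases that is followed by at least `lookahead = 4` further bases of which
at least `min_matches = 3` are the tail base.  The lookahead window must
exist in full; a read ending in exactly five tail bases is *unselected*.
This reproduces the published selection criterion and its selection loss.
Adapter-ligated reads are cut 5' of the first exact occurrence of the
7-nt seed `AGATCGG` (error rate 0, no alignment).  A minimum retained
length of 4 nt applies to all chemistries (the published pipeline states it
for the adapter library; we apply it uniformly, configurably).  `N` bases
never count as tail or seed matches.

## Mapping

Short targets (< 40 nt, where every length variant shares one 5' end) use
an exact 5-nt 5'-prefix criterion; the 3'-end position equals the trimmed
read length.  Long targets use the first 30 nt of the 3'-proximal 40-nt
window as a mismatch-free anchor; reads must match the target exactly 3'
of the anchor and end at one of the last 11 positions `[L-10, L]`.  The
"first 30 of the last 40" wording plus an 11-position quantification
window contains an inherent off-by-one; we resolve it by letting a read
end flush with the anchor (position `L-10`) as the 11th outcome.  Reads
extending past the target 3' end, or containing the anchor twice, are
rejected (tallied separately), not clipped.  Profiles are normalized
per-mille: `f1000[p] = 1000 · counts[p] / total_mapped`.

## The merge

The merge walks the target 3'→5'.  With tail bases X and Y (e.g. A and C):

* **case #1** — position base differs from both tail bases: merged value is
  the mean of the two libraries' f1000.
* **case #2** — a run of X whose anchor base is Y: the run takes the
  Y-library values verbatim (single-source); the X-library estimate at the
  anchor is its collapsed mass minus the resolved run mass.  The estimate
  is consumed by the next window 5' of it, so interlocking windows chain
  (window order is strictly 3'-most first).
* **case #3** — that subtraction is negative: the libraries are
  incongruent.  The tail-base anchor is clamped to 0, the run receives the
  mean of the two competing window totals (distributed proportionally to
  the resolving library's per-position values when the run spans several
  positions), and one warning per window is emitted.
* **case #4** — a run whose anchor is a non-tail base in both libraries:
  a scaling factor SF = total_collapsed / total_resolved distributes the
  collapsed mass over the window, and the merged value is the per-position
  mean of the two library estimates; the per-position standard deviation
  |x−y|/√2 of those two estimates provides the error bar.

Merged absolute counts are `merged_f1000 / 1000 ×` mean of the two library
totals.

Numerical choices:

* Full float precision throughout; published worked-example intermediates
  are integer-rounded, so tests compare them at ±1 f1000 unit while the
  full-precision values are locked against an exact-rational hand oracle.
* A case #2 subtraction only counts as negative below a relative tolerance
  of 1e-9; otherwise it is clamped to 0.  Without this, float rounding on
  perfectly congruent libraries could fire spurious incongruency warnings.
* A case #4 window whose run mass resolves to 0 degenerates algebraically
  to a plain average at the anchor; the label is downgraded to #1
  accordingly (a zero-mass anchor after case #3 makes its 5' neighbour an
  ordinary unambiguous position).
* The two-estimate SD uses the sample (n−1) form; single-source and
  incongruent positions report sd 0 with a flag.
* Mass is conserved by construction (each window redistributes the mean of
  the two libraries' window masses), so Σ merged_f1000 = 1000; a logged
  renormalization guards against float drift or exotic incongruencies
  (> 1e-6 deviation).
* A tail-base run at the target 5' terminus has no anchor: its reads are
  lost before mapping in the collapsed library.  Such positions are
  reported single-source from the other library, flagged `unresolvable`,
  and excluded from the normalization mass.
* Only pairwise merges are supported; merge of three chemistries is out of
  scope.

## Library simulation

`simulate_tailed_profile` predicts what a tailed library of a chosen depth
would report if a reference profile (typically from an adapter-ligated
library, which has no blind spots) were the truth: every count is scaled
by SF = total_target / total_reference and each ambiguity window's mass
(anchor + run, including zero-count positions) collapses onto the anchor.
This is a deterministic expectation, not a resampling; counts stay real
numbers and are rounded only for display.  Merging the simulated polyA and
polyC libraries returns the reference fractions exactly at all resolvable
positions — an end-to-end consistency check in the test suite.

## Synthetic reads

The generator emulates the sequencing protocol: 75-nt single-end reads,
each a 5' fragment of the target ending at a position drawn from a
programmed true 3'-end distribution, followed by a homonucleotide tail or
the adapter read-through, padded to the read length with the tail base
(standing in for the homopolymer stretch encoded in the RT primer) or a
fixed base after the adapter.  Defaults encode the stated experimental
world: read length 75 nt, error-free bases, tail lengths uniform on
[10, 25] nt — inside the tail-length range observed on tailing gels but
bounded below by 9 nt so that every read carries the five-plus-lookahead
selection signature.  Constant quality `I` is attached and never
interpreted.  One seeded `numpy` generator drives all draws in a fixed
documented order (end positions, then tail lengths, then substitution
errors), so a given seed yields byte-identical FASTQ anywhere.

What a green synthetic round-trip establishes — and what it does not: with
error-free reads and tails ≥ 9 nt, the pipeline profile provably equals
the analytic collapse of the realized truth, and merging an A- and a
C-tailed library recovers the programmed distribution up to sampling
noise.  The generator does not emulate ligation/tailing sequence bias,
PCR duplication, quality degradation, or non-uniform error models, so
green tests say nothing about those effects.  The analytic collapse oracle
additionally assumes the target contains no genomic run of the tail base
of length ≥ 5 outside the 3' region of interest (such a run would truncate
reads at an internal position); the packaged targets satisfy this.

## Known limitations

* Mapping is exact-match by design (the published pipeline disables error
  tolerance); sequencing errors in the anchor or fragment drop reads
  rather than mis-assigning them.
* Paired-end data, quality-based trimming, 5'-adapter removal and
  genome-wide RNA-class annotation are out of scope; reads are assumed to
  start at the RNA 5' end after upstream demultiplexing.  Whether deposited
  raw runs still carry a 5'-adapter remnant is not documented; users
  reprocessing them should verify before trimming.
* The count tables shipped for the tRNA-Glu 3' fragment place the
  reference reads not printed per-position (57 of 212) at a single
  upstream position of a synthetic G/T-only stand-in sequence; all
  quantities computed from them are invariant to that placement, but the
  stand-in is not the biological tRNA sequence (files are labelled
  `synthetic`).
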