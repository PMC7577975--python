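# Methods

## The problem and the model

Plant miRNA precursors are imperfect foldbacks from which DICER-LIKE1
(DCL1) excises a ~21-nt miRNA/miRNA* duplex with two staggered cuts, each
leaving the 2-nt 3' overhang characteristic of Dicer-family ribonucleases.
Although precursors vary widely in size and shape, the two cut regions can
be compared across precursors once every hairpin is placed in a common
coordinate system anchored on the duplex.  `mirduplex` implements that
coordinate system and the positional statistics built on it:

1. **Star inference.**  Given a precursor's secondary structure and its
   mature-miRNA interval, the miRNA* is inferred from the overhang rule:
   star 5' end = partner(miRNA 3' end − 2); star 3' end = partner(miRNA 5'
   end) + 2.  When an anchor position is unpaired, the nearest paired
   position within ±3 nt substitutes and the offset is compensated (ties in
   distance break toward the duplex interior); the record is flagged
   `star_interpolated`.  If no paired anchor exists within ±3 nt at either
   end, the record is quarantined (`star_uninferrable`).  On a perfectly
   complementary duplex the rule forces |star| = |miRNA| and exactly 2-nt
   3' overhangs at both ends; this is asserted exactly in the tests.

2. **Arm registration.**  The 5' arm (walked 5'→3') and the 3' arm (walked
   3'→5') are merged into an ordered alignment of position-pairs by a
   two-pointer walk starting at the basal boundary of the duplex.  Rows are
   *paired* when the pair table links the two pointers, *mismatch* when two
   unpaired nucleotides face each other, and *bulge* (one side gapped) when
   a nucleotide's counterpart is consumed by a pair further along.  The
   walk extends upward until the terminal loop (no pair left inside the
   pointers) and downward toward the precursor base.  For ambiguous
   unpaired runs (asymmetric internal loops) the walk is canonical: it
   maximizes the number of mismatch rows and, among those, pairs each
   5'-arm nucleotide with the outermost available 3'-arm nucleotide.  The
   test suite proves this equals an exhaustive enumeration of monotone
   pairings on every small hairpin with up to two bulges per arm.

3. **Cleavage-site coordinates.**  Coordinate 1 is the basal-most position
   of the miRNA/miRNA* duplex; coordinates increase toward the loop,
   negative coordinates run below the duplex, and 0 does not exist.  The
   basal cut spans {−1, 1, 2, 3} and the apical cut {L, L+1, L+2, L+3} for
   an L-nt miRNA.  For base-to-loop precursors the basal cut is the *first*
   cleavage site; for loop-to-base precursors the labels swap while the
   coordinates stay fixed, so matrices from mixed sets remain comparable.
   Records with unknown direction are treated as base-to-loop and flagged
   (`direction_assumed`), base-to-loop being the more common mechanism.
   The analysis window is 56 coordinates: 15 below the duplex and 41
   at/above it, truncated at the precursor's limits (`short_window` flag).
   The split is configurable; the default covers the documented 15–17-bp
   lower stem plus the duplex and upper region.

4. **Classification and matrices.**  Rows classify as Watson–Crick (A-U,
   G-C), wobble (G-U), mismatch, or bulge.  Mismatch identities are
   reported symmetrically (A-C pools A-C and C-A; ten symmetric classes) or
   ordered (16 classes).  Bulges are never counted as mismatches — identity
   tables stay pure two-nucleotide classes — but fold into "unpaired" for
   the paired/unpaired dichotomy by default.  Overall shares pool positions
   across precursors (a per-precursor averaging mode exists); per-position
   columns always normalize to 100% over records that have the coordinate.
   A structure reporting a paired non-canonical combination raises an
   integrity error rather than being silently reclassified.

5. **Mononucleotide null.**  Under independence, the expected share of the
   ordered pair (x, y) is p(x)·p(y) from the window's nucleotide
   composition; symmetric classes sum their ordered members.  Observed
   matrices are compared by per-class log2(observed/expected) enrichment
   (±∞ sentinels where one side is zero; zero-expectation classes are
   excluded from the fit with a warning) and a per-position chi-square
   goodness of fit computed over the usable classes.

6. **Group comparison.**  Cell-wise percentage-point differences between
   two matrices with two-proportion z-tests, Benjamini–Hochberg adjusted at
   0.05 across all cells.  No phylogenetic correction is applied for shared
   ancestry among species.

## Folding

Structures either arrive precomputed (Vienna dot-bracket) or are computed
by ViennaRNA's MFE fold at default parameters; only the single MFE
structure is used, no suboptimal ensemble, and the engine's defaults
(lonely pairs, dangling ends) are accepted unmodified.  The engine name and
version are embedded in every report.  Folding is unconstrained — the
miRNA/miRNA* pairing is not forced.  Different MFE engines and parameter
sets can shift individual structures; positional percentages from folded
sets should be read with a few-percentage-point engine uncertainty in mind,
which is why precomputed structures take precedence when supplied.

## The synthetic generator

`synthetic_data` builds hairpins row by row in cleavage-site coordinates:
an 8-nt unstructured A-rich flank on each side, a 16-row lower stem
(emulating the 15–17-bp basal dsRNA segment), the L-row duplex region
(L = 21 by default), an 8-row upper extension, and an 8-nt terminal loop.
Each row's class is drawn from a per-coordinate probability vector, with
defaults emulating the positional biases of natural plant precursors:

| region | default |
|---|---|
| coord 1 | G-C 59%, ≥90% paired, no C-C/G-G |
| coord −1 | ~40% unpaired, A-C 25% |
| coords 3 and L+2 | 85% paired |
| other site coords (2, L, L+1, L+3) | ~67% paired, no C-C/G-G |
| lower stem | 90% paired |
| elsewhere | ~67% paired, U-U the most common mismatch, C-C/G-G 0.5% |

Orientation of asymmetric identities is drawn 50/50, so symmetric-mode
statistics are exact targets and ordered-mode splits are binomial.  The
outermost lower-stem row and the topmost row are clamped to Watson–Crick
closing pairs: the registration walk stops below the last basal pair and at
the terminal loop, so an unclamped terminal mismatch row would be silently
dropped and bias class recovery at the edge coordinates.  Per-record seeds
derive from the spec seed through a splittable seed sequence, making every
bundle byte-reproducible.

What the generator does *not* emulate: real species composition and
phylogeny; length variation of loops and stems; sequence covariation
between arms beyond the planted classes.  Two quantitative caveats:

* the overall paired share in the cropped synthetic window is ~75%, above
  the ~65% typical of natural precursor windows, because the strongly
  paired lower stem and site coordinates dominate the shorter synthetic
  hairpin — the per-coordinate site conditions are the primary planted
  quantities and are matched exactly;
* MFE-refolding a generated sequence reproduces the planted pairing at
  ≥95% of duplex positions only for structure-dominant specs (planted
  mismatch density ≲15%).  At the default ~33% mismatch density, runs of
  planted mismatches make alternative folding registers competitive
  (measured 84–86% agreement), so the survey pipeline consumes the
  generator's ground-truth structures and the refolding guarantee is
  asserted for a 12%-mismatch spec.  Passing tests on synthetic data
  therefore demonstrate correctness of registration and statistics given a
  structure, not robustness to folding-engine disagreement on floppy
  hairpins.

## Design-rule screening

`design_check.amirna_check` maps the empirical processing outcomes to
severities: C-C mismatch anywhere → fail; G-G at a cleavage-site coordinate
→ fail, elsewhere → warn; any cleavage-site mismatch outside {A-C, C-U,
U-U} → warn (such variants retain roughly 10% of mature miRNA); unpaired
coordinate 1, 3 or L+2 → warn; C-C inside the duplex additionally carries
an isomiR info note (duplex flexibility can yield small-RNA variants, a
possibly functional outcome, hence not a fail on its own).  Coordinate −1
pairing is never penalized, since ~40% of natural precursors are unpaired
there.  Rules are individually toggleable and every finding carries its
rationale string.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive in every file; internal conventions
  never leak into outputs.
* Percentages keep full precision internally; TSV reports round to two
  decimals, JSON reports carry exact counts (the bit-exact round-trip
  format).
* Dot-bracket parse errors report the 1-based position of the first
  violation; pair tables are validated as involutions.
* Quarantine is conservative and audited: records in = records valid +
  records quarantined, with per-record reasons in the run log; empty inputs
  produce a nonzero exit with an explanatory message.
* Short precursors yield short, flagged alignments; columns lacking a
  record simply exclude it from that denominator.
* miRNA intervals must sit on one arm (terminal closing pairs within 2 nt
  of the interval ends are tolerated); intervals spanning the loop apex or
  entirely unpaired are quarantined, not repaired.

## Problem sizes

The test suite and the acceptance script run on synthetic surveys of
60–500 precursors (≈22,000 window positions at n = 500), exhaustive
registration oracles over all ≈380 hairpin patterns up to 4 interior rows,
and closed-form null cases; the full suite completes in well under a
minute on one CPU.
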