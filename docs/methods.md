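# Methods

## Model

`lasamatch` scores the orthographic confusability of a name pair with the
match value of a spatial-coding comparison. One member of the pair plays
the *stored word* (node *i*), the other the *input*. Both are reduced to
ordered A–Z letter tokens; repeated letters are distinct channels indexed
by occurrence (the second N of SINIPHEN is the token N#2).

1. **Position encoding.** Each letter token receives an activity from a
   monotonically descending series. The default `descending_unit` series
   assigns the *p*-th of *n* letters the value *n* − *p* + 1, i.e. its
   position counted from the end; `ascending_unit` assigns *p* and negates.
   Any strictly descending series is admissible in principle; the unit
   series makes every signal-weight difference an integer displacement,
   and the shift/reflection relating the two packaged series provably
   leaves the match value unchanged (tested).
2. **Binding.** Each word letter token is paired with at most one input
   token of the same letter. `in_order` binding pairs the *k*-th
   occurrence with the *k*-th occurrence; `optimal` binding enumerates the
   per-letter one-to-one assignments and keeps the one maximising the
   final value (the denominator does not depend on the assignment, so
   maximising the superposition peak is equivalent; enumeration is capped
   at 200,000 combinations, far above anything drug-name-length strings
   produce). Each bound pair contributes d = input activity − word weight.
   Word tokens with no partner contribute no Gaussian but still count in
   the denominator — otherwise two disjoint names could score 1.
3. **End markers.** Two extra channels compare the first letters and the
   last letters of the pair. A channel fires only when the letters agree
   and then contributes the positional difference of the two end tokens
   (0 whenever the names have equal length); the pair of channels adds 2
   to the denominator whether or not they fire. Computing the marker d in
   the same frame as the letter ds is what keeps the value invariant to
   code shifts and identical across code series for unequal-length pairs;
   pinning markers at 0 breaks both invariants.
4. **Superposition and peak.** Every center d contributes
   exp(−(d − x)²/σ); the peak of the sum over x measures how many channels
   agree on a common displacement. σ is the letter-position uncertainty.
   The exponent divides by σ itself (not σ²), matching the source
   formulation of the difference function; a `sigma_squared_exponent` flag
   provides the alternative normalisation, off by default.
5. **Normalisation.** M = peak / l. By default l is the word's letter
   count (+2 with markers); `denominator_mode` can instead select the
   input's count, the longer, the shorter, or the mean of the two. Under
   every mode the number of Gaussian centers cannot exceed the
   denominator, so 0 ≤ M ≤ 1 holds by construction and is never clamped.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `sigma` | 3 | width of the Gaussian difference functions (positional tolerance, in letter-position units); larger σ forgives larger displacements |
| `end_markers` | on | first/last-letter channels; needed to reproduce the reference table's anchor rows exactly |
| `word_role` | `first_name` | the local proprietary name is the stored word |
| `denominator_mode` | `word` | word letter count (+2 with markers) normalises the peak |
| `binding_mode` | `in_order` | deterministic occurrence-wise binding of repeated letters |
| `code_series` | `descending_unit` | unit descending position code |

This default set is the *calibrated convention*: with it, TINYPHEN/SINIPHEN
reproduces its printed 70 exactly and FARALEX/FARMALEX computes 92.1
against a printed 91. The published analysis does not state its
conventions; the calibration rests on those anchor rows, and the
`reproduce_reference` sweep reports every convention's median absolute
deviation rather than pretending one convention reproduces all 99 printed
values (none does; CIPLEX/IPLEX, printed 75, happens to reproduce exactly
under the calibrated convention because the shared suffix aligns at
displacement 0). Computed percents are compared with printed values at
the table's printed precision, i.e. rounded to integers.

## Risk banding and summaries

Match percents are banded with inclusive lower edges: high ≥ 66,
medium ≥ 33, low ≥ 1; values below 1% get the label `none` (the sub-1%
band is unnamed in the source thresholds). `summarize` reports the mean
on the percent scale and the standard deviation on the 0–1 scale — the
scale on which the reference table prints its footer — population divisor
by default, sample by flag. Missing values are excluded from mean/SD and
counted under their printed band when one exists (the table's one
valueless row prints a high rating). Of note: the exact population SD of
the 99 printed values is 0.09924 (sample 0.09974); the table footer's
"0.09" is that value truncated, not rounded, to two decimals.

## Peak finding

F(x) is a positive 1-D Gaussian mixture, so its global maximum lies in the
convex hull of the centers. `find_peak` deduplicates centers into
weighted components, evaluates F on a coarse grid over [min d, max d] with
step ≤ min(0.05, √(σ/2)/8) — well below the component width √(σ/2), so
every local maximum is bracketed — then narrows all candidate brackets in
lockstep by vectorised 9-point grid-zoom rounds (width ÷ 4 per round) down
to 10⁻⁸, keeping every near-tied mode until the end. Ties within 10⁻⁹ of
the maximum break toward the smallest x, for determinism. Against an
exhaustive 10⁻⁴-step grid oracle the worst peak-height error over 1,000
random center multisets is below 10⁻⁸. All-coincident centers shortcut to
the exact answer (the center, the channel count), which is why identity
pairs score exactly 1.0 in floating point. Degenerate inputs: an empty
center set has peak 0; σ ≤ 0 is a validation error; single-letter names
are legal, empty names are errors, never silently skipped.

## Synthetic cohorts

`synthetic` generates the name population the screening analysis assumes:
uppercase strings, lengths drawn uniformly from 5–13 by default (the
typical proprietary-name range), i.i.d. uniform letters, or repeat-free
sampling for the closed-form regime. Variants apply a controlled recipe —
deletions, then substitutions, then adjacent transpositions, then
insertions, a fixed order chosen for reproducibility — at seed-determined
positions, logging every edit. Substituted-in and inserted letters are
drawn from letters absent from the base and from each other, so on a
repeat-free base of length *n* with markers off and the word denominator
the expected values are exact: one substitution scores (n−1)/n, one
adjacent transposition (n−2+2e^(−1/σ))/n. These closed forms, the
identical > transposed > substituted ordering, and the monotone decline of
the mean match with substitution count are asserted in the tests and the
acceptance sweep.

What the generator does **not** emulate: pharmaceutical morphology (stems
like -pril/-mab, shared prefixes by therapeutic class), letter-frequency
structure, or phonetics. Passing property suites on these cohorts
establishes the mathematical behaviour of the score, not its operating
characteristics on a real formulary, where names are far from uniform
strings; the packaged reference table is the only real-data anchor, and it
validates summary-level, not pairwise, agreement.

## Problem sizes

The acceptance property sweep uses 10,000 seeded pairs (8,000 edit-related
across an eight-cell grid, 2,000 unrelated) under all 80 convention
combinations in the test suite, and 2,000 pairs in the standalone
acceptance script; the oracle comparison uses 1,000 random center sets,
the transposition-ordering suite 500 repeat-free bases, and the
monotonicity suite 300 pairs — sizes chosen so the whole pipeline
re-verifies in a few minutes on one core while keeping every estimate's
Monte-Carlo error far below the margins being asserted.

## Known limitations

- Orthographic only: no sound-alike (phonetic) component is computed.
- The published conventions are underdetermined; all convention choices
  remain selectable and the sweep quantifies their effect, but the
  calibrated default rests on two anchor rows.
- `optimal` binding is exhaustive per letter type; pathological inputs
  (one letter repeated many times in both names) hit the enumeration cap.
- Indication comparison — whether two similar names would actually be
  co-prescribed — is a curation step outside the package's scope.
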