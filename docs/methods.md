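# Methods

## Generative model for the synthetic benchmark

Each dataset is built from a single seeded RNG stream:

1. **Parent sequence.** `parent_length` residues (default 180) drawn
   i.i.d. uniformly from the 20 standard amino acids
   (`ARNDCQEGHILKMFPSTWYV`).
2. **Children.** `n_sequences − 1` children (default 9) are derived
   from the parent independently per site: with probability `p_gap`
   (default 0.05) the site becomes a gap `-`; otherwise with
   probability `p_mut` (default 0.1) it is substituted by a uniform
   draw over the **other 19** residues; otherwise it is copied. Two
   deliberate choices make the model exactly testable: gapping is
   evaluated before substitution, so the marginal gap rate is exactly
   `p_gap`; and substitutions never reproduce the parent residue, so
   the mismatch rate among non-gap sites is exactly `p_mut`. Children
   never insert columns, so every row has the parent's length and
   alignment columns coincide with parent residue indices (1-based,
   inclusive).
3. **Regions.** A region count is drawn uniformly over
   `region_count_range` (default {2,…,5}; "between two and five" admits
   other distributions, and uniform is the natural minimal choice —
   note that under it a 100-dataset corpus totals 350 ± 11.2 regions,
   so any single printed realization in the high 370s is a ~2.4 σ
   draw). Lengths are uniform over [10, 30]; start columns are drawn
   uniformly and accepted when all pairwise separations after sorting
   are ≥ `min_inter_region_gap` (default 4). Rejection sampling is
   bounded: 1000 start draws per length vector, 10 length resamples,
   then a `GenerationError` naming the violated constraint. At the
   defaults the worst case (5 × 30 + 4 × 4 = 166 ≤ 180) is always
   feasible, so termination is guaranteed in practice.
4. **Names.** Each region draws a base name uniformly from the pool
   ("Mutation Hotspot", "Low Conservation", "Binding Site",
   "Structural Motif") and receives a letter suffix assigned per base
   name in ascending start order (A, B, C, …; a base used once still
   gets "A"), so full names are unique within a dataset.

Corpora derive per-dataset seeds from `(master_seed, index)` via a seed
sequence, recorded in the manifest; regeneration from the manifest
reproduces ground truth byte-for-byte.

**What the generator does not emulate:** real MSAs vary in depth,
length, substitution structure (no rate matrices or indel-length
models here) and figure style. The synthetic images are deliberately
clean and homogeneous, so accuracies measured on them should be read
as an approximate upper bound for annotators facing the heterogeneous
figures of the published literature. Passing benchmarks here says an
annotator can read this controlled format, not any journal's.

## Rendering

Alignments are wrapped at `wrap_length` columns per row panel (default
60; 180 columns → 3 panels), residue numbers every `tick_interval`
columns (default 10). Each region is drawn as a bar colored by an
independent uniform draw from the palette (red, green, blue, orange,
purple; collisions allowed), its name above the bar start in the same
color. A region crossing a wrap boundary is split across panels with
the label only on the starting fragment — precisely the visual
situation that invites "improvised name" errors for the continuation
fragment. Letters are colored by a fixed residue-group scheme; font
and letter-coloring details are not part of the measured contract.

The output file is standardized to exactly `canvas_size` pixels
(default 1006 × 867) by Lanczos resampling of the rendered figure,
because native figure output varies with plotting backend and DPI while
the benchmark fixes the pixel geometry annotators see. Images are saved
through Pillow without timestamps, so re-rendering the same dataset is
byte-identical.

## Annotation backends

All backends produce per-image `AnnotationResult`s (records, raw
responses, attempt count, blank flag) through the same contract.

**Parsing pipeline.** Raw text is stripped of code-fence lines and
surrounding backticks; the list-of-lists literal following the *last*
`parsed_result =` assignment is located by a balanced-bracket scan
(responses often restate the requested format before answering, so the
final assignment is taken as the answer; whitespace around `=` is
tolerated); the literal is read with `ast.literal_eval` only — response
content is never executed, which a test verifies with a payload that
would create a file if evaluated as code. Each element must be
`[name, start, end]` with a textual name; numeric strings are silently
coerced to integers (annotators sometimes quote numbers, and coercion
loses nothing). Failures carry a reason: `missing_key`, `syntax`, or
`schema`.

**Retries.** `max_attempts` counts total queries (default 3, so a
failed image is three unparsable outputs in a row). Transport errors
count as attempts. After the last failure a blank result is returned
with every raw response archived. The default pacing pauses (5 s
between images, 3 s before retries) exist for API quota management and
are set to 0 for offline backends and tests.

**Simulated annotator.** Per true region, independently: miss with
`p_miss`; otherwise emit with per-endpoint jitter uniform on
[−`jitter_halfwidth`, +`jitter_halfwidth`]; with `p_row_shift` subtract
`row_width` (default 60) from both endpoints (the one-row-up misread);
with `p_name_typo` corrupt one character of the name; with
`p_duplicate` re-emit the record. Finally with `p_spurious` append one
fabricated region with an improvised name drawn from a pool disjoint
from the generator's ("Unlabeled Region", "Unknown", "Unnamed
Segment"). The signed boundary error therefore follows the analytic
mixture `(1−p)·J + p·(−row_width + J)` with `J` uniform on the jitter
set, giving E|error| = (1−p)·E|J| + p·E|−row_width + J|; tests recover
these values within 3 Monte-Carlo standard errors over ≥ 10⁴ regions.
In pipeline runs the simulated backend emits its records as response
text in the prompts' requested format, so simulated corpora exercise
the same parsing path as a live VLM.

**Human import.** A TSV with columns `image_id`, `sbre`, `start`,
`end`; names are whitespace-trimmed, boundaries must parse as integers
(row-level errors report the line number), and images absent from the
file evaluate as blank results.

## Evaluation protocol

Per image, predicted names are normalized (whitespace-trimmed; default
matching is case-sensitive, since the protocol demands exact match — a
case-insensitive matcher is provided because annotators demonstrably
emit sentence-case variants of correct names) and deduplicated into a
set. Correct = |predicted set ∩ truth set|. Precision, recall and F1
are micro-averaged: counts are pooled over all images before dividing.
Blank results contribute zero extractions but their truth regions stay
in the recall denominator. Precision (and MAE) with an empty
denominator is reported as null rather than 0 — extracting nothing is
not the same as extracting everything wrong; F1 is then null as well.

For boundaries, each predicted record whose normalized name matches
exactly one truth region *and* was not predicted more than once in that
image is paired with that region; it contributes signed errors
(estimated − truth) for start and end separately. Mismatched and
duplicated names are excluded and counted (both copies of a duplicate
are excluded). No validity filter is applied to predictions: inverted
or out-of-range boundaries are paired and their errors reported as-is.
MAE is the mean absolute signed error per endpoint. Histograms use
integer-aligned bins of configurable width; the −60 band of the signed
error distribution isolates the row-misassignment mode.

## Numerical and design choices

- Seeds: per-dataset seeds derive from `(master_seed, index)` and stay
  below 2³¹; the annotation stream in a pipeline run derives from the
  master seed under a distinct index so generation and annotation
  noise are decoupled.
- Degenerate inputs: zero-length parents, empty region lists in
  sidecars, empty prediction lists, and empty error vectors are all
  defined (empty string, header-only TSV, null precision, null MAE).
- Problem sizes: the test suite validates 1000 generated datasets for
  structural invariants, uses 10⁴-region Monte-Carlo checks for rate
  recovery, and runs the end-to-end identity pipeline on a 100-dataset
  corpus; rendering-specific checks use a handful of images since every
  render is standardized to identical pixel geometry.
- The end-to-end pipeline can skip rendering (`render: false`): the
  offline backends consume ground truth rather than pixels, so
  evaluation-oriented runs need not pay the rendering cost. Rendered
  output is validated by its own dimension and determinism checks.

## Limitations

- The simulated annotator is a parametric caricature of observed error
  modes; it recovers its own parameters by construction and is meant
  for calibrating the evaluation machinery and generating controlled
  error distributions, not for predicting any particular model's
  accuracy. Live-annotator accuracy tables require live annotators.
- Exact-match name scoring gives no partial credit (no edit-distance or
  overlap/IoU matching); a single typo costs both the name and its
  boundary pair, which is the intended strictness of the protocol.
- The renderer fixes one visual style; robustness of annotators across
  the heterogeneous styles of real publications is out of scope.
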