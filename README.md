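# msabench

A benchmark-generation and evaluation toolkit for measuring how well
annotators — vision–language models (VLMs), simulated error models, or
humans — extract **named structural regions and their residue ranges**
from raster images of multiple sequence alignments (MSAs).

## The problem

Structural biology papers routinely define functionally relevant
segments of a protein in sequence figures: an MSA image with colored
bars and names such as "Mutation Hotspot A" spanning residues 39–56.
The name is a *structural biological referring expression* (SBRE); the
residue range it denotes is the definition of a *structural biological
entity* (SBE). Linking the two at scale requires extracting both from
rasterized figures, and it is an open question how accurately automated
annotators (in particular VLMs) can do this compared with trained
humans.

`msabench` answers this with a fully synthetic, fully ground-truthed
benchmark:

1. **Generate** — a random 180-residue parent sequence (i.i.d. uniform
   over the 20 standard amino acids), nine children derived per site
   with gap probability 0.05 and substitution probability 0.1
   (substitutions always change the residue), giving a 10 × 180
   alignment. Two to five named regions of length 10–30 are placed with
   at least four columns between them.
2. **Render** — the alignment wrapped at 60 columns per row with
   residue numbers every 10 columns, each region drawn as a colored bar
   (red/green/blue/orange/purple, drawn uniformly) with its name above
   in the same color; output standardized to exactly 1006 × 867 px PNG.
3. **Annotate** — any backend that maps (image, prompt) → text can be
   plugged in. Responses are parsed by stripping formatting, taking the
   list-of-lists literal after the last `parsed_result =` sentinel, and
   reading it with `ast.literal_eval` (never executed). Up to three
   attempts per image; after three failures a blank result is archived.
   A parametric simulated annotator (misses, boundary jitter, one-row-up
   offsets, duplicates, name typos, improvised spurious regions) and a
   human-annotation TSV importer run fully offline.
4. **Evaluate** — per image, predicted names are deduplicated into a
   set and counted correct only on exact match; precision, recall and
   F1 are micro-averaged over the corpus:

   P = Σ correct / Σ extracted,  R = Σ correct / Σ truth,  F1 = 2PR/(P+R).

   Each uniquely name-matched record contributes signed boundary errors
   (estimated − truth) for start and end; mismatched or duplicated names
   are excluded. MAE(start) and MAE(end) are means of absolute errors,
   and signed-error histograms expose systematic modes such as the −60
   peak caused by reading a bar one wrapped row too high.

## Worked example

Score one image whose annotator found the three true regions (with
sentence-case names and slipped boundaries) plus one improvised
"Unlabeled region":

```python
from msabench import (AnnotationResult, ExtractedRegion, MatcherConfig,
                      RegionAnnotation, build_report)

truth = [RegionAnnotation("Mutation Hotspot A", 39, 56),
         RegionAnnotation("Low Conservation A", 63, 75),
         RegionAnnotation("Low Conservation B", 116, 128)]
pred = AnnotationResult("img_000", [
    ExtractedRegion("Mutation hotspot A", 37, 59),
    ExtractedRegion("Low conservation A", 10, 28),
    ExtractedRegion("Low conservation B", 126, 137),
    ExtractedRegion("Unlabeled region", 111, 119)], [], 1, False)

report = build_report([pred], {"img_000": truth},
                      MatcherConfig(case_sensitive=False))
print(report.summary())
```

```
images:            1
truth regions:     3
extracted names:   4
correct names:     3
precision:         0.750
recall:            1.000
F1-score:          0.857
MAE (start):       21.667
MAE (end):         19.667
matched pairs:     3
excluded records:  1
```

Three of the four extracted names match ground truth (precision 0.75);
all true regions were found (recall 1.0). The matched records give
signed start errors (−2, −53, +10) and end errors (+3, −47, +9) —
MAE(start) = 65/3 ≈ 21.667 — and the improvised record is excluded from
boundary scoring. The −53/−47 pair is the signature of a one-row-up
misread on a 60-column wrap.

## Command line

```bash
msabench generate --n 100 --seed 42 --out corpus/      # alignments + ground truth + manifest
msabench render   --corpus corpus/                     # 1006x867 PNG per dataset
msabench annotate --corpus corpus/ --backend simulated --seed 7
msabench evaluate --corpus corpus/                     # prints the summary table
msabench pipeline --out run/ --seed 42                 # all of the above in one step
```

Corpora are reproducible: the manifest records the master seed and each
dataset's derived seed, and regeneration from the manifest reproduces
ground truth byte-for-byte. A live VLM backend is any Python callable
`(image, prompt) -> str` passed to `run_pipeline(..., transport=...)`;
the shipped prompt constants (`PROMPT_NAIVE`, `PROMPT_STRICT`) are the
two prompt styles the benchmark defines.

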