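"""Scoring annotator outputs against ground truth.

Two levels of evaluation:

* name extraction (SBREs): per image, predicted names are deduplicated
  into a set and counted correct only on exact match with ground truth;
  precision, recall and F1 are micro-averaged, i.e. computed from
  counts pooled over all images;
* boundary extraction (SBE definitions): each predicted record whose
  name matches exactly one truth region, and was not predicted more
  than once, contributes signed errors (estimated - truth) for start
  and end; mismatched or duplicated names are excluded. The signed
  convention makes a one-row-above misread on a 60-column wrap appear
  as -60.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .backends import AnnotationResult, ExtractedRegion
from .synthetic import RegionAnnotation


@dataclass(frozen=True)
class MatcherConfig:
    """How predicted names are compared with ground-truth names.

    Default is case-sensitive exact match after whitespace trimming;
    ``case_sensitive=False`` casefolds both sides first.
    """

    case_sensitive: bool = True
    trim_whitespace: bool = True

    def normalize(self, name: str) -> str:
        if self.trim_whitespace:
            name = name.strip()
        if not self.case_sensitive:
            name = name.casefold()
        return name

    def to_dict(self) -> dict:
        return {"case_sensitive": self.case_sensitive, "trim_whitespace": self.trim_whitespace}


@dataclass
class BoundaryErrors:
    """Signed boundary errors over uniquely name-matched pairs."""

    start_errors: list[int] = field(default_factory=list)
    end_errors: list[int] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.start_errors)


@dataclass
class Histogram:
    """Integer-aligned histogram of signed errors."""

    edges: list[float]
    counts: list[int]

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def mass(self, lo: float, hi: float) -> float:
        """Fraction of entries whose bin lies inside [lo, hi]."""
        if self.total == 0:
            return 0.0
        inside = sum(
            c
            for left, right, c in zip(self.edges[:-1], self.edges[1:], self.counts)
            if left >= lo and right <= hi
        )
        return inside / self.total


@dataclass
class EvaluationReport:
    """Pooled name-extraction metrics plus boundary-error summaries.

    ``precision`` (and the MAEs) are None when their denominators are
    empty — extracting nothing is not the same as extracting everything
    wrong.
    """

    precision: Optional[float]
    recall: float
    f1: Optional[float]
    mae_start: Optional[float]
    mae_end: Optional[float]
    n_images: int
    n_truth_regions: int
    n_extracted_names: int
    n_correct_names: int
    errors: BoundaryErrors
    histogram: Histogram

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mae_start": self.mae_start,
            "mae_end": self.mae_end,
            "n_images": self.n_images,
            "n_truth_regions": self.n_truth_regions,
            "n_extracted_names": self.n_extracted_names,
            "n_correct_names": self.n_correct_names,
            "errors": {
                "start_errors": list(self.errors.start_errors),
                "end_errors": list(self.errors.end_errors),
                "n_excluded": self.errors.n_excluded,
            },
            "histogram": {"edges": list(self.histogram.edges), "counts": list(self.histogram.counts)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            precision=d["precision"],
            recall=d["recall"],
            f1=d["f1"],
            mae_start=d["mae_start"],
            mae_end=d["mae_end"],
            n_images=d["n_images"],
            n_truth_regions=d["n_truth_regions"],
            n_extracted_names=d["n_extracted_names"],
            n_correct_names=d["n_correct_names"],
            errors=BoundaryErrors(
                start_errors=list(d["errors"]["start_errors"]),
                end_errors=list(d["errors"]["end_errors"]),
                n_excluded=d["errors"]["n_excluded"],
            ),
            histogram=Histogram(
                edges=list(d["histogram"]["edges"]), counts=list(d["histogram"]["counts"])
            ),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary(self) -> str:
        def fmt(x, nd=3):
            return "n/a" if x is None else f"{x:.{nd}f}"

        lines = [
            f"images:            {self.n_images}",
            f"truth regions:     {self.n_truth_regions}",
            f"extracted names:   {self.n_extracted_names}",
            f"correct names:     {self.n_correct_names}",
            f"precision:         {fmt(self.precision)}",
            f"recall:            {fmt(self.recall)}",
            f"F1-score:          {fmt(self.f1)}",
            f"MAE (start):       {fmt(self.mae_start)}",
            f"MAE (end):         {fmt(self.mae_end)}",
            f"matched pairs:     {self.errors.n_matched}",
            f"excluded records:  {self.errors.n_excluded}",
        ]
        return "\n".join(lines)


def dedupe_names(
    records: Sequence[ExtractedRegion], matcher: MatcherConfig = MatcherConfig()
) -> tuple[set[str], set[str]]:
    """Normalize predicted names into a set; also report duplicated names."""
    seen: dict[str, int] = {}
    for rec in records:
        name = matcher.normalize(rec.sbre)
        seen[name] = seen.get(name, 0) + 1
    names = set(seen)
    duplicated = {name for name, count in seen.items() if count > 1}
    return names, duplicated


def _truth_map(
    truths: Mapping[str, Sequence[RegionAnnotation]], matcher: MatcherConfig
) -> dict[str, dict[str, RegionAnnotation]]:
    out = {}
    for dataset_id, regions in truths.items():
        out[dataset_id] = {matcher.normalize(r.sbre): r for r in regions}
    return out


def _check_pairing(results, truths) -> None:
    missing = [r.dataset_id for r in results if r.dataset_id not in truths]
    if missing:
        raise KeyError(f"no ground truth for dataset ids: {missing}")


def score_sbre_corpus(
    results: Sequence[AnnotationResult],
    truths: Mapping[str, Sequence[RegionAnnotation]],
    matcher: MatcherConfig = MatcherConfig(),
) -> dict:
    """Micro-averaged precision/recall/F1 on deduplicated names."""
    _check_pairing(results, truths)
    n_correct = n_extracted = n_truth = 0
    for result in results:
        truth_names = {matcher.normalize(r.sbre) for r in truths[result.dataset_id]}
        predicted, _ = dedupe_names(result.records, matcher)
        n_correct += len(predicted & truth_names)
        n_extracted += len(predicted)
        n_truth += len(truth_names)
    precision = n_correct / n_extracted if n_extracted else None
    recall = n_correct / n_truth if n_truth else 0.0
    if precision is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_correct_names": n_correct,
        "n_extracted_names": n_extracted,
        "n_truth_regions": n_truth,
    }


def boundary_errors(
    results: Sequence[AnnotationResult],
    truths: Mapping[str, Sequence[RegionAnnotation]],
    matcher: MatcherConfig = MatcherConfig(),
) -> BoundaryErrors:
    """Signed (estimated - truth) errors for uniquely matched records.

    Records whose name does not match any truth region, or whose name
    was predicted more than once in the same image, are excluded and
    counted.
    """
    _check_pairing(results, truths)
    by_name = _truth_map(truths, matcher)
    errors = BoundaryErrors()
    for result in results:
        truth_names = by_name[result.dataset_id]
        _, duplicated = dedupe_names(result.records, matcher)
        for rec in result.records:
            name = matcher.normalize(rec.sbre)
            if name in duplicated or name not in truth_names:
                errors.n_excluded += 1
                continue
            truth = truth_names[name]
            errors.start_errors.append(rec.start - truth.start)
            errors.end_errors.append(rec.end - truth.end)
    return errors


def mae(errors: BoundaryErrors) -> tuple[Optional[float], Optional[float]]:
    """Mean absolute error per endpoint; None when no pairs matched."""
    mae_start = (
        float(np.mean(np.abs(errors.start_errors))) if errors.start_errors else None
    )
    mae_end = float(np.mean(np.abs(errors.end_errors))) if errors.end_errors else None
    return mae_start, mae_end


def error_histogram(values, bin_width: int = 1) -> Histogram:
    """Histogram signed errors into integer-aligned bins of ``bin_width``.

    Accepts a sequence of signed errors or a ``BoundaryErrors`` (start
    and end errors pooled). Bin edges are multiples of ``bin_width``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if isinstance(values, BoundaryErrors):
        values = list(values.start_errors) + list(values.end_errors)
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return Histogram(edges=[], counts=[])
    lo = int(np.floor(values.min() / bin_width)) * bin_width
    hi = (int(np.floor(values.max() / bin_width)) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return Histogram(edges=[float(e) for e in edges], counts=[int(c) for c in counts])


def build_report(
    results: Sequence[AnnotationResult],
    truths: Mapping[str, Sequence[RegionAnnotation]],
    matcher: MatcherConfig = MatcherConfig(),
    bin_width: int = 1,
) -> EvaluationReport:
    """Assemble the full evaluation report for a corpus of results."""
    scores = score_sbre_corpus(results, truths, matcher)
    errors = boundary_errors(results, truths, matcher)
    mae_start, mae_end = mae(errors)
    return EvaluationReport(
        precision=scores["precision"],
        recall=scores["recall"],
        f1=scores["f1"],
        mae_start=mae_start,
        mae_end=mae_end,
        n_images=len(results),
        n_truth_regions=scores["n_truth_regions"],
        n_extracted_names=scores["n_extracted_names"],
        n_correct_names=scores["n_correct_names"],
        errors=errors,
        histogram=error_histogram(errors, bin_width),
    )
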