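"""Annotation backends and the response-parsing pipeline.

Three interchangeable ways to produce ``ExtractedRegion`` records for a
benchmark image:

* a pluggable VLM transport (any callable taking an image and a prompt
  and returning raw text), driven through the prompt constants, the
  sentinel-based parser and a bounded retry protocol;
* a parametric simulated annotator that perturbs the ground truth with
  the empirically observed error modes (misses, boundary jitter,
  one-row-up offsets, duplicated records, name typos, improvised
  spurious regions);
* import of human annotations from a TSV spreadsheet export.

Parsing is strictly literal: model responses are never executed, only
read with ``ast.literal_eval`` after sentinel extraction.
"""

from __future__ import annotations

import ast
import csv
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .synthetic import RegionAnnotation

PathLike = Union[str, Path]

PROMPT_NAIVE = (
    "This is a figure from a biological paper. Identify any structural region "
    "defined here. Report the python list of lists as parsed_result = "
    "[[region_name, region_init, region_end],...]"
)

PROMPT_STRICT = (
    "This is a figure from a biological paper. Identify any structural region "
    "defined here. You must extract the residue indexes as precisely as possible "
    "from the figure, ideally at one-residue resolution. Residue indexes are "
    "shown at sparse, roughly regular intervals for clarity, so you'll need to "
    "estimate the actual start and end positions of structural regions by "
    "interpolating between the visible labels. Report the python list of lists "
    "as parsed_result = [[region_name, region_init, region_end],...]"
)

SENTINEL = "parsed_result"

IMPROVISED_NAME_POOL = ("Unlabeled Region", "Unknown", "Unnamed Segment")


def build_prompt(mode: str) -> str:
    """Return the verbatim prompt text for mode ``naive`` or ``strict``."""
    prompts = {"naive": PROMPT_NAIVE, "strict": PROMPT_STRICT}
    try:
        return prompts[mode]
    except KeyError:
        raise ValueError(f"unknown prompt mode {mode!r}; expected 'naive' or 'strict'")


class ParseFailure(Exception):
    """A response that could not be turned into records.

    ``reason`` is one of ``missing_key`` (no sentinel assignment found),
    ``syntax`` (no balanced literal / not literal Python), or ``schema``
    (literal parsed but elements are not ``[name, start, end]``).
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class ExtractedRegion:
    """One predicted (name, start, end) record.

    No validity constraints are imposed at parse time: predictions may
    be out of range or inverted; evaluation handles them.
    """

    sbre: str
    start: int
    end: int


@dataclass(frozen=True)
class RetryPolicy:
    """Bounded retry protocol for the VLM transport.

    ``max_attempts`` counts total queries (default 3: a failure means
    three unparsable outputs in a row). The pauses exist for API quota
    pacing, not correctness; set them to 0 in tests.
    """

    max_attempts: int = 3
    inter_image_pause: float = 5.0
    pre_retry_pause: float = 3.0

    def __post_init__(self) -> None:
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.inter_image_pause < 0 or self.pre_retry_pause < 0:
            raise ValueError("pauses must be >= 0")


@dataclass
class AnnotationResult:
    """Per-image annotator output, blank when all attempts failed."""

    dataset_id: str
    records: list[ExtractedRegion]
    raw_responses: list[str]
    n_attempts: int
    blank: bool


_FENCE_LINE = re.compile(r"```[\w+-]*\s*$")


def strip_formatting(raw: str) -> str:
    """Remove code-fence markers, surrounding backticks and outer whitespace."""
    text = raw.strip()
    lines = [ln for ln in text.splitlines() if not _FENCE_LINE.fullmatch(ln.strip())]
    return "\n".join(lines).strip().strip("`").strip()


def _scan_balanced_list(text: str) -> Optional[str]:
    """Return the leading balanced ``[...]`` literal of ``text``, or None."""
    if not text.startswith("["):
        return None
    depth = 0
    quote: Optional[str] = None
    i = 0
    while i < len(text):
        ch = text[i]
        if quote is not None:
            if ch == "\\":
                i += 2
                continue
            if ch == quote:
                quote = None
        elif ch in "'\"":
            quote = ch
        elif ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth == 0:
                return text[: i + 1]
        i += 1
    return None


def extract_payload(cleaned: str, sentinel: str = SENTINEL) -> str:
    """Extract the bracketed literal after the last ``<sentinel> =``.

    Responses may restate the expected format before answering, so the
    final assignment is taken as the model's answer. Raises
    ``ParseFailure(missing_key)`` when no such assignment exists and
    ``ParseFailure(syntax)`` when nothing balanced follows it.
    """
    positions = [m.start() for m in re.finditer(re.escape(sentinel), cleaned)]
    if not positions:
        raise ParseFailure("missing_key", f"no {sentinel!r} in response")
    for pos in reversed(positions):
        rest = cleaned[pos + len(sentinel):].lstrip()
        if not rest.startswith("="):
            continue
        payload = _scan_balanced_list(rest[1:].lstrip())
        if payload is None:
            raise ParseFailure("syntax", "no balanced list literal after sentinel")
        return payload
    raise ParseFailure("missing_key", f"{sentinel!r} never followed by '='")


def _coerce_boundary(value) -> int:
    if isinstance(value, bool):
        raise ParseFailure("schema", f"boundary {value!r} is not an integer")
    if isinstance(value, int):
        return value
    if isinstance(value, float) and value.is_integer():
        return int(value)
    if isinstance(value, str):
        try:
            return int(value.strip())
        except ValueError:
            pass
    raise ParseFailure("schema", f"boundary {value!r} is not an integer")


def parse_literal(literal: str) -> list[ExtractedRegion]:
    """Safely interpret a list-of-lists literal into records.

    Uses literal evaluation only — response content is never executed.
    Every element must be a 3-item ``[name, start, end]`` with a textual
    name and integer (or numeric-string) boundaries; one malformed
    element fails the whole parse.
    """
    try:
        value = ast.literal_eval(literal)
    except (ValueError, SyntaxError, MemoryError, RecursionError) as exc:
        raise ParseFailure("syntax", str(exc))
    if not isinstance(value, (list, tuple)):
        raise ParseFailure("schema", "top-level value is not a list")
    records = []
    for item in value:
        if not isinstance(item, (list, tuple)) or len(item) != 3:
            raise ParseFailure("schema", f"element {item!r} is not [name, start, end]")
        name, start, end = item
        if not isinstance(name, str):
            raise ParseFailure("schema", f"name {name!r} is not textual")
        records.append(
            ExtractedRegion(sbre=name, start=_coerce_boundary(start), end=_coerce_boundary(end))
        )
    return records


def parse_response(raw: str, sentinel: str = SENTINEL) -> list[ExtractedRegion]:
    """Full parsing pipeline: strip formatting, extract payload, read literal."""
    return parse_literal(extract_payload(strip_formatting(raw), sentinel))


def format_response(records: Sequence[ExtractedRegion]) -> str:
    """Render records in the response format the prompts request."""
    inner = ", ".join(f"[{r.sbre!r}, {r.start}, {r.end}]" for r in records)
    return f"{SENTINEL} = [{inner}]"


def run_backend_with_retries(
    backend: Callable[[object, str], str],
    image,
    prompt: str,
    policy: RetryPolicy = RetryPolicy(),
    parser: Callable[[str], list[ExtractedRegion]] = parse_response,
    dataset_id: str = "",
) -> AnnotationResult:
    """Query a backend until a response parses, up to ``max_attempts`` times.

    Transport errors count as failed attempts. If every attempt fails, a
    blank result is returned with all raw responses retained for audit.
    """
    raw_responses: list[str] = []
    for attempt in range(1, policy.max_attempts + 1):
        if attempt > 1 and policy.pre_retry_pause > 0:
            time.sleep(policy.pre_retry_pause)
        try:
            raw = backend(image, prompt)
        except Exception as exc:  # noqa: BLE001 - transport failure is a failed attempt
            raw_responses.append(f"<transport error: {exc}>")
            continue
        raw_responses.append(raw)
        try:
            records = parser(raw)
        except ParseFailure:
            continue
        return AnnotationResult(
            dataset_id=dataset_id,
            records=records,
            raw_responses=raw_responses,
            n_attempts=attempt,
            blank=False,
        )
    return AnnotationResult(
        dataset_id=dataset_id,
        records=[],
        raw_responses=raw_responses,
        n_attempts=policy.max_attempts,
        blank=True,
    )


@dataclass(frozen=True)
class ErrorModel:
    """Parametric annotator error model.

    The modes mirror observed annotator behavior: dropped regions,
    per-endpoint boundary jitter, a one-row-up misread that shifts both
    boundaries by ``-row_width``, duplicated records, single-character
    name typos, and spurious regions with improvised names.
    """

    p_miss: float = 0.0
    p_spurious: float = 0.0
    p_row_shift: float = 0.0
    jitter_halfwidth: int = 0
    p_duplicate: float = 0.0
    p_name_typo: float = 0.0
    row_width: int = 60

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_spurious", "p_row_shift", "p_duplicate", "p_name_typo"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.jitter_halfwidth < 0:
            raise ValueError("jitter_halfwidth must be >= 0")

    def to_dict(self) -> dict:
        return {
            "p_miss": self.p_miss,
            "p_spurious": self.p_spurious,
            "p_row_shift": self.p_row_shift,
            "jitter_halfwidth": self.jitter_halfwidth,
            "p_duplicate": self.p_duplicate,
            "p_name_typo": self.p_name_typo,
            "row_width": self.row_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModel":
        return cls(**d)


IDENTITY_MODEL = ErrorModel()


def _corrupt_name(name: str, rng: np.random.Generator) -> str:
    if not name:
        return name
    pos = int(rng.integers(0, len(name)))
    letter = chr(ord("a") + int(rng.integers(0, 26)))
    return name[:pos] + letter + name[pos + 1:]


def simulate_annotations(
    truth: Sequence[RegionAnnotation],
    model: ErrorModel,
    rng: np.random.Generator,
    n_columns: int = 180,
) -> list[ExtractedRegion]:
    """Perturb ground truth through the error model into predicted records."""
    records: list[ExtractedRegion] = []
    j = model.jitter_halfwidth
    for region in truth:
        if rng.random() < model.p_miss:
            continue
        start = region.start + int(rng.integers(-j, j + 1)) if j else region.start
        end = region.end + int(rng.integers(-j, j + 1)) if j else region.end
        if rng.random() < model.p_row_shift:
            start -= model.row_width
            end -= model.row_width
        name = region.sbre
        if rng.random() < model.p_name_typo:
            name = _corrupt_name(name, rng)
        record = ExtractedRegion(sbre=name, start=start, end=end)
        records.append(record)
        if rng.random() < model.p_duplicate:
            records.append(record)
    if rng.random() < model.p_spurious:
        name = IMPROVISED_NAME_POOL[int(rng.integers(0, len(IMPROVISED_NAME_POOL)))]
        length = int(rng.integers(5, 16))
        start = int(rng.integers(1, max(2, n_columns - length + 1)))
        records.append(ExtractedRegion(sbre=name, start=start, end=start + length - 1))
    return records


def make_simulated_backend(
    truth_by_id: dict[str, Sequence[RegionAnnotation]],
    model: ErrorModel,
    rng: np.random.Generator,
    n_columns: int = 180,
) -> Callable[[str, str], str]:
    """Build a transport-compatible backend that answers from perturbed truth.

    The returned callable takes (dataset_id, prompt) and emits a response
    string in the prompts' requested format, so simulated runs exercise
    the same parsing pipeline as a live VLM.
    """

    def backend(dataset_id: str, prompt: str) -> str:
        records = simulate_annotations(truth_by_id[dataset_id], model, rng, n_columns)
        return format_response(records)

    return backend


def import_human_annotations(tsv_path: PathLike) -> dict[str, AnnotationResult]:
    """Read human annotations from a TSV with columns image_id, sbre, start, end."""
    required = ("image_id", "sbre", "start", "end")
    results: dict[str, AnnotationResult] = {}
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise ValueError(f"{tsv_path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            image_id = (row["image_id"] or "").strip()
            name = (row["sbre"] or "").strip()
            try:
                start = int((row["start"] or "").strip())
                end = int((row["end"] or "").strip())
            except ValueError:
                raise ValueError(
                    f"{tsv_path}:{lineno}: non-integer boundary for image {image_id!r}"
                )
            result = results.setdefault(
                image_id,
                AnnotationResult(
                    dataset_id=image_id, records=[], raw_responses=[],
                    n_attempts=1, blank=False,
                ),
            )
            result.records.append(ExtractedRegion(sbre=name, start=start, end=end))
    return results
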