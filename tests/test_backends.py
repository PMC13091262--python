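"""Backends: prompt constants, parsing pipeline, retries, error simulation."""

import numpy as np
import pytest

from msabench.backends import (
    IMPROVISED_NAME_POOL,
    PROMPT_NAIVE,
    PROMPT_STRICT,
    ErrorModel,
    ExtractedRegion,
    ParseFailure,
    RetryPolicy,
    build_prompt,
    extract_payload,
    format_response,
    import_human_annotations,
    parse_literal,
    parse_response,
    run_backend_with_retries,
    simulate_annotations,
    strip_formatting,
)
from msabench.synthetic import RegionAnnotation


class TestPrompts:
    def test_naive_prompt_shape(self):
        text = build_prompt("naive")
        assert text is PROMPT_NAIVE
        assert text.startswith("This is a figure from a biological paper.")
        assert text.endswith("parsed_result = [[region_name, region_init, region_end],...]")

    def test_strict_prompt_shape(self):
        text = build_prompt("strict")
        assert text is PROMPT_STRICT
        assert "ideally at one-residue resolution" in text
        assert "interpolating between the visible labels" in text
        assert text.endswith("parsed_result = [[region_name, region_init, region_end],...]")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="medium"):
            build_prompt("medium")


class TestStripFormatting:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("```\nparsed_result = [['A', 1, 2]]\n```", "parsed_result = [['A', 1, 2]]"),
            ("```python\nprint(x)\n```", "print(x)"),
            ("no fences here", "no fences here"),
            ("  `parsed_result = [[1]]`  ", "parsed_result = [[1]]"),
            ("", ""),
        ],
    )
    def test_cases(self, raw, expected):
        assert strip_formatting(raw) == expected


class TestExtractPayload:
    def test_plain_assignment(self):
        out = extract_payload("parsed_result = [['Mutation Hotspot A', 39, 56]]")
        assert out == "[['Mutation Hotspot A', 39, 56]]"

    def test_last_occurrence_wins(self):
        raw = (
            "The format is parsed_result = [[name, init, end],...]. Here: "
            "parsed_result = [['A', 1, 2]]"
        )
        assert extract_payload(raw) == "[['A', 1, 2]]"

    def test_missing_key(self):
        with pytest.raises(ParseFailure) as exc:
            extract_payload("result = [['A', 1, 2]]")
        assert exc.value.reason == "missing_key"

    def test_truncated_payload(self):
        with pytest.raises(ParseFailure) as exc:
            extract_payload("here it is: parsed_result =")
        assert exc.value.reason == "syntax"

    def test_code_without_literal_assignment(self):
        code = (
            "regions = detect(img)\n"
            "print('parsed_result =', [[r.name, r.a, r.b] for r in regions])\n"
        )
        with pytest.raises(ParseFailure) as exc:
            extract_payload(code)
        assert exc.value.reason in {"missing_key", "syntax"}


class TestParseLiteral:
    def test_two_records(self):
        records = parse_literal(
            "[['Mutation Hotspot A', 39, 56], ['Low Conservation A', 63, 75]]"
        )
        assert records == [
            ExtractedRegion("Mutation Hotspot A", 39, 56),
            ExtractedRegion("Low Conservation A", 63, 75),
        ]

    def test_arity_violation(self):
        with pytest.raises(ParseFailure) as exc:
            parse_literal("[['A', 1]]")
        assert exc.value.reason == "schema"

    def test_numeric_string_coercion(self):
        assert parse_literal("[['A', '10', '20']]") == [ExtractedRegion("A", 10, 20)]

    def test_non_literal_is_syntax_failure(self):
        with pytest.raises(ParseFailure) as exc:
            parse_literal("[f(1)]")
        assert exc.value.reason == "syntax"

    def test_never_executes_content(self, tmp_path):
        # a payload that would create a file if evaluated as code
        marker = tmp_path / "pwned"
        payload = (
            f"parsed_result = [open({str(marker)!r}, 'w').write('x')]"
        )
        with pytest.raises(ParseFailure):
            parse_response(payload)
        assert not marker.exists()


class TestRetries:
    def fast_policy(self):
        return RetryPolicy(max_attempts=3, inter_image_pause=0.0, pre_retry_pause=0.0)

    def test_immediate_success(self):
        backend = lambda image, prompt: "parsed_result = [['A', 1, 2]]"
        result = run_backend_with_retries(backend, None, "p", self.fast_policy())
        assert not result.blank
        assert result.n_attempts == 1
        assert result.records == [ExtractedRegion("A", 1, 2)]

    def test_three_failures_blank_with_archived_responses(self):
        calls = []

        def backend(image, prompt):
            calls.append(1)
            return "def solve():\n    return regions\n"

        result = run_backend_with_retries(backend, None, "p", self.fast_policy())
        assert result.blank
        assert result.n_attempts == 3
        assert len(result.raw_responses) == 3
        assert len(calls) == 3

    def test_success_on_third_attempt(self):
        responses = iter(["junk", "more junk", "parsed_result = [['A', 1, 2]]"])
        result = run_backend_with_retries(
            lambda i, p: next(responses), None, "p", self.fast_policy()
        )
        assert not result.blank
        assert result.n_attempts == 3
        assert len(result.raw_responses) == 3

    def test_transport_error_counts_as_attempt(self):
        calls = []

        def backend(image, prompt):
            calls.append(1)
            raise ConnectionError("boom")

        result = run_backend_with_retries(backend, None, "p", self.fast_policy())
        assert result.blank
        assert len(calls) == 3
        assert all("transport error" in r for r in result.raw_responses)


class TestSimulatedAnnotator:
    def test_identity_model(self, example_truth):
        out = simulate_annotations(example_truth, ErrorModel(), np.random.default_rng(0))
        assert [(r.sbre, r.start, r.end) for r in out] == [
            (r.sbre, r.start, r.end) for r in example_truth
        ]

    def test_row_shift_moves_both_boundaries(self, example_truth):
        model = ErrorModel(p_row_shift=1.0, row_width=60)
        out = simulate_annotations(example_truth, model, np.random.default_rng(0))
        assert [(r.start, r.end) for r in out] == [(-21, -4), (3, 15), (56, 68)]

    def test_spurious_region_has_improvised_name(self, example_truth):
        model = ErrorModel(p_spurious=1.0)
        out = simulate_annotations(example_truth, model, np.random.default_rng(0))
        truth_names = {r.sbre for r in example_truth}
        extra = [r for r in out if r.sbre not in truth_names]
        assert len(extra) == 1
        assert extra[0].sbre in IMPROVISED_NAME_POOL

    def test_duplicate_re_emits_record(self, example_truth):
        model = ErrorModel(p_duplicate=1.0)
        out = simulate_annotations(example_truth, model, np.random.default_rng(0))
        assert len(out) == 2 * len(example_truth)
        assert out[0] == out[1]

    def test_miss_drops_everything_at_p1(self, example_truth):
        out = simulate_annotations(example_truth, ErrorModel(p_miss=1.0), np.random.default_rng(0))
        assert out == []

    def test_format_response_round_trip(self, example_truth):
        records = simulate_annotations(example_truth, ErrorModel(), np.random.default_rng(0))
        assert parse_response(format_response(records)) == records


class TestHumanImport:
    def test_import_worked_example(self, tmp_path, example_truth):
        tsv = tmp_path / "human.tsv"
        rows = ["image_id\tsbre\tstart\tend"] + [
            f"img_000\t{r.sbre}\t{r.start}\t{r.end}" for r in example_truth
        ]
        tsv.write_text("\n".join(rows) + "\n")
        results = import_human_annotations(tsv)
        assert set(results) == {"img_000"}
        result = results["img_000"]
        assert not result.blank and result.n_attempts == 1
        assert [(r.sbre, r.start, r.end) for r in result.records] == [
            (r.sbre, r.start, r.end) for r in example_truth
        ]

    def test_header_only_gives_empty_map(self, tmp_path):
        tsv = tmp_path / "empty.tsv"
        tsv.write_text("image_id\tsbre\tstart\tend\n")
        assert import_human_annotations(tsv) == {}

    def test_non_integer_boundary_reports_line(self, tmp_path):
        tsv = tmp_path / "bad.tsv"
        tsv.write_text("image_id\tsbre\tstart\tend\nimg_001\tBinding Site A\t12\tx\n")
        with pytest.raises(ValueError, match=":2"):
            import_human_annotations(tsv)

    def test_missing_column_named(self, tmp_path):
        tsv = tmp_path / "cols.tsv"
        tsv.write_text("image_id\tname\tstart\tend\nimg_001\tA\t1\t2\n")
        with pytest.raises(ValueError, match="sbre"):
            import_human_annotations(tsv)

    def test_names_whitespace_trimmed(self, tmp_path):
        tsv = tmp_path / "trim.tsv"
        tsv.write_text("image_id\tsbre\tstart\tend\nimg_001\t Binding Site A \t1\t2\n")
        result = import_human_annotations(tsv)["img_001"]
        assert result.records[0].sbre == "Binding Site A"
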