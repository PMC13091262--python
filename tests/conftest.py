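import pytest

from msabench.backends import AnnotationResult, ExtractedRegion
from msabench.synthetic import GeneratorConfig, RegionAnnotation


@pytest.fixture
def default_config():
    return GeneratorConfig()


@pytest.fixture
def example_truth():
    """A worked ground-truth layout: three named regions on 180 columns."""
    return [
        RegionAnnotation(sbre="Mutation Hotspot A", start=39, end=56),
        RegionAnnotation(sbre="Low Conservation A", start=63, end=75),
        RegionAnnotation(sbre="Low Conservation B", start=116, end=128),
    ]


@pytest.fixture
def example_prediction():
    """A matching annotator output with a near hit, a row swap, boundary
    slips, sentence-case names, and one improvised spurious region."""
    return AnnotationResult(
        dataset_id="img_000",
        records=[
            ExtractedRegion(sbre="Mutation hotspot A", start=37, end=59),
            ExtractedRegion(sbre="Low conservation A", start=10, end=28),
            ExtractedRegion(sbre="Low conservation B", start=126, end=137),
            ExtractedRegion(sbre="Unlabeled region", start=111, end=119),
        ],
        raw_responses=[],
        n_attempts=1,
        blank=False,
    )
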