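import numpy as np
import pytest

from histotriage.classifier import TileClassification
from histotriage.hierarchy import CLASSES, DiagnosticClass
from histotriage.synthetic import CohortSpec, generate_cohort, write_cohort
from histotriage.tiling import Tile


def make_classification(
    label: DiagnosticClass, score: float, slide_id="s", row0=0, col0=0
) -> TileClassification:
    """A tile classification with the given argmax label and score.

    The score must exceed 1/n_classes so the label really is the argmax.
    """
    assert score > 1.0 / len(CLASSES) + 1e-9
    p = np.full(len(CLASSES), (1.0 - score) / (len(CLASSES) - 1))
    p[CLASSES.index(label)] = score
    return TileClassification.from_probabilities(slide_id, row0, col0, p)


def make_tile(pixels: np.ndarray, slide_id="s", row0=0, col0=0) -> Tile:
    return Tile(
        slide_id=slide_id,
        row0=row0,
        col0=col0,
        size=pixels.shape[0],
        pixels=pixels,
        tissue_fraction=1.0,
    )


#: Case-level diagnosis mix used for small cohort fixtures: covers every
#: reported aggregate (neoplasia, inflammation, HP/SSL, normal mucosa).
COHORT_MIX = {
    DiagnosticClass.normal_large_bowel: 0.30,
    DiagnosticClass.adenoma: 0.20,
    DiagnosticClass.inflammation: 0.15,
    DiagnosticClass.hp_ssl: 0.15,
    DiagnosticClass.adenocarcinoma: 0.10,
    DiagnosticClass.normal_small_bowel: 0.10,
}


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 6-case synthetic cohort written to disk (slides at 1024px)."""
    spec = CohortSpec(
        n_cases=6,
        class_mix=COHORT_MIX,
        specimens_per_case=(1, 2),
        slides_per_specimen=(1, 2),
        image_size=(1024, 1024),
        n_sections=2,
        seed=11,
    )
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(generate_cohort(spec), out)
    return out
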