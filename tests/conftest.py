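import numpy as np
import pytest

from spheroscreen import analyze_stack
from spheroscreen.segmentation import SegmentationConfig, Structure
from spheroscreen.synthetic import PhenotypeSpec, make_field


def rasterize_disk(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def as_structure(mask: np.ndarray, label: int = 1) -> Structure:
    return Structure(label=label, bbox=(slice(0, mask.shape[0]), slice(0, mask.shape[1])), mask=mask.astype(bool))


@pytest.fixture
def config() -> SegmentationConfig:
    return SegmentationConfig()


@pytest.fixture(scope="session")
def default_field():
    """One default synthetic field plus its full pipeline analysis."""
    stack, truth = make_field(PhenotypeSpec(seed=0))
    result = analyze_stack(stack, image_id="field0")
    return stack, truth, result


@pytest.fixture(scope="session")
def matched_records(default_field):
    """Per-structure (truth, measured row) pairs matched by centroid."""
    import scipy.ndimage as ndi

    _, truth, result = default_field
    cents = ndi.center_of_mass(
        result.labels > 0, result.labels, range(1, int(result.labels.max()) + 1)
    )
    pairs = []
    for sid, c in enumerate(cents, start=1):
        d = [np.hypot(c[0] - s.center[0], c[1] - s.center[1]) for s in truth.structures]
        pairs.append(
            (truth.structures[int(np.argmin(d))], result.records[result.records.structure_id == sid].iloc[0])
        )
    return pairs
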