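import numpy as np
import pytest

from bollcount import pipeline
from bollcount.synthetic_fixtures import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def training_scene():
    """One annotated synthetic plot, the training substrate for the SVM."""
    return generate_scene(SceneConfig(height=224, width=224, n_bolls=45, seed=11))


@pytest.fixture(scope="session")
def training_report(training_scene):
    """Classifier trained once per session on the fixture scene."""
    return pipeline.train_pixel_classifier(training_scene.image, training_scene.mask)


@pytest.fixture(scope="session")
def classifier(training_report):
    return training_report.classifier


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def flood_fill_count(mask):
    """Brute-force 8-connected component oracle: BFS flood fill.

    Independent of scipy.ndimage; used to cross-check count_components.
    """
    mask = np.asarray(mask) != 0
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < H
                                and 0 <= nx < W
                                and mask[ny, nx]
                                and not seen[ny, nx]
                            ):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
    return count
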