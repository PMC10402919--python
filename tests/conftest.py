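import numpy as np
import pytest

from spheroidq import (
    SpheroidScene,
    annotations_from_truth,
    project,
    render_scene,
    train_classifier,
)

NOMINAL_INTENSITY = 200.0  # generator default fluorescence level


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


def truth_label_map(truth) -> np.ndarray:
    labels = np.zeros(truth.core_mask.shape, dtype=np.uint8)
    labels[truth.core_mask] = 1
    labels[truth.outgrowth_mask] = 2
    return labels


def match_centers(detected, planted, tol=2.0):
    """Greedy 1:1 nearest-neighbor matching within ``tol`` pixels."""
    used, matched = set(), 0
    for r, c in detected:
        best, best_d = None, tol
        for j, (pr, pc) in enumerate(planted):
            if j in used:
                continue
            d = np.hypot(r - pr, c - pc)
            if d <= best_d:
                best_d, best = d, j
        if best is not None:
            used.add(best)
            matched += 1
    return matched


@pytest.fixture(scope="session")
def noiseless_pair():
    return render_scene(SpheroidScene(seed=5, noise_sigma=0.0))


@pytest.fixture(scope="session")
def default_pair():
    return render_scene(SpheroidScene(seed=3))


@pytest.fixture(scope="session")
def training_pool():
    """Representative pictures spanning the noise range the model must handle."""
    pairs = [
        render_scene(SpheroidScene(seed=s, noise_sigma=ns))
        for s, ns in [(100, 8.0), (101, 24.0), (102, 40.0)]
    ]
    images = [project(stack) for stack, _ in pairs]
    truths = [truth for _, truth in pairs]
    return images, truths


@pytest.fixture(scope="session")
def trained_model(training_pool):
    images, truths = training_pool
    annotations = annotations_from_truth(truths, fraction=0.02, seed=0)
    return train_classifier(images, annotations, seed=0)
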