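import numpy as np
import pytest

from rnaspots.synthetic import FieldSpec, generate_field


@pytest.fixture(scope="session")
def default_field():
    """One default 512x512 field (20 nuclei, lambda 5/channel) + truth."""
    return generate_field(FieldSpec(n_nuclei=20, seed=7))


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free field with well-separated nuclei and no far dots."""
    spec = FieldSpec(
        n_nuclei=12,
        background_sigma=0.0,
        far_dot_fraction=0.0,
        seed=11,
    )
    return generate_field(spec)


def match_truth_labels(truth_labels: np.ndarray, pred_labels: np.ndarray) -> dict[int, int]:
    """Map each ground-truth nucleus to the predicted label covering it most."""
    out = {}
    for t in range(1, int(truth_labels.max()) + 1):
        overlap = pred_labels[truth_labels == t]
        overlap = overlap[overlap > 0]
        out[t] = int(np.bincount(overlap).argmax()) if len(overlap) else 0
    return out
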