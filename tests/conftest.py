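"""Shared fixtures: expensive trained models are session-scoped so the
recovery tests and the CAM tests reuse one training run."""

import numpy as np
import pytest

from angioscreen import classify as C
from angioscreen import profiles as P


@pytest.fixture(scope="session")
def easy_trained_classifier():
    """2-CAT severity classifier trained to convergence on the easy profile
    (no lesion vs 70% narrowing); held-out AUC ~0.95+."""
    images, labels, _ = P.easy_classification_dataset(120, seed=0)
    cfg = P.easy_classifier_config(seed=0, epochs=40)
    return C.train_view_classifier(images, labels, cfg)


@pytest.fixture(scope="session")
def easy_detection_testset():
    """Held-out single-lesion frames with truth boxes (severity 60-100)."""
    return P.easy_detection_dataset(20, seed=500)
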