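"""Shared fixtures: synthetic phantom datasets and a trained classifier.

The heavyweight fixtures are session-scoped so the separability training
run happens once per session and is shared by the attribution tests and the
end-to-end acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from suturevision.age_cnn import NetworkSpec, TrainConfig, build_network, train
from suturevision.phantom import CohortMember, PhantomParams, fused_image_of

THREE_CLASS_OMEGAS = (0.1, 0.5, 0.9)


def make_three_class_set(n_per_class: int, seed: int):
    """Fused phantom images for three widely spaced ossification levels."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for ci, om in enumerate(THREE_CLASS_OMEGAS):
        for i in range(n_per_class):
            member = CohortMember(
                subject_id=f"c{ci}_{i:03d}",
                participant_id=f"c{ci}_{i:03d}",
                age_months=120,
                sex="F",
                omega=om,
                params=PhantomParams.from_ossification(
                    om, seed=int(rng.integers(0, 2**31 - 1))
                ),
            )
            images.append(fused_image_of(member))
            labels.append(ci)
    return np.stack(images), np.asarray(labels)


@pytest.fixture(scope="session")
def three_class_data():
    """300 fused images (100 per class), split 70/30 train/held-out."""
    images, labels = make_three_class_set(n_per_class=100, seed=2024)
    rng = np.random.default_rng(0)
    train_idx, test_idx = [], []
    for c in range(3):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        train_idx.extend(idx[:70])
        test_idx.extend(idx[70:])
    return {
        "x_train": images[train_idx],
        "y_train": labels[train_idx],
        "x_test": images[test_idx],
        "y_test": labels[test_idx],
    }


@pytest.fixture(scope="session")
def three_class_model(three_class_data):
    """Small residual net trained on the three-class phantom set."""
    model = build_network(NetworkSpec.small(n_classes=3), seed=0)
    config = TrainConfig(
        learning_rate=0.02, max_steps=600, batch_size=50, checkpoint_every=200, seed=0
    )
    history = train(
        model,
        (three_class_data["x_train"], three_class_data["y_train"]),
        None,
        config,
        test_set=(three_class_data["x_test"], three_class_data["y_test"]),
    )
    return {"model": model, "history": history}
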