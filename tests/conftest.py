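import numpy as np
import pytest

import snpmri as sm


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted-effect cohort used across unit tests."""
    spec = sm.SyntheticSpec(
        n_subjects=240, n_snps=10, n_rois=6, mafs=0.3,
        causal_pairs=[(0, 0, 2.0)],
        class_shifts={"AD": np.array([-1.5, -1.5, 0, 0, 0, 0.0]),
                      "MCI": np.array([-0.75, -0.75, 0, 0, 0, 0.0])},
        liability_snps=[(0, 1.5), (1, 1.5)],
        seed=11,
    )
    cohort, manifest = sm.simulate_cohort(spec)
    return cohort, manifest, spec


@pytest.fixture(scope="session")
def trained_stack(small_cohort):
    """Alignment model + combined-modality ensemble trained on the small cohort."""
    cohort, _, _ = small_cohort
    split = sm.split_cohort(cohort, seed=11)
    model = sm.train_alignment(
        cohort, split, sm.TrainConfig(epochs=25, d=16, batch_size=32, seed=11))
    tr, va = split.indices("train"), split.indices("validation")
    F = sm.embed_features(model, cohort, "combined")
    ens = sm.fit_ensemble(F[tr], cohort.labels[tr], seed=11,
                          X_val=F[va], y_val=cohort.labels[va],
                          modality="combined")
    return cohort, split, model, ens
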