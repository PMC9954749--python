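import numpy as np
import pytest

from fabnet.synthetic import SyntheticClassSpec, SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def breakhis_style_cohort(tmp_path_factory):
    """A small taxonomy-named synthetic cohort tree plus its records.

    Two subclasses (benign PHT sparse nuclei, malignant DUC dense nuclei),
    three patients each, two images per patient at two magnifications.
    """
    root = tmp_path_factory.mktemp("cohort")
    config = SyntheticCohortConfig(
        classes=(
            SyntheticClassSpec(name="PHT", nucleus_density=5.0, category="benign"),
            SyntheticClassSpec(name="DUC", nucleus_density=50.0, category="malignant"),
        ),
        patients_per_class=3,
        images_per_patient=2,
        magnifications=("40X", "100X"),
        image_size=64,
        seed=11,
    )
    records = generate_cohort(config, root, style="breakhis")
    return root, config, records


def make_random_prediction_records(rng, n_patients=6, n_classes=2, images_per_patient=(1, 5),
                                   patches_per_image=(1, 4)):
    """Random patch-level prediction sets with full lineage, for oracles."""
    from fabnet.evaluation import PredictionRecord

    records = []
    for p in range(n_patients):
        n_img = int(rng.integers(*images_per_patient, endpoint=True))
        for i in range(n_img):
            true = int(rng.integers(0, n_classes))
            n_patch = int(rng.integers(*patches_per_image, endpoint=True))
            for k in range(n_patch):
                probs = rng.random(n_classes) + 1e-3
                probs = probs / probs.sum()
                records.append(
                    PredictionRecord(
                        record_id=f"pt{p}_im{i}_p{k}",
                        image_id=f"pt{p}_im{i}",
                        patient_id=f"pt{p}",
                        true_label=true,
                        probabilities=tuple(probs),
                    )
                )
    return records
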