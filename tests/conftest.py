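import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_cohort():
    """Small clean synthetic cohort with ground-truth peaks, varied rates."""
    from ecgfusion.data_io import SyntheticSpec, generate_synthetic_record

    out = []
    for i, bpm in enumerate((52, 60, 75, 90, 105, 118)):
        rec, peaks = generate_synthetic_record(
            SyntheticSpec(bpm_mean=bpm, noise_sd=0.0, rng_seed=i),
            record_id=f"clean{i}",
        )
        out.append((rec, peaks))
    return out


@pytest.fixture(scope="session")
def toy_features():
    """Feature-extracted 2-class toy cohort for model/training tests.

    Small (60 records) so unit tests stay fast; the acceptance suite builds
    its own 200-record cohort.
    """
    from ecgfusion.data_io import synthetic_dataset
    from ecgfusion.pipeline import prepare_dataset

    data = synthetic_dataset(60, n_classes=2, seed=7, noise_sd=0.02)
    labeled = [(rec, rec.binary_label) for rec, _ in data]
    feats, dropped = prepare_dataset(labeled, ("raw", "qrs", "qrs_entropy"))
    assert dropped == 0
    return feats
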