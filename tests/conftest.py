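import warnings

import numpy as np
import pytest

from ontopool.network import TrialNetwork, TrialRecord

warnings.filterwarnings("ignore", message=".*ArviZ.*")


def make_network(spec, enrollments=None, base_enrollment=800):
    """Build a small network from {drug_code: (class_code, n_trials)}."""
    records, k = [], 0
    for drug_code, (class_code, n_trials) in spec.items():
        for _ in range(n_trials):
            n = enrollments[k] if enrollments is not None else base_enrollment
            records.append(
                TrialRecord(
                    trial_id=f"T{k:03d}",
                    drug_code=drug_code,
                    class_code=class_code,
                    enrollment=int(n),
                )
            )
            k += 1
    return TrialNetwork(records)


@pytest.fixture
def tiny_network():
    """Two classes, three drugs, six trials."""
    return make_network(
        {
            "A10BH01": ("A10BH", 3),
            "A10BH02": ("A10BH", 2),
            "A10BX03": ("A10BX", 1),
        }
    )


@pytest.fixture
def medium_network():
    """Three classes, eight drugs, 21 trials of varied size."""
    rng = np.random.default_rng(7)
    spec = {
        "A10BH01": ("A10BH", 5),
        "A10BH02": ("A10BH", 3),
        "A10BH03": ("A10BH", 2),
        "A10BJ01": ("A10BJ", 4),
        "A10BJ02": ("A10BJ", 3),
        "A10BX01": ("A10BX", 2),
        "A10BX02": ("A10BX", 1),
        "A10BX90": ("A10BX", 1),
    }
    enrollments = rng.integers(300, 4000, size=21)
    return make_network(spec, enrollments=enrollments)


def random_network(rng, max_trials=10):
    """A random small network for property tests."""
    n_classes = int(rng.integers(1, 4))
    records, k = [], 0
    for c in range(n_classes):
        class_code = f"A10B{chr(65 + c)}"
        for d in range(int(rng.integers(1, 4))):
            drug_code = f"{class_code}{d + 1:02d}"
            for _ in range(int(rng.integers(1, 4))):
                if k >= max_trials:
                    break
                records.append(
                    TrialRecord(
                        trial_id=f"T{k}",
                        drug_code=drug_code,
                        class_code=class_code,
                        enrollment=int(rng.integers(300, 5000)),
                    )
                )
                k += 1
    if not records:
        records.append(TrialRecord("T0", "A10BA01", "A10BA", 1000))
    return TrialNetwork(records)
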