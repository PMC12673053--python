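import numpy as np
import pandas as pd
import pytest

from coughvision.synthesis import default_cohort_profiles, generate_cohort


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """9 categories x 3 subjects, 2-minute recordings: fast integration data."""
    root = tmp_path_factory.mktemp("cohort_small")
    profiles = default_cohort_profiles(
        subjects_per_category=3, recording_duration=120.0, seed=11
    )
    generate_cohort(profiles, seed=11, out_dir=root)
    return root


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cohort_table(rng, n_categories=None, min_subjects=3, max_subjects=12):
    """A random subject table (subject_id, category, sex, cough_rate)."""
    if n_categories is None:
        n_categories = int(rng.integers(3, 6))
    rows = []
    for c in range(n_categories):
        n = int(rng.integers(min_subjects, max_subjects + 1))
        base_rate = float(rng.uniform(10, 450))
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"C{c}S{i:02d}",
                    "category": f"cat{c}",
                    "sex": "M" if rng.random() < rng.uniform(0.2, 0.8) else "F",
                    "cough_rate": base_rate * float(np.exp(rng.normal(0, 0.4))),
                }
            )
    return pd.DataFrame(rows)
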