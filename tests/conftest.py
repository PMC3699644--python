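import pytest

from cecmarkers import reference
from cecmarkers.expression import matrix_from_arrays, metadata_from_records


@pytest.fixture(scope="session")
def core_meta():
    """One sample per corneal class, sample ids equal to class labels."""
    return reference.reference_metadata()


@pytest.fixture()
def small_counts():
    """3-gene x 4-sample count matrix with easy round depths."""
    matrix = matrix_from_arrays(
        ["G1", "G2", "G3"],
        ["cec_young", "cec_old", "cec_culture", "stroma"],
        [[250, 100, 0, 40],
         [250, 300, 500, 10],
         [2000, 600, 500, 950]],
        unit="counts")
    meta = metadata_from_records([
        ("cec_young", "cec_young", 2_500_000),
        ("cec_old", "cec_old", 1_000_000),
        ("cec_culture", "cec_culture", 1_000_000),
        ("stroma", "stroma", 1_000_000),
    ])
    return matrix, meta
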