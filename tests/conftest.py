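import numpy as np
import pandas as pd
import pytest

from ctewas.synthetic import (
    generate_bulk_cohort,
    generate_sorted_cohort,
    make_default_design,
    null_design,
)

DESIGN_SEED = 11


@pytest.fixture(scope="session")
def design():
    """Default study design at desk scale."""
    return make_default_design(3000, DESIGN_SEED)


@pytest.fixture(scope="session")
def sorted_cohort(design):
    """(beta, sheet, annotation) for 40 donors per fraction."""
    return generate_sorted_cohort(design, 40)


@pytest.fixture(scope="session")
def bulk_cohort(design):
    return generate_bulk_cohort(design, 50)


@pytest.fixture(scope="session")
def null_cohort():
    d = null_design(1500, 5)
    beta, sheet, ann = generate_sorted_cohort(d, 50)
    return d, beta, sheet, ann


def small_sheet(n=6):
    """Hand-built valid sample sheet for IO and unit tests."""
    half = n // 2
    return pd.DataFrame(
        {
            "cohort": "c1",
            "cell_fraction": ["neuron"] * half + ["glia"] * (n - half),
            "age": np.linspace(40, 90, n),
            "sex": ["female", "male"] * (n // 2) + ["female"] * (n % 2),
            "braak": (list(range(7)) * (n // 7 + 1))[:n],
            "diagnosis": ["control"] * n,
            "batch": "b1",
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
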