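import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from perigut import CohortConfig, CountTable, generate_cohort
from perigut.io_formats import read_newick


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject cohort with the default injected effects."""
    return generate_cohort(CohortConfig(n_subjects=20, n_taxa=15, depth=500, seed=7))


@pytest.fixture()
def star_tree3():
    """Three-leaf star with unit branches."""
    return read_newick("(A:1,B:1,C:1):0;")


@pytest.fixture()
def cherry_tree():
    return read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture()
def tiny_table():
    return CountTable(["s1", "s2"], ["tA", "tB"], np.array([[5, 0], [3, 7]]))


def make_metadata(rows):
    """Helper: metadata frame from (sample, subject, tp, ileo, sdd, source) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "timepoint", "ileostomy", "sdd", "source"]
    )
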