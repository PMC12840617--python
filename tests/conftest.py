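import pandas as pd
import pytest

from peptiforge import MotifDatabase, get_rule


@pytest.fixture(scope="session")
def pepsin():
    return get_rule("pepsin")


@pytest.fixture(scope="session")
def trypsin():
    return get_rule("trypsin")


@pytest.fixture(scope="session")
def chymotrypsin():
    return get_rule("chymotrypsin")


@pytest.fixture(scope="session")
def bromelain():
    return get_rule("bromelain")


@pytest.fixture(scope="session")
def screened_peptides_table():
    """The nine screened peptidomics hits with their printed peak areas and
    external bioactivity scores."""
    return pd.DataFrame(
        {
            "sequence": ["FPL", "YPW", "FPH", "FPHF", "FPHFD", "FPHFDL", "FPFA", "HPYF", "YPWTQRFF"],
            "abundance": [2.27e7, 3.12e7, 1.02e9, 2.56e9, 8.32e8, 4.33e9, 1.28e7, 7.75e8, 2.26e8],
            "score": [0.9790, 0.9751, 0.9401, 0.9872, 0.9274, 0.9448, 0.9843, 0.9396, 0.9556],
        }
    )


@pytest.fixture(scope="session")
def motif_fixture_db():
    """A small in-repo motif database for digestion/frequency tests only."""
    return MotifDatabase(
        frozenset({"IP", "FP", "VPL", "FPL", "LA", "GP", "IPI", "PW"}),
        activity_label="DPP-IV inhibitor",
    )
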