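import pytest

from tgskit.panel import default_panel
from tgskit.simulate import default_simulation_config, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort():
    """A deterministic 42-subject synthetic cohort under the shipped calibration."""
    return simulate_cohort(default_simulation_config(seed=20260930))


SUBJECT_HEADER = "id,rs2010963,rs1042713,rs1042714,rs1205,rs8192678,pre_yoyo_m,post_yoyo_m"


@pytest.fixture()
def subject_csv(tmp_path):
    """Write a small subject table and return its path."""

    def _write(rows, header=SUBJECT_HEADER):
        path = tmp_path / "subjects.csv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write
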