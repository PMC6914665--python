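import pandas as pd
import pytest

from aggexpo import study_io


@pytest.fixture(scope="session")
def fixtures():
    """Packaged study tables (participants, profiles, parameters, matrices)."""
    return study_io.load_study_fixtures()


@pytest.fixture
def void_csv(tmp_path):
    """Factory: write a wide void CSV and return its path."""

    def _write(rows, columns=("participant_id", "time_h", "volume_L", "MP")):
        path = tmp_path / "voids.csv"
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return path

    return _write


def make_void_table(rows):
    """Build a VoidTable from (pid, time_h, volume_L, analyte, conc, detected) rows."""
    df = pd.DataFrame(rows, columns=list(study_io.VoidTable.COLUMNS))
    return study_io.VoidTable(df)
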