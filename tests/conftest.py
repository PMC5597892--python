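import numpy as np
import pandas as pd
import pytest

from postprandial.io import TIMEPOINTS, TISSUES, SampleSheet


@pytest.fixture
def sheet() -> SampleSheet:
    rows = [
        {"sample_id": f"{t[0].upper()}{i}", "tissue": t, "timepoint": tp}
        for t in TISSUES
        for i, tp in enumerate(TIMEPOINTS)
    ]
    # heart/liver vs intestine share initials with nothing here; stomach=S, pancreas=P
    frame = pd.DataFrame(rows)
    frame["sample_id"] = [
        f"{letter}{i}"
        for letter, i in zip(
            [{"heart": "H", "liver": "L", "stomach": "S", "pancreas": "P", "intestine": "I"}[t] for t in frame.tissue],
            [int(s[-1]) for s in frame.sample_id],
        )
    ]
    return SampleSheet(frame)


@pytest.fixture
def stomach_cols(sheet):
    return [sheet.samples_for("stomach")[tp] for tp in TIMEPOINTS]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_expr(rows: dict[str, tuple], columns) -> pd.DataFrame:
    """Expression matrix helper: gene -> values across the given columns."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(columns)).rename_axis(
        "gene_id"
    )
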