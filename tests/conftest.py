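import numpy as np
import pandas as pd
import pytest

from pyebench.composition import pye_design
from pyebench.quant_io import QuantTable, RunMetadata


@pytest.fixture(scope="session")
def series():
    return pye_design()


@pytest.fixture()
def meta_dia():
    return {
        "S1": RunMetadata(
            setup_id="S1",
            acquisition_mode="DIA",
            gradient_length=60.0,
            cycle_time_s=1.0,
            peak_fwhm_min=0.1,
        )
    }


def make_table(rows, metadata=None):
    """Build a QuantTable from (sample, rep, protein, intensity, ...) dicts."""
    df = pd.DataFrame(rows)
    if "setup_id" not in df.columns:
        df["setup_id"] = "S1"
    metadata = metadata or {
        "S1": RunMetadata(setup_id="S1", acquisition_mode="DIA", gradient_length=60.0)
    }
    return QuantTable(df, metadata)


@pytest.fixture()
def toy_table():
    """Two proteins x (PYE1A, PYE1B) x 3 replicates, fully detected."""
    rows = []
    for prot, sp, base in (("P1_HUMAN", "human", 1000.0), ("P2_YEAST", "yeast", 90.0)):
        for sample, scale in (("PYE1A", 1.0), ("PYE1B", 3.0 if sp == "yeast" else 1.0)):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": sample,
                        "replicate": rep,
                        "protein_group": prot,
                        "species": sp,
                        "intensity": base * scale,
                        "n_peptides": 3,
                        "rt": 10.0,
                    }
                )
    return make_table(rows)
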