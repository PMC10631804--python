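import numpy as np
import pandas as pd
import pytest

from secretome.simulate import evidence_raw_file_hours, make_donor_metadata


@pytest.fixture(scope="session")
def donor_metadata() -> pd.DataFrame:
    """30-donor cohort template: 16 ASC / 14 BMSC, ages 1.5-24 years."""
    return make_donor_metadata(seed=1)


def canonical_evidence(evidence: pd.DataFrame, config=None) -> pd.DataFrame:
    """Rename a simulated MaxQuant-dialect evidence frame to canonical columns.

    Shortcut for tests that exercise kinetics directly without writing the
    table to disk (the disk round-trip has its own tests).
    """
    out = evidence.rename(
        columns={
            "Sequence": "peptide_sequence",
            "Leading razor protein": "protein_id",
            "Intensity L": "intensity_light",
            "Intensity H": "intensity_heavy",
        }
    ).copy()
    out["time_point"] = out["Raw file"].map(evidence_raw_file_hours(config))
    out["is_reverse"] = out["Reverse"].astype(str).eq("+")
    out["is_contaminant"] = out["Potential contaminant"].astype(str).eq("+")
    return out


def expected_labels(truth: pd.DataFrame, cutoff: float = 0.01) -> np.ndarray:
    return np.where(truth["true_k"] > cutoff, "secreted", "intracellular")
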