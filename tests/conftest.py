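import numpy as np
import pandas as pd
import pytest

from isletmir.io_ct import CtMatrix


def make_ct_matrix(values, donors=None, control="RNU48"):
    """Small CtMatrix builder: `values` is a dict assay -> list of Cts laid
    out as all alpha samples then all beta samples, one per donor."""
    frame = pd.DataFrame(values).T
    n = frame.shape[1] // 2
    donors = donors or [f"D{i+1}" for i in range(n)]
    sample_ids = [f"{d}_alpha" for d in donors] + [f"{d}_beta" for d in donors]
    frame.columns = sample_ids
    samples = pd.DataFrame(
        {
            "donor_id": donors + donors,
            "cell_type": ["alpha"] * n + ["beta"] * n,
            "card": ["merged"] * 2 * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    controls = frozenset({control}) if control in frame.index else frozenset()
    return CtMatrix(values=frame.astype(float), samples=samples, control_assays=controls)


@pytest.fixture
def simple_ct_files(tmp_path):
    """A 3-assay x 4-sample simple_tsv fixture with one Undetermined cell."""
    ct = tmp_path / "ct.tsv"
    ct.write_text(
        "assay_id\tS1\tS2\tS3\tS4\n"
        "miR-1\t25.0\t26.0\t24.5\t25.5\n"
        "miR-2\t30.0\tUndetermined\t29.0\t31.0\n"
        "RNU48\t22.0\t22.5\t21.5\t22.0\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "sample_id\tdonor_id\tcell_type\tcard\n"
        "S1\tD1\talpha\tA\n"
        "S2\tD1\tbeta\tA\n"
        "S3\tD2\talpha\tA\n"
        "S4\tD2\tbeta\tA\n"
    )
    return ct, meta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
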