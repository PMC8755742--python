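import numpy as np
import pandas as pd
import pytest

import afproteome as afp


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down cohort: same design, fewer analytes, for fast unit tests."""
    return afp.SimConfig(
        n_analytes=300,
        n_controls=8,
        module_sizes=(40, 30, 30),
        n_tissues=4,
        signature_size=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return afp.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    """Normalized log2 assay matrix for the small cohort (exact steps only)."""
    matrix, metadata, annotation, truth = small_sim
    norm, factors = afp.normalize_chain(
        matrix,
        annotation,
        control_reference=truth.reference,
        calibrator_reference=truth.reference,
        plate_ids=metadata.table["plate_id"],
        calibrators=truth.calibrators,
        steps=("hyb", "plate"),
        log2=True,
    )
    return norm.subset(analytes=annotation.assay_ids), factors


@pytest.fixture
def toy_matrix():
    """3 samples x 2 analytes raw matrix."""
    df = pd.DataFrame(
        {"A1": [2.0, 4.0, 8.0], "A2": [1.0, 16.0, 1024.0]},
        index=["S1", "S2", "S3"],
    )
    return afp.AbundanceMatrix(df, scale="raw")


@pytest.fixture
def toy_annotation():
    return afp.AnalyteAnnotation(
        pd.DataFrame(
            {
                "gene_symbols": ["CGA LHB", "LTF", "FTH1 FTL", "CTRL"],
                "protein_name": ["LH", "Lactotransferrin", "Ferritin", "spike"],
                "dilution_bin": pd.array([1, 2, 1, pd.NA], dtype="Int64"),
                "is_control": [False, False, False, True],
            },
            index=pd.Index(["A1", "A2", "A3", "C1"], name="analyte_id"),
        )
    )
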