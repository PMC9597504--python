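import numpy as np
import pandas as pd
import pytest

from rosaeval import simulate


@pytest.fixture(scope="session")
def small_voc_sim():
    """A small volatile survey: 3 cultivars x 4 stages x 3 reps x 30 compounds."""
    design = simulate.VOCDesign(
        compounds=simulate.default_voc_compounds(30), flat_fraction=0.0, seed=7
    )
    return simulate.gen_voc_experiment(design)


@pytest.fixture(scope="session")
def study_design():
    return simulate.StudyDesign(seed=11)


@pytest.fixture
def consistent_matrix():
    """A perfectly consistent 3x3 judgment matrix with weights 4:2:1."""
    w = np.array([4.0, 2.0, 1.0])
    return np.outer(w, 1.0 / w)


@pytest.fixture
def voc_frame():
    """A tiny hand-written long-format VOC table (1 cultivar, 2 compounds)."""
    rows = []
    for stage in (1, 2, 3, 4):
        for rep in (1, 2, 3):
            rows.append(("CV", stage, rep, "linalool", "Monoterpenes", 100.0 * stage))
            rows.append(("CV", stage, rep, "hexanal", "Aldehydes", 50.0))
    return pd.DataFrame(
        rows, columns=["cultivar", "stage", "replicate", "compound", "compound_class", "concentration"]
    )
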