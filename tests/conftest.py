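import numpy as np
import pytest

import glyconet as g


def make_design(conditions, n_reps=3):
    """Design with the given (substrate, phase) conditions, n_reps each."""
    code = {"glucose": "G", "xylose": "X", "fructose": "F",
            "cellobiose": "C", "glucose_xylose": "GX"}
    samples = []
    for sub, ph in conditions:
        for rep in range(1, n_reps + 1):
            samples.append(g.Sample(f"{code[sub]}_{ph}_{rep}", sub, ph, rep))
    return g.SampleDesign(tuple(samples))


def make_matrix(values, design, genes=None, snr=None, snr_min=2.0):
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i:03d}" for i in range(values.shape[0])]
    return g.ExpressionMatrix(genes=genes, design=design, values=values,
                              snr=None if snr is None else np.asarray(snr, float),
                              snr_min=snr_min)


@pytest.fixture(scope="session")
def preset_result():
    """One full study-scale pipeline run (2322 genes, 33 arrays, 13 planted
    modules), shared by the recovery tests."""
    return g.run_synthetic_pipeline(g.study_preset(seed=1))


@pytest.fixture()
def one_condition_design():
    return make_design([("glucose", "mid")])
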