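import pandas as pd
import pytest

from anro import SimConfig, differential, preprocess
from anro.simulate import generate_experiment


@pytest.fixture(scope="session")
def experiment():
    """A small default-design synthetic experiment shared across tests."""
    cfg = SimConfig(n_genes=1500, seed=20100315)
    nro, total, annot, truth = generate_experiment(cfg)
    return cfg, nro, total, annot, truth


@pytest.fixture(scope="session")
def processed(experiment):
    """Detection-filtered matrices, z-scores and per-timepoint DE tables."""
    _, nro, total, annot, _ = experiment
    out = {}
    for name, mat in (("nro", nro), ("total", total)):
        filt = preprocess.filter_undetected(mat)
        z = preprocess.ztransform_array(filt)
        out[name] = {
            "matrix": filt,
            "z": z,
            "de": differential.timepoint_de_tables(z, filt, annot),
        }
    out["annotation"] = annot
    return out


@pytest.fixture()
def toy_annotation():
    rows = []
    for t, n in ((0.0, 2), (1.0, 2)):
        for r in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"S_T{t:g}_R{r}",
                    "timepoint_hr": t,
                    "replicate": r,
                    "rna_source": "TOTAL",
                    "platform": "toy",
                    "group": f"t{t:g}",
                }
            )
    return pd.DataFrame(rows)
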