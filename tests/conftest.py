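import numpy as np
import pandas as pd
import pytest

import fuzzsig as fs


@pytest.fixture(scope="session")
def signal_dataset():
    """Simulated paired dataset with strong planted signal (shared, read-only)."""
    cfg = fs.SynthConfig(seed=7)
    expr, meth, ann, loci, truth = fs.simulate_dataset(cfg)
    return cfg, expr, meth, ann, loci, truth


@pytest.fixture(scope="session")
def signal_panel(signal_dataset):
    _, _, _, _, _, truth = signal_dataset
    return fs.BiomarkerPanel("SYNTH", tuple(sorted(truth.biomarker_genes)))


@pytest.fixture(scope="session")
def signal_calls(signal_dataset):
    """DEG/DML/DMG tables for the shared signal dataset."""
    _, expr, meth, ann, loci, _ = signal_dataset
    degs = fs.call_deg(expr)
    pmap = fs.map_promoter_loci(ann, loci)
    dml = fs.call_dml(meth)
    dmgs = fs.call_dmg(dml, pmap)
    return degs, dml, dmgs, pmap


def toy_matrix(values, labels):
    """Small OmicsMatrix from a nested dict / DataFrame and a label mapping."""
    df = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    return fs.OmicsMatrix(df, pd.Series(labels))


def two_group_matrix(rows, n_tumor, n_normal, prefix=("T", "N")):
    """Features x samples matrix where each row is (tumor_values, normal_values)."""
    samples = [f"{prefix[0]}{i}" for i in range(n_tumor)] + \
              [f"{prefix[1]}{i}" for i in range(n_normal)]
    labels = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    data = {f"g{i}": np.concatenate([np.asarray(t, float), np.asarray(n, float)])
            for i, (t, n) in enumerate(rows)}
    df = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return fs.OmicsMatrix(df, labels)
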