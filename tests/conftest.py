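import numpy as np
import pandas as pd
import pytest

from silacq import synthetic_data as sd


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation shared across tests (fixed seed)."""
    cfg = sd.SimConfig(seed=42)
    evidence, truth = sd.simulate_evidence(cfg)
    return cfg, evidence, truth


@pytest.fixture()
def tiny_evidence():
    """Hand-written evidence: 2 proteins x 2 replicates, known ratios."""
    rows = []
    for rep in ("rep1", "rep2"):
        for seq, prot, l, m, h in [
            ("ELVISLIVEK", "P1", 100.0, 500.0, 1000.0),
            ("PEPTIDERK", "P1", 200.0, 1000.0, 2000.0),
            ("AAAAAAK", "P2", 100.0, 100.0, 50.0),
        ]:
            rows.append(
                dict(sequence=seq, protein=prot, charge=2, intensity_l=l,
                     intensity_m=m, intensity_h=h, replicate=rep)
            )
    return pd.DataFrame(rows)
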