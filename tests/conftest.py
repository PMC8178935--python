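import numpy as np
import pandas as pd
import pytest

from reasonscore import MethylationDataset, SimulationConfig, generate_bundle
from reasonscore.containers import validate_manifest


def make_dataset(beta_rows, detp_rows=None, outcome=(0, 0, 1, 1), probe_ids=None):
    """Small dataset builder: rows are per-probe beta tuples."""
    beta = np.asarray(beta_rows, dtype=float)
    n_probes, n_samples = beta.shape
    if probe_ids is None:
        probe_ids = [f"cg{i:03d}" for i in range(n_probes)]
    samples = [f"S{i}" for i in range(n_samples)]
    detp = (
        np.asarray(detp_rows, dtype=float)
        if detp_rows is not None
        else np.full_like(beta, 0.001)
    )
    return MethylationDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=samples),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=samples),
        outcome=pd.Series(list(outcome), index=samples),
    )


def make_manifest(probe_ids, chrom="1", gene="G1", snp=False, cross=False):
    """Manifest builder; scalar arguments broadcast across probes."""
    n = len(probe_ids)

    def expand(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return validate_manifest(
        pd.DataFrame(
            {
                "probe_id": list(probe_ids),
                "chrom": expand(chrom),
                "pos": np.arange(1, n + 1),
                "gene": expand(gene),
                "snp_flag": expand(snp),
                "cross_reactive_flag": expand(cross),
            }
        )
    )


@pytest.fixture(scope="session")
def planted_bundle():
    """A TCGA-scale planted bundle shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_patients=60, n_probes=2000, delta_beta=0.25)
    return generate_bundle(cfg)
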