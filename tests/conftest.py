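import numpy as np
import pandas as pd
import pytest

from perturbdecode import perturbseq as ps
from perturbdecode.simulate import (
    InSituSimConfig,
    PerturbseqSimConfig,
    simulate_insitu,
    simulate_perturbseq,
)


@pytest.fixture(scope="session")
def perturbseq_sim():
    """Default-scale dissociated Perturb-seq simulation with planted effects."""
    cfg = PerturbseqSimConfig(seed=1)
    counts, guides, meta, truth = simulate_perturbseq(cfg)
    return cfg, counts, guides, meta, truth


@pytest.fixture(scope="session")
def assigned(perturbseq_sim):
    """Counts and metadata restricted to singlet-assigned cells."""
    _, counts, guides, meta, _ = perturbseq_sim
    assign = ps.assign_perturbations(guides, min_umi=3)
    meta = meta.join(assign)
    keep = (meta["status"] == "singlet").to_numpy()
    return counts[keep], meta[keep]


@pytest.fixture(scope="session")
def insitu_sim():
    """Default-scale in situ Perturb-seq simulation."""
    cfg = InSituSimConfig(seed=5)
    counts, meta, truth, orf_counts, barcode_map = simulate_insitu(cfg)
    return cfg, counts, meta, truth, orf_counts, barcode_map


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_signature(target, up=(), down=(), **kw):
    from perturbdecode.perturbseq import GASignature

    return GASignature(target=target, up=frozenset(up), down=frozenset(down), **kw)


@pytest.fixture(scope="session")
def toy_signatures():
    """Hand-built GA signatures for network and hit-scoring tests."""
    return [
        make_signature("A", up={"X", "Y", "A"}, down={"Z"}),
        make_signature("B", up={"X"}, down={"Z", "W"}),
        make_signature("C", up={"Z"}, down={"X", "Y"}),
    ]
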