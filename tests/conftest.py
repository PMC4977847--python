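import numpy as np
import pytest

from mirx.energy import BASES, default_energy_model
from mirx.hybridize import DuplexHit
from mirx.pipeline import PipelineConfig, generate_inputs, run_pipeline
from mirx.synthgen import SynthConfig


@pytest.fixture(scope="session")
def model():
    return default_energy_model()


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=42)


@pytest.fixture(scope="session")
def study(tmp_path_factory, synth_cfg):
    """One synthetic study directory plus a completed pipeline run,
    shared across tests that score recovery of the planted structure."""
    root = tmp_path_factory.mktemp("study")
    paths = generate_inputs(synth_cfg, root / "inputs")
    cfg = PipelineConfig(seed=42, **paths)
    summary = run_pipeline(cfg, root / "run1")
    return {"root": root, "paths": paths, "cfg": cfg,
            "rundir": root / "run1", "summary": summary,
            "truth_dir": root / "inputs" / "truth"}


def random_rna(rng, length):
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def perfect_helix_pairs(n_pairs=21, j_hi=50):
    return tuple((i, j_hi - i) for i in range(n_pairs))


def make_hit(mfe=-30.0, pvalue=0.01, gene="g1", mirna="m1", region="CDS",
             pairs=None, symbols=None, start=None):
    """A structurally explicit hit for filter/rank tests."""
    pairs = pairs if pairs is not None else perfect_helix_pairs()
    symbols = symbols if symbols is not None else "|" * len(pairs)
    js = [j for _, j in pairs]
    return DuplexHit(mirna_id=mirna, gene_id=gene, region=region,
                     target_start=min(js) if start is None else start,
                     target_end=max(js) + 1, mfe=mfe, pvalue=pvalue,
                     pairs=pairs, pair_symbols=symbols, pairing="")


def random_structured_hit(rng, gene):
    """A hit with a random (but valid, non-crossing) gap structure."""
    pairs = []
    i, j = 0, int(rng.integers(60, 90))
    while i < 21 and j >= 0:
        pairs.append((i, j))
        step = rng.random()
        if step < 0.7:
            a, b = 0, 0
        elif step < 0.85:
            a, b = (int(rng.integers(1, 12)), 0) if rng.random() < 0.5 \
                else (0, int(rng.integers(1, 12)))
        else:
            a, b = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        i += 1 + a
        j -= 1 + b
    symbols = "".join("|" if rng.random() < 0.9 else ":"
                      for _ in range(len(pairs)))
    return make_hit(mfe=float(rng.uniform(-45, -10)),
                    pvalue=float(rng.uniform(0, 0.2)), gene=gene,
                    pairs=tuple(pairs), symbols=symbols)
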