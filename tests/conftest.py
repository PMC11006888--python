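import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from riboplast.io import OrfRecord, footprint_frame
from riboplast.simulate import SimulationConfig, make_toy_annotation

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_annotation():
    """Deterministic 3-gene toy plastid genome: +, -, + strands."""
    return make_toy_annotation(
        n_genes=3, lengths_codons=(100, 508, 80), spacer_nt=50, seed=0
    )


@pytest.fixture(scope="session")
def toy_genome(toy_annotation):
    return toy_annotation[0]


@pytest.fixture(scope="session")
def toy_orfs(toy_annotation):
    return toy_annotation[1]


@pytest.fixture()
def single_gene_config():
    """One 508-codon gene, clean signal: no noise, perfect frame."""
    genome, orfs = make_toy_annotation(
        n_genes=1, lengths_codons=(508,), spacer_nt=50, seed=0,
        gene_ids=("psbB",),
    )
    return SimulationConfig(
        genome=genome, orfs=orfs, depth_per_gene=10_000,
        replicate_noise_cv=0.0, frame_fidelity=1.0, seed=0,
    )


def make_footprints(entries, seq_id="toyplastid", sample_id="s1"):
    """entries: iterable of (start, end, strand[, sample_id])."""
    starts, ends, strands, samples = [], [], [], []
    for e in entries:
        starts.append(e[0])
        ends.append(e[1])
        strands.append(e[2])
        samples.append(e[3] if len(e) > 3 else sample_id)
    return footprint_frame(seq_id, starts, ends, np.array(strands, dtype=object), np.array(samples, dtype=object))


@pytest.fixture()
def plus_orf():
    return OrfRecord(gene_id="gA", seq_id="toyplastid", start=100, end=400, strand="+")


@pytest.fixture()
def minus_orf():
    return OrfRecord(gene_id="gB", seq_id="toyplastid", start=100, end=400, strand="-")
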