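import logging

import numpy as np
import pytest

from seedshift.io_formats import UTRSequence
from seedshift.synthetic_data import GeneratorConfig, generate
from seedshift.target_scan import MatureMiRNA

logging.getLogger("seedshift").setLevel(logging.ERROR)

_B2DNA = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")


def random_dna(rng: np.random.Generator, length: int) -> str:
    arr = rng.integers(0, 4, size=length, dtype=np.uint8)
    return bytes(arr).translate(_B2DNA).decode()


def make_utr(sequence: str, transcript_id: str = "t1", gene: str = "GENE",
             chrom: str = "1", strand: str = "+",
             start: int = 1) -> UTRSequence:
    return UTRSequence(transcript_id=transcript_id, gene_symbol=gene,
                       chrom=chrom, strand=strand,
                       genomic_span=((start, start + len(sequence) - 1),),
                       sequence=sequence)


@pytest.fixture
def toy_mirna():
    """A hand-checkable 10-nt miRNA (seed CAAGUAU -> 8mer site ATACTTGA)."""
    return MatureMiRNA(name="toy", sequence="UCAAGUAUCA")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle, shared read-only across the session."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths, truth = generate(GeneratorConfig(seed=7), outdir)
    return paths, truth
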