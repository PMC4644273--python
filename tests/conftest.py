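import numpy as np
import pytest
from hypothesis import settings

from diffpick.simdata import PLATFORM_A, Read, SimProfile, generate_genome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome_20kb():
    return generate_genome(20_000, 0.47, seed=11, genome_id="g20")


@pytest.fixture(scope="session")
def noiseless_profile():
    return SimProfile(error_rate=0.0, wga_chimera_rate=0.0)


def make_read(seq, rid="r1", quals=None, platform=PLATFORM_A, mate_id=None):
    return Read(
        id=rid,
        platform=platform,
        sequence=seq,
        qualities=list(quals) if quals is not None else [30] * len(seq),
        mate_id=mate_id,
    )


def tiling_reads(sequence, read_len=200, step=50):
    """Error-free reads tiling a linear sequence."""
    return [
        make_read(sequence[i : i + read_len], rid=f"t{i}")
        for i in range(0, len(sequence) - read_len + 1, step)
    ]


@pytest.fixture
def toy_genbank(tmp_path):
    """A small annotated GenBank record written with Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(5)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1000)])
    rec = SeqRecord(Seq(seq), id="toy001", name="toy001", description="toy record")
    rec.annotations["molecule_type"] = "DNA"
    rec.features = [
        SeqFeature(SimpleLocation(0, 9, strand=1), type="CDS", qualifiers={"product": ["p1"]}),
        SeqFeature(
            CompoundLocation([SimpleLocation(0, 3, strand=-1), SimpleLocation(6, 9, strand=-1)]),
            type="CDS",
            qualifiers={"product": ["p2"]},
        ),
        SeqFeature(SimpleLocation(199, 275, strand=1), type="tRNA"),
        SeqFeature(SimpleLocation(299, 350, strand=1), type="CDS", qualifiers={"pseudo": [""]}),
    ]
    path = tmp_path / "toy.gb"
    from Bio import SeqIO

    SeqIO.write(rec, str(path), "genbank")
    return path, seq
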