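import numpy as np
import pytest

TOY_GFF = """##gff-version 3
chr1\ttoy\tgene\t100\t400\t.\t+\t.\tID=geneA
chr1\ttoy\tmRNA\t100\t400\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttoy\texon\t100\t200\t.\t+\t.\tParent=geneA.t1
chr1\ttoy\texon\t301\t400\t.\t+\t.\tParent=geneA.t1
chr1\ttoy\tCDS\t150\t200\t.\t+\t0\tParent=geneA.t1
chr1\ttoy\tCDS\t301\t350\t.\t+\t0\tParent=geneA.t1
chr1\ttoy\tgene\t1000\t1400\t.\t-\t.\tID=geneB
chr1\ttoy\tmRNA\t1000\t1400\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\ttoy\texon\t1000\t1400\t.\t-\t.\tParent=geneB.t1
chr1\ttoy\tCDS\t1050\t1350\t.\t-\t0\tParent=geneB.t1
"""


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_protein(rng, n):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, n))
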