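import numpy as np
import pandas as pd
import pytest

from elsplice.io_formats import GenomicInterval, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    """Deterministic 6-kb single-contig genome as a plain string dict."""
    r = np.random.default_rng(42)
    seq = "".join(r.choice(list("ACGT"), size=6000))
    return {"chr1": seq}


@pytest.fixture
def three_exon_transcript():
    # internal exon of 120 nt; introns (1200,1500) and (1620,2000)
    return TranscriptModel("tx1", "chr1", "+",
                           [(1000, 1200), (1500, 1620), (2000, 2300)],
                           biotype="lncRNA")


@pytest.fixture
def minus_transcript():
    return TranscriptModel("txm", "chr1", "-",
                           [(1000, 1200), (1500, 1620), (2000, 2300)],
                           biotype="lncRNA")


@pytest.fixture
def enhancer_intervals():
    return [GenomicInterval("chr1", 3000, 3500, ".", "enh1")]


@pytest.fixture
def promoter_intervals():
    return [GenomicInterval("chr1", 100, 400, ".", "prom1")]


@pytest.fixture
def counts_table():
    from elsplice.io_formats import IntronClusterTable
    counts = pd.DataFrame(
        {"s1": [30, 10, 10, 5], "s2": [0, 0, 0, 8], "s3": [4, 4, 2, 100]},
        index=["chr1:100:200:clu_1", "chr1:100:300:clu_1",
               "chr1:100:400:clu_1", "chr2:50:80:clu_2"])
    counts.index.name = "intron"
    return IntronClusterTable(counts=counts)
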