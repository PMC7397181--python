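import numpy as np
import pandas as pd
import pytest

from isoloc.models import ExpressionTable, TranscriptModel


def make_expression(values: dict[str, list[float]], n_rep: int = 2,
                    transcripts=None) -> ExpressionTable:
    """Build an ExpressionTable from per-sample TPM columns.

    ``values`` maps sample ids like 'cytoplasm_1' to TPM lists.
    """
    meta_rows = []
    for sid in values:
        fraction, rep = sid.rsplit("_", 1)
        meta_rows.append((sid, fraction, int(rep)))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "fraction",
                                            "replicate"]).set_index("sample_id")
    n = len(next(iter(values.values())))
    idx = transcripts if transcripts is not None else [f"T{i+1}" for i in range(n)]
    return ExpressionTable(pd.DataFrame(values, index=idx), meta)


def two_isoform_gene(gene="G1", chrom="chr1", strand="+"):
    """A gene with a skipped internal exon between its two isoforms."""
    t1 = TranscriptModel(f"{gene}.t1", gene, chrom, strand,
                         ((100, 200), (300, 400), (500, 600)))
    t2 = TranscriptModel(f"{gene}.t2", gene, chrom, strand,
                         ((100, 200), (500, 600)))
    return [t1, t2]


@pytest.fixture
def se_gene():
    return two_isoform_gene()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
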