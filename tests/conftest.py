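import numpy as np
import pandas as pd
import pytest

from dtusage.data import TranscriptQuantification


@pytest.fixture
def small_quant() -> TranscriptQuantification:
    """Two genes (2 + 1 transcripts), two samples, hand-readable counts."""
    values = pd.DataFrame(
        {"s1": [2.0, 3.0, 4.0], "s2": [1.0, 2.0, 0.0]},
        index=["tx1", "tx2", "tx3"],
    )
    gene_of = pd.Series(["g1", "g1", "g2"], index=["tx1", "tx2", "tx3"])
    samples = pd.DataFrame({"group": ["A", "B"]}, index=["s1", "s2"])
    return TranscriptQuantification(values=values, gene_of=gene_of, sample_table=samples)


def random_quant(rng: np.random.Generator, n_genes: int = 8, n_samples: int = 6,
                 max_tx: int = 4, lam: float = 20.0) -> TranscriptQuantification:
    """Random Poisson count fixture with 1..max_tx transcripts per gene."""
    tx_ids, gene_ids, rows = [], [], []
    for g in range(n_genes):
        T = int(rng.integers(1, max_tx + 1))
        for t in range(T):
            tx_ids.append(f"g{g}t{t}")
            gene_ids.append(f"g{g}")
            rows.append(rng.poisson(lam, size=n_samples).astype(float))
    cols = [f"s{i}" for i in range(n_samples)]
    values = pd.DataFrame(np.array(rows), index=tx_ids, columns=cols)
    samples = pd.DataFrame({"group": ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)},
                           index=cols)
    return TranscriptQuantification(values=values, gene_of=pd.Series(gene_ids, index=tx_ids),
                                    sample_table=samples)


def write_quant_tsv(q: TranscriptQuantification, tmp_path):
    """Write a quantification to TSV files; returns (values, tx2gene, samples) paths."""
    vp = tmp_path / "counts.tsv"
    tp = tmp_path / "tx2gene.tsv"
    sp = tmp_path / "samples.tsv"
    q.values.to_csv(vp, sep="\t", index_label="transcript_id")
    q.gene_of.rename("gene_id").to_csv(tp, sep="\t", index_label="transcript_id")
    q.sample_table.to_csv(sp, sep="\t", index_label="sample_id")
    return vp, tp, sp
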