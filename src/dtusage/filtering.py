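"""Transcript retention filters.

Two strategies are provided: a lenient CPM-based filter in the style of
edgeR's ``filterByExpr`` and a stringent three-step filter in the style of
DRIMSeq's ``dmFilter``.  Both finish by discarding transcripts whose gene
retains only a single transcript, since usage analysis is vacuous there.
The edgeR-style rule here is pure CPM thresholding as the strategy is
usually described; it does not replicate filterByExpr's library-size
adjusted cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TranscriptQuantification, gene_totals

logger = logging.getLogger(__name__)


def smallest_group_size(groups: pd.Series) -> int:
    """Size of the smallest group (n_s) of the primary grouping factor."""
    return int(groups.value_counts().min())


@dataclass
class EdgeRFilterParams:
    """CPM thresholds for the edgeR-style filter.

    ``n_required`` may be fractional; "at least n samples" is then satisfied
    only by integer counts >= n_required (an effective ceiling).
    """

    min_count: float = 10.0
    n_required: float = 10.0
    min_total_count: float = 10.0

    def __post_init__(self) -> None:
        if min(self.min_count, self.n_required, self.min_total_count) < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def bulk(cls, n_s: int) -> "EdgeRFilterParams":
        return cls(min_count=10.0, n_required=min(10.0, 0.7 * n_s), min_total_count=10.0)

    @classmethod
    def single_cell(cls, n_s: int) -> "EdgeRFilterParams":
        return cls(min_count=1.0, n_required=0.5 * n_s, min_total_count=0.0)

    @classmethod
    def preset(cls, name: str, n_s: int) -> "EdgeRFilterParams":
        if name in ("bulk",):
            return cls.bulk(n_s)
        if name in ("single_cell", "sc"):
            return cls.single_cell(n_s)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class DmFilterParams:
    """Thresholds for the DRIMSeq-style three-step filter."""

    min_count_per_sample: float = 10.0
    min_prop: float = 0.10
    min_gene_count: float = 10.0

    def __post_init__(self) -> None:
        if min(self.min_count_per_sample, self.min_gene_count) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.min_prop <= 1:
            raise ValueError("min_prop must lie in [0, 1]")


def cpm(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Counts per million: each entry over its sample's column total, x 1e6.

    Zero-total samples yield zeros.
    """
    arr = np.asarray(values, dtype=float)
    totals = arr.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = arr / totals * 1e6
    out[:, totals.ravel() == 0] = 0.0
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def _drop_single_transcript_genes(keep: pd.Index, gene_of: pd.Series) -> pd.Index:
    genes = gene_of.loc[keep]
    counts = genes.value_counts()
    multi = set(counts.index[counts >= 2])
    return keep[[g in multi for g in genes]]


def filter_edger_style(
    q: TranscriptQuantification,
    groups: pd.Series,
    params: EdgeRFilterParams | None = None,
    preset: str = "bulk",
) -> pd.Index:
    """Retain transcripts with CPM >= min_count in >= n_required samples and
    total CPM >= min_total_count; then drop single-transcript genes."""
    if params is None:
        params = EdgeRFilterParams.preset(preset, smallest_group_size(groups))
    c = np.asarray(cpm(q.values))
    n_pass = (c >= params.min_count).sum(axis=1)
    keep_mask = (n_pass >= params.n_required) & (c.sum(axis=1) >= params.min_total_count)
    keep = q.values.index[keep_mask]
    keep = _drop_single_transcript_genes(keep, q.gene_of)
    if len(keep) == 0:
        logger.warning("edgeR-style filter retained no transcripts")
    logger.info("edgeR-style filter: %d -> %d transcripts", q.n_transcripts, len(keep))
    return keep


def filter_drimseq_style(
    q: TranscriptQuantification,
    groups: pd.Series,
    params: DmFilterParams | None = None,
) -> pd.Index:
    """Three sequential retention steps on raw counts, then drop
    single-transcript genes.

    1. count >= min_count_per_sample in >= n_s samples;
    2. within-gene proportion >= min_prop in >= n_s samples;
    3. remove every transcript of a gene whose total falls below
       min_gene_count in any sample.
    """
    if params is None:
        params = DmFilterParams()
    n_s = smallest_group_size(groups)
    counts = q.values.to_numpy()
    totals = gene_totals(q)
    denom = totals.loc[q.gene_of.to_numpy()].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        props = np.where(denom > 0, counts / np.where(denom > 0, denom, 1.0), 0.0)

    step1 = (counts >= params.min_count_per_sample).sum(axis=1) >= n_s
    step2 = (props >= params.min_prop).sum(axis=1) >= n_s
    gene_ok = (totals.to_numpy() >= params.min_gene_count).all(axis=1)
    gene_ok = pd.Series(gene_ok, index=totals.index)
    step3 = gene_ok.loc[q.gene_of.to_numpy()].to_numpy()

    keep = q.values.index[step1 & step2 & step3]
    keep = _drop_single_transcript_genes(keep, q.gene_of)
    if len(keep) == 0:
        logger.warning("DRIMSeq-style filter retained no transcripts")
    logger.info("DRIMSeq-style filter: %d -> %d transcripts", q.n_transcripts, len(keep))
    return keep
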