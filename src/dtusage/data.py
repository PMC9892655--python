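"""Transcript-level quantification containers and abundance transforms.

The central object is :class:`TranscriptQuantification`: a transcripts x
samples matrix of non-negative expression estimates (counts, scaledTPM,
exon counts or equivalence-class counts) together with a transcript->gene
map and per-sample annotations.  From it we derive per-gene totals
``Y_g.i`` and within-gene usages ``U_gti = Y_gti / Y_g.i``, the response
modelled downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

FEATURE_LEVELS = ("transcript", "exon", "equivalence_class")


@dataclass
class TranscriptQuantification:
    """Transcripts x samples expression matrix with gene map and annotations.

    Parameters
    ----------
    values
        Non-negative matrix; rows indexed by transcript id, columns by
        sample/cell id.
    gene_of
        Series mapping transcript id -> gene id; must cover every row.
    sample_table
        Per-sample annotations (group labels, covariates), indexed by
        sample id in the same order as ``values`` columns.
    lengths
        Optional per-transcript length in base pairs (required only for
        scaledTPM conversion); strictly positive.
    feature_level
        One of ``transcript``, ``exon``, ``equivalence_class``.  The
        statistical machinery is identical for all three; only the meaning
        of a "transcript" row changes.
    """

    values: pd.DataFrame
    gene_of: pd.Series
    sample_table: pd.DataFrame
    lengths: pd.Series | None = None
    feature_level: str = "transcript"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups[:10]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative entries")
        missing = self.values.index.difference(self.gene_of.index)
        if len(missing) > 0:
            raise ValueError(
                "transcripts missing from tx2gene map: " + ", ".join(map(str, missing[:10]))
            )
        self.gene_of = self.gene_of.reindex(self.values.index)
        if not self.values.columns.equals(pd.Index(self.sample_table.index)):
            raise ValueError("sample mismatch between matrix columns and sample table rows")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any():
                raise ValueError("lengths missing for some transcripts")
            if (self.lengths <= 0).any():
                raise ValueError("transcript lengths must be strictly positive")
        if self.feature_level not in FEATURE_LEVELS:
            raise ValueError(f"feature_level must be one of {FEATURE_LEVELS}")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_transcripts(self, keep: Sequence[str]) -> "TranscriptQuantification":
        """Return a copy restricted to ``keep`` (original row order preserved)."""
        keep_idx = self.values.index.intersection(pd.Index(keep))
        keep_idx = self.values.index[self.values.index.isin(keep_idx)]
        return TranscriptQuantification(
            values=self.values.loc[keep_idx].copy(),
            gene_of=self.gene_of.loc[keep_idx].copy(),
            sample_table=self.sample_table.copy(),
            lengths=None if self.lengths is None else self.lengths.loc[keep_idx].copy(),
            feature_level=self.feature_level,
        )


@dataclass
class DesignSpec:
    """Design matrix and named contrasts for the mean model.

    ``X`` is the n x p design matrix (one row per sample); each contrast is
    a length-p vector L, and L'beta is the tested log-odds ratio.
    """

    X: np.ndarray
    column_names: list[str]
    contrasts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match X")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix X is not of full column rank")
        self.contrasts = {k: np.asarray(v, dtype=float) for k, v in self.contrasts.items()}
        for name, L in self.contrasts.items():
            if L.shape != (self.X.shape[1],):
                raise ValueError(f"contrast {name!r} has length {L.size}, expected {self.X.shape[1]}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def design_from_groups(groups: pd.Series, contrast_name: str | None = None) -> DesignSpec:
    """Two-group intercept + indicator design with a single group contrast.

    The first group label in sorted order is the reference; the contrast
    tests the log-odds ratio of the second group versus the reference.
    """
    levels = sorted(pd.unique(groups.astype(str)))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    ind = (groups.astype(str) == levels[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(ind), ind])
    name = contrast_name or f"{levels[1]}_vs_{levels[0]}"
    return DesignSpec(X=X, column_names=["intercept", levels[1]], contrasts={name: np.array([0.0, 1.0])})


def _read_table(path: Path, index_col: int | None = 0) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def _read_matrix(path: Path) -> pd.DataFrame:
    """Read a matrix from TSV/CSV (first column = transcript id) or
    MatrixMarket coordinate format with ``<path>.rows``/``<path>.cols``
    sidecar name files."""
    if path.suffix.lower() == ".mtx":
        rows_file = path.with_suffix(path.suffix + ".rows")
        cols_file = path.with_suffix(path.suffix + ".cols")
        for side in (rows_file, cols_file):
            if not side.exists():
                raise FileNotFoundError(f"sidecar name file not found: {side}")
        m = mmread(str(path))
        mat = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
        row_names = rows_file.read_text().split()
        col_names = cols_file.read_text().split()
        return pd.DataFrame(mat, index=row_names, columns=col_names)
    out = _read_table(path)
    out.index.name = None
    out.columns.name = None
    return out


def load_quantification(
    values_path: str | Path,
    tx2gene_path: str | Path,
    samples_path: str | Path,
    lengths_path: str | Path | None = None,
    feature_level: str = "transcript",
) -> TranscriptQuantification:
    """Load and validate a quantification matrix with its gene map.

    ``tx2gene_path`` must be a two-column table (transcript_id, gene_id);
    ``samples_path`` rows must match the matrix columns.
    """
    values_path, tx2gene_path, samples_path = Path(values_path), Path(tx2gene_path), Path(samples_path)
    for p in (values_path, tx2gene_path, samples_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    values = _read_matrix(values_path)
    t2g = _read_table(tx2gene_path, index_col=None)
    if t2g.shape[1] < 2:
        raise ValueError("tx2gene must have columns (transcript_id, gene_id)")
    gene_of = pd.Series(t2g.iloc[:, 1].to_numpy(), index=t2g.iloc[:, 0].to_numpy())
    if gene_of.index.has_duplicates:
        conflicting = gene_of.groupby(level=0).nunique()
        if (conflicting > 1).any():
            raise ValueError(
                "tx2gene maps transcripts to multiple genes: "
                + ", ".join(map(str, conflicting.index[conflicting > 1][:10]))
            )
        gene_of = gene_of[~gene_of.index.duplicated()]
    sample_table = _read_table(samples_path)
    lengths = None
    if lengths_path is not None:
        ltab = _read_table(Path(lengths_path))
        lengths = ltab.iloc[:, 0].astype(float)
    return TranscriptQuantification(
        values=values,
        gene_of=gene_of,
        sample_table=sample_table,
        lengths=lengths,
        feature_level=feature_level,
    )


def drop_multi_gene_classes(tx2gene: pd.DataFrame) -> pd.DataFrame:
    """Drop equivalence classes mapped to more than one gene.

    Returns the filtered two-column map; logs how many classes were removed.
    """
    ngenes = tx2gene.groupby(tx2gene.columns[0])[tx2gene.columns[1]].nunique()
    bad = set(ngenes.index[ngenes > 1])
    if bad:
        logger.info("dropping %d equivalence classes mapped to >1 gene", len(bad))
    return tx2gene[~tx2gene.iloc[:, 0].isin(bad)].drop_duplicates()


def gene_totals(q: TranscriptQuantification) -> pd.DataFrame:
    """Per-gene, per-sample totals ``Y_g.i``: sum of the gene's transcript rows."""
    return q.values.groupby(q.gene_of.to_numpy()).sum()


def usage(q: TranscriptQuantification) -> pd.DataFrame:
    """Within-gene usages ``U_gti = Y_gti / Y_g.i``.

    Entries are missing (NaN) exactly where the gene total is zero; the
    binomial-style variance is undefined there and downstream fitting gives
    such observations zero weight.
    """
    totals = gene_totals(q)
    denom = totals.loc[q.gene_of.to_numpy()].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = q.values.to_numpy() / denom
    u[denom == 0] = np.nan
    return pd.DataFrame(u, index=q.values.index, columns=q.values.columns)


def transcript_gene_totals(q: TranscriptQuantification) -> pd.DataFrame:
    """Gene totals broadcast to transcript rows (the GLM prior weights)."""
    totals = gene_totals(q)
    out = totals.loc[q.gene_of.to_numpy()]
    out.index = q.values.index
    return out


def scaled_tpm(q: TranscriptQuantification) -> TranscriptQuantification:
    """Length-corrected abundances rescaled to the original count depth.

    Per sample: reads per kilobase RPK = count / (length/1000); TPM = RPK
    normalised to sum to 1e6; scaledTPM = TPM rescaled so the per-sample
    sum equals that sample's original count total.  A sample with zero
    total yields all zeros.
    """
    if q.lengths is None:
        raise ValueError("scaled_tpm requires transcript lengths")
    counts = q.values.to_numpy()
    kb = (q.lengths.to_numpy() / 1000.0)[:, None]
    rpk = counts / kb
    rpk_tot = rpk.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = rpk / rpk_tot * 1e6
    count_tot = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = tpm / tpm.sum(axis=0, keepdims=True) * count_tot
    out[:, count_tot.ravel() == 0] = 0.0
    values = pd.DataFrame(out, index=q.values.index, columns=q.values.columns)
    return TranscriptQuantification(
        values=values,
        gene_of=q.gene_of.copy(),
        sample_table=q.sample_table.copy(),
        lengths=q.lengths.copy(),
        feature_level=q.feature_level,
    )
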