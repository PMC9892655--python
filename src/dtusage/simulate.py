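"""Synthetic two-group benchmark data with swap-based DTU ground truth.

The generator emulates the structure of a subsampled two-group RNA-seq
benchmark: per-gene, per-cell totals from a negative binomial with
gene-specific means, transcript counts allocated within each gene by a
Dirichlet-multinomial around gene-specific baseline proportions, and DTU
introduced non-parametrically by permuting ("swapping") the counts of a
subset of transcripts within a gene in one group only.  Swapping leaves
every per-cell gene total untouched, so the induced signal is pure
differential usage with no differential gene expression.

The number of transcripts swapped in a DTU gene is k = min(T_g, max(2,
Binomial(T_g, 1/3))): at least two, at most all of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TranscriptQuantification

logger = logging.getLogger(__name__)


@dataclass
class SwapTruth:
    """Ground-truth record of one perturbed gene."""

    gene_id: str
    swapped_transcripts: list[str]
    permutation: dict[str, str]
    group_perturbed: str

    def __post_init__(self) -> None:
        if len(self.swapped_transcripts) < 2:
            raise ValueError("a DTU gene must have at least 2 swapped transcripts")
        if any(src == dst for src, dst in self.permutation.items()):
            raise ValueError("swap permutation must have no fixed points")


@dataclass
class SyntheticParams:
    """Generator settings.

    ``mean_total`` is the expected per-cell gene total averaged over genes;
    gene-specific means are lognormal around it (sigma
    ``total_log_sigma``), and per-cell totals are negative binomial with
    dispersion ``total_dispersion`` (variance mu + total_dispersion *
    mu^2).  ``usage_overdispersion`` theta controls the
    Dirichlet-multinomial concentration 1/theta of within-gene
    proportions; theta = 0 gives conditionally multinomial (binomial per
    transcript) counts.
    """

    n_genes: int = 3000
    tx_per_gene: tuple[int, int] = (2, 5)
    n_per_group: int = 20
    dtu_fraction: float = 0.15
    mean_total: float = 100.0
    total_log_sigma: float = 1.0
    total_dispersion: float = 0.3
    usage_overdispersion: float = 0.02
    group_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dtu_fraction <= 1:
            raise ValueError("dtu_fraction must lie in [0, 1]")
        if self.tx_per_gene[0] < 1 or self.tx_per_gene[1] < self.tx_per_gene[0]:
            raise ValueError("invalid tx_per_gene range")
        if self.usage_overdispersion < 0:
            raise ValueError("usage_overdispersion must be >= 0")


def n_transcripts_to_swap(T_g: int, rng: np.random.Generator) -> int:
    """k = min(T_g, max(2, Binomial(T_g, 1/3)))."""
    if T_g < 2:
        raise ValueError("need at least 2 transcripts to swap")
    return int(min(T_g, max(2, rng.binomial(T_g, 1.0 / 3.0))))


def _random_cycle(items: list[str], rng: np.random.Generator) -> dict[str, str]:
    """A uniformly random cyclic permutation of ``items`` (no fixed points)."""
    order = [items[i] for i in rng.permutation(len(items))]
    return {order[i]: order[(i + 1) % len(order)] for i in range(len(order))}


def introduce_dtu_by_swap(
    q: TranscriptQuantification,
    groups: pd.Series,
    dtu_fraction: float = 0.15,
    rng: np.random.Generator | int | None = None,
    group_perturbed: str | None = None,
) -> tuple[TranscriptQuantification, list[SwapTruth]]:
    """Introduce DTU by permuting transcript count rows within genes in one group.

    A ``dtu_fraction`` sample of the genes with >= 2 transcripts is drawn
    uniformly; within each selected gene, k transcripts (see
    :func:`n_transcripts_to_swap`) are permuted by a random cycle in the
    perturbed group's columns only.  Per-cell gene totals are unchanged.
    """
    rng = np.random.default_rng(rng)
    levels = sorted(pd.unique(groups.astype(str)))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if group_perturbed is None:
        group_perturbed = levels[1]
    col_mask = (groups.astype(str) == group_perturbed).to_numpy()

    tx_per_gene = q.gene_of.value_counts()
    eligible = np.array(sorted(tx_per_gene.index[tx_per_gene >= 2]))
    n_dtu = int(round(dtu_fraction * len(tx_per_gene)))
    if n_dtu > len(eligible):
        logger.warning(
            "requested %d DTU genes but only %d eligible; using all eligible", n_dtu, len(eligible)
        )
        n_dtu = len(eligible)
    chosen = rng.choice(eligible, size=n_dtu, replace=False)

    values = q.values.copy()
    arr = values.to_numpy()
    row_of = {tx: i for i, tx in enumerate(values.index)}
    truths: list[SwapTruth] = []
    for gene in chosen:
        txs = list(q.gene_of.index[q.gene_of.to_numpy() == gene])
        k = n_transcripts_to_swap(len(txs), rng)
        swapped = [txs[i] for i in rng.choice(len(txs), size=k, replace=False)]
        perm = _random_cycle(swapped, rng)
        src_rows = [row_of[t] for t in swapped]
        # row of t receives the counts of the transcript mapping TO t
        inv = {dst: src for src, dst in perm.items()}
        new_block = arr[[row_of[inv[t]] for t in swapped]][:, col_mask]
        for r, t in zip(src_rows, swapped):
            arr[r, col_mask] = new_block[swapped.index(t)]
        truths.append(
            SwapTruth(
                gene_id=str(gene),
                swapped_transcripts=[str(t) for t in swapped],
                permutation={str(a): str(b) for a, b in perm.items()},
                group_perturbed=str(group_perturbed),
            )
        )
    out = TranscriptQuantification(
        values=values,
        gene_of=q.gene_of.copy(),
        sample_table=q.sample_table.copy(),
        lengths=None if q.lengths is None else q.lengths.copy(),
        feature_level=q.feature_level,
    )
    return out, truths


def simulate_dataset(
    params: SyntheticParams,
) -> tuple[TranscriptQuantification, pd.Series, list[SwapTruth]]:
    """Generate a two-group dataset with swap-based DTU and ground truth.

    Fully reproducible under ``params.seed``.  Returns the perturbed
    quantification, the per-cell group labels, and the truth records.
    """
    rng = np.random.default_rng(params.seed)
    n_cells = 2 * params.n_per_group
    lab_a, lab_b = params.group_labels
    cells = [f"cell{i+1:04d}" for i in range(n_cells)]
    groups = pd.Series([lab_a] * params.n_per_group + [lab_b] * params.n_per_group, index=cells)

    tx_counts = rng.integers(params.tx_per_gene[0], params.tx_per_gene[1] + 1, size=params.n_genes)
    # lognormal gene means centred so E[mu_g] = mean_total
    log_mu = rng.normal(
        np.log(params.mean_total) - params.total_log_sigma**2 / 2.0,
        params.total_log_sigma,
        size=params.n_genes,
    )
    mu_g = np.exp(log_mu)

    rows = []
    tx_ids: list[str] = []
    gene_ids: list[str] = []
    for g in range(params.n_genes):
        T_g = int(tx_counts[g])
        gene = f"gene{g+1:05d}"
        base = rng.dirichlet(np.ones(T_g))
        # NB totals: gamma-Poisson with shape 1/alpha
        if params.total_dispersion > 0:
            shape = 1.0 / params.total_dispersion
            lam = rng.gamma(shape, mu_g[g] / shape, size=n_cells)
        else:
            lam = np.full(n_cells, mu_g[g])
        totals = rng.poisson(lam)
        if params.usage_overdispersion > 0:
            conc = base / params.usage_overdispersion
            props = rng.dirichlet(conc, size=n_cells)
        else:
            props = np.broadcast_to(base, (n_cells, T_g))
        counts = rng.multinomial(totals, props)  # (n_cells, T_g)
        rows.append(counts.T)
        tx_ids.extend(f"{gene}_tx{t+1}" for t in range(T_g))
        gene_ids.extend([gene] * T_g)

    values = pd.DataFrame(np.vstack(rows), index=tx_ids, columns=cells, dtype=float)
    q = TranscriptQuantification(
        values=values,
        gene_of=pd.Series(gene_ids, index=tx_ids),
        sample_table=pd.DataFrame({"group": groups}),
        feature_level="transcript",
    )
    if params.dtu_fraction > 0:
        q, truths = introduce_dtu_by_swap(
            q, groups, dtu_fraction=params.dtu_fraction, rng=rng, group_perturbed=lab_b
        )
    else:
        truths = []
    return q, groups, truths


def truth_table(truths: list[SwapTruth]) -> pd.DataFrame:
    """Flatten truth records to one row per swapped transcript."""
    rows = [
        {
            "transcript_id": tx,
            "gene_id": t.gene_id,
            "swapped_with": t.permutation[tx],
            "group_perturbed": t.group_perturbed,
        }
        for t in truths
        for tx in t.swapped_transcripts
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "swapped_with", "group_perturbed"])
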