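"""Benchmark evaluation: confusion counts, FDR-TPR curves, usage plot data,
and the end-to-end pipeline runner.

A transcript counts as "true DTU" iff it belongs to a swap set in the
ground truth; calls are made on BH-adjusted empirical p-values at a
nominal level alpha.  The FDR-TPR curve ranks transcripts by empirical
p-value (ties broken by |t| descending, then id, for determinism) and
traces the false discovery proportion FDP = FP / (FP + TP) against the
true positive rate TPR = TP / (TP + FN) along the ranking, with working
points marked at the 1%, 5% and 10% nominal FDR levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference
from .data import TranscriptQuantification, design_from_groups, gene_totals, load_quantification, usage
from .filtering import filter_drimseq_style, filter_edger_style
from .model import TranscriptFit, fit_all
from .simulate import SwapTruth, SyntheticParams, simulate_dataset, truth_table

logger = logging.getLogger(__name__)

NOMINAL_LEVELS = (0.01, 0.05, 0.10)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def tpr(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) > 0 else 0.0

    @property
    def fdp(self) -> float:
        # 0/0 at zero calls: defined as 0 by convention
        return self.FP / (self.FP + self.TP) if (self.FP + self.TP) > 0 else 0.0


def _truth_set(truth: list[SwapTruth] | pd.DataFrame | set) -> set[str]:
    if isinstance(truth, set):
        return truth
    if isinstance(truth, pd.DataFrame):
        return set(truth["transcript_id"].astype(str))
    return {tx for t in truth for tx in t.swapped_transcripts}


def confusion(
    results: pd.DataFrame,
    truth: list[SwapTruth] | pd.DataFrame | set,
    alpha: float,
    call_col: str = "fdr_emp",
) -> ConfusionCounts:
    """Exact confusion counts at level alpha; missing p-values are non-calls."""
    pos = _truth_set(truth)
    ids = results["transcript_id"].astype(str)
    is_true = ids.isin(pos).to_numpy()
    called = (results[call_col].to_numpy() <= alpha) & np.isfinite(results[call_col].to_numpy())
    return ConfusionCounts(
        TP=int((called & is_true).sum()),
        FP=int((called & ~is_true).sum()),
        TN=int((~called & ~is_true).sum()),
        FN=int((~called & is_true).sum()),
    )


def fdr_tpr_curve(
    results: pd.DataFrame,
    truth: list[SwapTruth] | pd.DataFrame | set,
    rank_col: str = "p_emp",
    adj_col: str = "fdr_emp",
) -> pd.DataFrame:
    """One curve point per rank, plus marked nominal working points.

    Returns a table with columns rank, fdp, tpr, nominal_level, achieved;
    ``nominal_level`` is set on the row whose rank equals the number of
    calls at that BH level, ``achieved`` flags empirical FDP <= nominal.
    Transcripts with missing ranking p-values are excluded from the curve.
    """
    pos = _truth_set(truth)
    r = results.copy()
    r["transcript_id"] = r["transcript_id"].astype(str)
    r = r[np.isfinite(r[rank_col].to_numpy())]
    order = r.sort_values(
        by=[rank_col, "t", "transcript_id"],
        ascending=[True, True, True],
        key=lambda s: -s.abs() if s.name == "t" else s,
    )
    is_true = order["transcript_id"].isin(pos).to_numpy()
    n_pos = len(pos & set(results["transcript_id"].astype(str)))
    tp = np.cumsum(is_true)
    fp = np.cumsum(~is_true)
    ranks = np.arange(1, len(order) + 1)
    with np.errstate(invalid="ignore"):
        fdp = fp / ranks
        tpr = tp / n_pos if n_pos > 0 else np.zeros_like(tp, dtype=float)
    curve = pd.DataFrame(
        {
            "rank": np.concatenate([[0], ranks]),
            "fdp": np.concatenate([[0.0], fdp]),
            "tpr": np.concatenate([[0.0], tpr]),
            "nominal_level": np.nan,
            "achieved": pd.array([pd.NA] * (len(order) + 1), dtype="boolean"),
        }
    )
    adj = order[adj_col].to_numpy()
    extra = []
    for level in NOMINAL_LEVELS:
        n_calls = int((adj[np.isfinite(adj)] <= level).sum())
        row = curve.index[curve["rank"] == n_calls][0]
        if pd.isna(curve.loc[row, "nominal_level"]):
            curve.loc[row, "nominal_level"] = level
            curve.loc[row, "achieved"] = bool(curve.loc[row, "fdp"] <= level)
        else:
            # several nominal levels land on the same number of calls:
            # emit a duplicate point so every level is represented
            dup = curve.loc[row].copy()
            dup["nominal_level"] = level
            dup["achieved"] = bool(dup["fdp"] <= level)
            extra.append(dup)
    if extra:
        curve = pd.concat([curve, pd.DataFrame(extra)], ignore_index=True)
    return curve


def usage_plot_data(
    q: TranscriptQuantification,
    fits: list[TranscriptFit],
    gene_id: str,
    groups: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Data behind a per-gene usage plot.

    Returns ``(points, summary)``: one point per transcript per cell with
    positive gene total (usage, gene total as point weight, group), and a
    per-transcript per-group summary with the model-estimated mean usage
    (inverse-logit of the fitted group linear predictor, i.e. the gene-
    total-weighted estimate), the raw mean usage, and the group's
    mean/median gene expression.  The weighted estimate and the raw mean
    diverge when low-total cells sit at extreme usages, which is exactly
    the case the weighting is designed to discount.
    """
    gmask = q.gene_of.to_numpy() == gene_id
    if not gmask.any():
        raise KeyError(f"unknown gene: {gene_id}")
    txs = q.values.index[gmask]
    U = usage(q).loc[txs]
    totals = gene_totals(q).loc[gene_id]
    fit_of = {f.transcript_id: f for f in fits}

    points = []
    for tx in txs:
        for cell in q.sample_ids:
            tot = totals[cell]
            if tot <= 0:
                continue
            points.append(
                {
                    "transcript_id": tx,
                    "cell": cell,
                    "group": str(groups[cell]),
                    "usage": U.loc[tx, cell],
                    "gene_total": float(tot),
                }
            )
    points_df = pd.DataFrame(points)

    summary = []
    for tx in txs:
        fit = fit_of.get(str(tx))
        for grp in sorted(pd.unique(groups.astype(str))):
            cells = groups.index[groups.astype(str) == grp]
            cmask = q.sample_ids.isin(cells)
            pos = totals[cells] > 0
            raw_mean = float(U.loc[tx, cells[pos]].mean()) if pos.any() else np.nan
            if fit is not None and fit.fitted_pi is not None:
                fitted = fit.fitted_pi[cmask.nonzero()[0]]
                fitted = fitted[np.isfinite(fitted)]
                model_mean = float(fitted.mean()) if fitted.size else np.nan
            else:
                model_mean = np.nan
            summary.append(
                {
                    "transcript_id": tx,
                    "group": grp,
                    "model_mean_usage": model_mean,
                    "raw_mean_usage": raw_mean,
                    "mean_gene_total": float(totals[cells].mean()),
                    "median_gene_total": float(totals[cells].median()),
                }
            )
    return points_df, pd.DataFrame(summary)


def run_benchmark(
    params: SyntheticParams,
    alpha: float = 0.05,
    filter_strategy: str = "edger",
    filter_preset: str = "single_cell",
    null_mode: str = "empirical",
) -> dict:
    """Simulate -> filter -> fit -> moderate -> test -> evaluate.

    Returns the result table, truth, confusion at ``alpha`` and the curve.
    """
    q, groups, truths = simulate_dataset(params)
    if filter_strategy == "edger":
        keep = filter_edger_style(q, groups, preset=filter_preset)
    elif filter_strategy == "drimseq":
        keep = filter_drimseq_style(q, groups)
    else:
        raise ValueError(f"unknown filter strategy {filter_strategy!r}")
    qf = q.subset_transcripts(keep)
    design = design_from_groups(groups)
    fits = fit_all(qf, design)
    tables = inference.test_dtu(fits, design, null_mode=null_mode)
    name, table = next(iter(tables.items()))
    conf = confusion(table, truths, alpha=alpha)
    curve = fdr_tpr_curve(table, truths)
    return {
        "contrast": name,
        "results": table,
        "truth": truths,
        "confusion": conf,
        "curve": curve,
        "n_filtered": len(keep),
        "groups": groups,
        "quantification": qf,
        "fits": fits,
    }


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """File-level pipeline driver used by the CLI ``run`` subcommand.

    ``config`` keys: either ``simulate_*`` generator settings or
    ``values``/``tx2gene``/``samples`` input paths; plus ``group_column``,
    ``filter`` (edger|drimseq), ``preset`` (bulk|single_cell), ``null_mode``,
    ``alpha``, ``seed``.  Writes per-contrast result TSVs (and, when truth
    is available, confusion and curve TSVs) into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alpha = float(config.get("alpha", 0.05))
    null_mode = config.get("null_mode", "empirical")
    truths: list[SwapTruth] = []

    if config.get("simulate", False):
        params = SyntheticParams(
            n_genes=int(config.get("n_genes", 3000)),
            tx_per_gene=(int(config.get("tx_min", 2)), int(config.get("tx_max", 5))),
            n_per_group=int(config.get("n_per_group", 20)),
            dtu_fraction=float(config.get("dtu_fraction", 0.15)),
            seed=int(config.get("seed", 0)),
        )
        q, groups, truths = simulate_dataset(params)
    else:
        q = load_quantification(config["values"], config["tx2gene"], config["samples"])
        groups = q.sample_table[config.get("group_column", "group")]

    strategy = config.get("filter", "edger")
    if strategy == "edger":
        keep = filter_edger_style(q, groups, preset=config.get("preset", "bulk"))
    elif strategy == "drimseq":
        keep = filter_drimseq_style(q, groups)
    else:
        raise ValueError(f"unknown filter strategy {strategy!r}")
    qf = q.subset_transcripts(keep)
    design = design_from_groups(groups)
    fits = fit_all(qf, design)
    tables = inference.test_dtu(fits, design, null_mode=null_mode)

    written = {}
    for name, table in tables.items():
        path = out_dir / f"results_{name}.tsv"
        inference.write_results(table, str(path))
        written[name] = path
        logger.info(
            "contrast %s: mu*=%.4f sigma*=%.4f d0=%.3f s0^2=%.4f",
            name,
            table.attrs["mu_star"],
            table.attrs["sigma_star"],
            table.attrs["d0"],
            table.attrs["s0_sq"],
        )
        if truths:
            conf = confusion(table, truths, alpha=alpha)
            curve = fdr_tpr_curve(table, truths)
            curve.to_csv(out_dir / f"curve_{name}.tsv", sep="\t", index=False)
            pd.DataFrame(
                [{"TP": conf.TP, "FP": conf.FP, "TN": conf.TN, "FN": conf.FN,
                  "TPR": conf.tpr, "FDP": conf.fdp, "alpha": alpha}]
            ).to_csv(out_dir / f"confusion_{name}.tsv", sep="\t", index=False)
    if truths:
        truth_table(truths).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return {"tables": tables, "truth": truths, "written": written}
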