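"""Triplicate aggregation, two-tailed percentile hit calling, robustness.

Per gene, the log2 fold-change is taken within each replicate and then
averaged across replicates (the geometric-mean convention on the linear
scale). Hits are the extreme ``tail_fraction`` of genes in each tail of
the mean mCherry log2 fold-change distribution — 2.5% up and 2.5% down by
default, so 5% of assessed genes in all, with floor rounding of the tail
size. Replicate robustness is summarised by the standard deviation of the
linear fold-changes, expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, SizingError
from .synth_screen import ROLE_SAMPLE

SCORE_COLUMNS = [
    "gene_id", "n_replicates_used",
    "mcherry_log2fc_mean", "mcherry_log2fc_sd",
    "yfp_log2fc_mean", "yfp_log2fc_sd",
    "fc_sd_pct", "hit", "direction",
]


@dataclass
class HitCallingParams:
    tail_fraction: float = 0.025
    channel: str = "mcherry"
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.tail_fraction < 0.5:
            raise InputError(
                f"tail_fraction must be in (0, 0.5), got {self.tail_fraction}")
        if self.channel not in ("mcherry", "yfp"):
            raise InputError(f"unknown channel {self.channel!r}")
        if self.min_replicates < 1:
            raise InputError("min_replicates must be >= 1")


def aggregate_replicates(
    wells: pd.DataFrame,
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse included sample wells into one score per gene.

    Returns ``(scores, dropped)``. Per gene: mean and unbiased SD of the
    per-replicate log2 fold-changes on each channel, plus ``fc_sd_pct`` —
    the SD of the *linear* mCherry fold-changes times 100, the replicate
    robustness metric. Genes with fewer than ``min_replicates`` included
    replicates go to ``dropped`` (gene_id, n_replicates_used) instead of
    raising.
    """
    for col in ("mcherry_fc", "yfp_fc"):
        if col not in wells.columns:
            raise InputError(f"wells table lacks {col!r}; run normalization")
    samples = wells[(wells["role"] == ROLE_SAMPLE) & wells["included"]].copy()
    samples["_l2m"] = np.log2(samples["mcherry_fc"].to_numpy())
    samples["_l2y"] = np.log2(samples["yfp_fc"].to_numpy())

    grouped = samples.groupby("sirna_id", sort=True)
    agg = grouped.agg(
        n_replicates_used=("_l2m", "size"),
        mcherry_log2fc_mean=("_l2m", "mean"),
        mcherry_log2fc_sd=("_l2m", "std"),   # pandas std is ddof=1
        yfp_log2fc_mean=("_l2y", "mean"),
        yfp_log2fc_sd=("_l2y", "std"),
        fc_sd_pct=("mcherry_fc", "std"),
    ).reset_index(names="gene_id")
    agg["fc_sd_pct"] = agg["fc_sd_pct"] * 100.0
    single = agg["n_replicates_used"] == 1
    agg.loc[single, ["mcherry_log2fc_sd", "yfp_log2fc_sd", "fc_sd_pct"]] = 0.0

    kept = agg[agg["n_replicates_used"] >= min_replicates].copy()
    kept["hit"] = False
    kept["direction"] = "none"
    scores = kept[SCORE_COLUMNS].reset_index(drop=True)

    # the dropped report also covers genes filtered out entirely
    counts = dict(zip(agg["gene_id"], agg["n_replicates_used"]))
    all_genes = set(wells.loc[wells["role"] == ROLE_SAMPLE, "sirna_id"])
    scored = set(scores["gene_id"])
    dropped = sorted((g, int(counts.get(g, 0)))
                     for g in all_genes - scored)
    dropped_df = pd.DataFrame(
        dropped, columns=["gene_id", "n_replicates_used"])
    return scores, dropped_df


def fc_sd_pct(linear_fcs: np.ndarray) -> float:
    """Unbiased SD of linear fold-changes, in percent."""
    fcs = np.asarray(linear_fcs, dtype=np.float64)
    if fcs.size < 2:
        return 0.0
    return float(fcs.std(ddof=1) * 100.0)


def call_hits(
    scores: pd.DataFrame,
    params: HitCallingParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag the two-tailed extreme fraction of genes as hits.

    Genes are ranked by the mean log2 fold-change on ``params.channel``;
    the ``floor(tail_fraction * N)`` lowest are flagged ``down`` and the
    same number highest ``up``. Ties are broken by lexicographic gene id,
    so the hit set is deterministic. Returns ``(scores with flags,
    hit table sorted by score)``.
    """
    params = params or HitCallingParams()
    n = len(scores)
    k = int(np.floor(params.tail_fraction * n))
    if k < 1:
        raise SizingError(
            f"{n} genes at tail_fraction {params.tail_fraction} yields an "
            "empty tail; need at least 1/tail_fraction genes")

    col = f"{params.channel}_log2fc_mean"
    out = scores.copy()
    order = out.sort_values(
        [col, "gene_id"], ascending=[True, True], kind="mergesort")
    down_ids = order["gene_id"].iloc[:k]
    up_ids = order["gene_id"].iloc[-k:]
    out["hit"] = out["gene_id"].isin(set(down_ids) | set(up_ids))
    out["direction"] = "none"
    out.loc[out["gene_id"].isin(set(down_ids)), "direction"] = "down"
    out.loc[out["gene_id"].isin(set(up_ids)), "direction"] = "up"
    hit_table = (out[out["hit"]]
                 .sort_values([col, "gene_id"], ascending=[True, True],
                              kind="mergesort")
                 .reset_index(drop=True))
    return out, hit_table


def robustness_report(
    scores: pd.DataFrame,
    sd_threshold_pct: float = 25.0,
) -> dict:
    """Descriptive replicate-robustness summary.

    Mean and SD of ``fc_sd_pct`` over all genes and over hits, plus the
    count of genes whose replicate SD exceeds ``sd_threshold_pct`` percent
    in each set.
    """
    hits = scores[scores["hit"]]
    def _mean(s): return float(s.mean()) if len(s) else float("nan")
    def _sd(s): return float(s.std(ddof=1)) if len(s) > 1 else float("nan")
    return {
        "n_genes": int(len(scores)),
        "n_hits": int(len(hits)),
        "fc_sd_pct_mean": _mean(scores["fc_sd_pct"]),
        "fc_sd_pct_sd": _sd(scores["fc_sd_pct"]),
        "fc_sd_pct_mean_hits": _mean(hits["fc_sd_pct"]),
        "fc_sd_pct_sd_hits": _sd(hits["fc_sd_pct"]),
        "n_above_threshold": int((scores["fc_sd_pct"] > sd_threshold_pct).sum()),
        "n_above_threshold_hits": int((hits["fc_sd_pct"] > sd_threshold_pct).sum()),
        "sd_threshold_pct": float(sd_threshold_pct),
    }
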