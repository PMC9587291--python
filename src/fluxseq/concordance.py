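"""Cross-time-point combination and cross-experiment ranking of DE genes.

A gene enters an experiment's combined list only if it is significant in
the same direction at both post-baseline time points; its effect size is
the mean log2FC over the two and its ranking statistic the larger
(worse) of the two adjusted p-values. Across experiments, genes are
ranked by the maximum-FDR rule: the largest adjusted p-value over the
selected experiments, ascending, with directionally discordant genes
excluded and optional opposite-direction requirements on the remaining
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .diffexpr import DEResult


@dataclass
class ConcordantDE:
    """Combined two-time-point DE list for one (cell line, treatment)."""

    cell_line: str
    treatment: str
    table: pd.DataFrame  # index gene_id; mean_log2FC, max_p_fdr, direction

    @property
    def experiment(self) -> tuple[str, str]:
        return (self.cell_line, self.treatment)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def genes_with_direction(self, direction: str) -> frozenset[str]:
        return frozenset(self.table.index[self.table.direction == direction])


def combine_timepoints(de_a: DEResult, de_b: DEResult, alpha: float = 0.05) -> ConcordantDE:
    """Keep genes significant (p_fdr < alpha) in the same direction at both
    time points; report mean log2FC and the max of the two p_fdr."""
    if (de_a.cell_line, de_a.treatment) != (de_b.cell_line, de_b.treatment):
        raise ValidationError("time points belong to different experiments")
    if set(de_a.table.index) != set(de_b.table.index):
        raise ValidationError("gene universes differ between time points")
    a = de_a.table
    b = de_b.table.reindex(a.index)
    sig = (a.p_fdr < alpha) & (b.p_fdr < alpha)
    same_dir = np.sign(a.log2FC) == np.sign(b.log2FC)
    nonzero = (a.log2FC != 0) & (b.log2FC != 0)
    keep = sig & same_dir & nonzero
    mean_fc = (a.log2FC[keep] + b.log2FC[keep]) / 2.0
    out = pd.DataFrame(
        {
            "mean_log2FC": mean_fc,
            "max_p_fdr": np.maximum(a.p_fdr[keep], b.p_fdr[keep]),
            "direction": np.where(mean_fc > 0, "up", "down"),
        }
    )
    out.index.name = "gene_id"
    return ConcordantDE(de_a.cell_line, de_a.treatment, out)


@dataclass
class OverlapReport:
    """Named gene sets with the counts/percentages that summarise them."""

    mode: str
    sets: dict[str, frozenset[str]]
    table: pd.DataFrame  # category, count, denominator, percent


def _pct(a: int, b: int) -> float:
    from .reporting import percentage_of

    return percentage_of(a, b)


def tally_overlaps(experiments: list[ConcordantDE], mode: str = "by_treatment") -> OverlapReport:
    """Overview tallies of DE genes across experiments.

    by_treatment: per treatment, genes DE in >= 1 cell line vs in every
    cell line. by_direction: up/down-regulated genes in >= 1 experiment
    (genes significantly up in one experiment and down in another are
    excluded first) and the share appearing in both treatments.
    """
    if len(experiments) < 2:
        raise ValidationError("tally_overlaps needs >= 2 experiments")
    if mode not in ("by_treatment", "by_direction"):
        raise ValidationError(f"unknown tally mode {mode!r}")
    rows = []
    sets: dict[str, frozenset[str]] = {}
    if mode == "by_treatment":
        treatments = sorted({e.treatment for e in experiments})
        for trt in treatments:
            group = [e.genes for e in experiments if e.treatment == trt]
            union = frozenset().union(*group)
            inter = group[0]
            for s in group[1:]:
                inter &= s
            sets[f"de_ge1_{trt}"] = union
            sets[f"de_all_{trt}"] = frozenset(inter)
            rows.append((f"de_ge1_{trt}", len(union), len(union), 100.0))
            rows.append((f"de_all_{trt}", len(inter), len(union), _pct(len(inter), len(union))))
    else:
        up_any = frozenset().union(*(e.genes_with_direction("up") for e in experiments))
        down_any = frozenset().union(*(e.genes_with_direction("down") for e in experiments))
        inconsistent = up_any & down_any
        up_any -= inconsistent
        down_any -= inconsistent
        treatments = sorted({e.treatment for e in experiments})
        for direction, universe in (("up", up_any), ("down", down_any)):
            per_trt = [
                frozenset().union(
                    *(e.genes_with_direction(direction) for e in experiments if e.treatment == t),
                )
                - inconsistent
                for t in treatments
            ]
            shared = per_trt[0]
            for s in per_trt[1:]:
                shared &= s
            sets[f"{direction}_ge1"] = universe
            sets[f"{direction}_shared_treatments"] = frozenset(shared)
            rows.append((f"{direction}_ge1", len(universe), len(universe), 100.0))
            rows.append(
                (f"{direction}_shared_treatments", len(shared), len(universe),
                 _pct(len(shared), len(universe)))
            )
        sets["direction_inconsistent"] = inconsistent
        rows.append(("direction_inconsistent", len(inconsistent), len(inconsistent), 100.0))
    table = pd.DataFrame(rows, columns=["category", "count", "denominator", "percent"])
    return OverlapReport(mode, sets, table)


def rank_max_fdr(
    selected: list[ConcordantDE],
    complementary: list[ConcordantDE] | None = None,
    top_n: int = 25,
) -> pd.DataFrame:
    """Rank genes by the maximum adjusted p-value across ``selected``.

    A gene is rankable only if present, with the same direction, in every
    selected experiment. If ``complementary`` is given, the mean log2FC
    over those experiments (missing entries set to 0) must point in the
    opposite direction; a zero mean is not opposite and excludes the gene.
    Ties in max p_fdr break lexicographically by gene_id.
    """
    if not selected:
        raise ValidationError("no experiments selected for ranking")
    common: frozenset[str] = selected[0].genes
    for e in selected[1:]:
        common &= e.genes
    records = []
    for gene in common:
        dirs = {e.table.direction[gene] for e in selected}
        if len(dirs) != 1:
            continue
        direction = dirs.pop()
        max_fdr = max(float(e.table.max_p_fdr[gene]) for e in selected)
        mean_sel = float(np.mean([e.table.mean_log2FC[gene] for e in selected]))
        if complementary is not None:
            comp = [
                float(e.table.mean_log2FC[gene]) if gene in e.table.index else 0.0
                for e in complementary
            ]
            comp_mean = float(np.mean(comp)) if comp else 0.0
            opposite = (direction == "up" and comp_mean < 0) or (
                direction == "down" and comp_mean > 0
            )
            if not opposite:
                continue
        rec = {"gene_id": gene, "max_p_fdr": max_fdr,
               "mean_log2FC": mean_sel, "direction": direction}
        for e in selected:
            rec[f"log2FC_{e.cell_line}_{e.treatment}"] = float(e.table.mean_log2FC[gene])
        records.append(rec)
    if not records:
        cols = ["gene_id", "max_p_fdr", "mean_log2FC", "direction"]
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame.from_records(records)
    out = out.sort_values(["max_p_fdr", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out.head(top_n)
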