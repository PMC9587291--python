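"""Transcription-factor-target / pathway crosstalk scoring.

A TFT set lists genes sharing a transcription factor's binding motif but
carries no interaction structure. To ask whether the factor's targets
can perturb a pathway, each pathway topology is restricted to the genes
it shares with the TFT set (induced subgraph: edges survive only if both
endpoints are retained; paths through removed genes are not contracted),
and the perturbation score with its permutation null is computed on that
subgraph. Pairs are aggregated across experiments either by requiring a
significant, direction-concordant signal everywhere, or by requiring it
in a named experiment subset and nowhere else.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError
from .diffexpr import adjust_bh
from .perturbation import score_pathway
from .types import GeneSetCollection, PathwayTopology

log = logging.getLogger(__name__)


def intersect_subgraph(pathway: PathwayTopology, tft_set: frozenset[str] | set[str]) -> PathwayTopology:
    """Induced subgraph of the pathway on its intersection with the TFT set."""
    return pathway.induced_subgraph(set(tft_set), name=pathway.name)


def crosstalk_test(
    subgraph: PathwayTopology,
    concordant,
    universe: frozenset[str] | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    damping: float | None = None,
) -> dict:
    """Perturbation contract applied to a pathway x TFT subgraph."""
    return score_pathway(
        subgraph,
        concordant.table["mean_log2FC"],
        universe=universe,
        n_perm=n_perm,
        seed=seed,
        damping=damping,
    )


def run_crosstalk(
    pathways: list[PathwayTopology],
    tft_sets: GeneSetCollection,
    concordant,
    universe: frozenset[str] | list[str] | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    damping: float | None = None,
) -> pd.DataFrame:
    """Score every (TFT set, pathway) pair for one experiment.

    Pairs with an empty intersection or no DE evidence on the subgraph
    are skipped with a log entry. BH FDR is taken over all scored pairs
    within the experiment. Per-pair seeds derive deterministically from
    ``seed``.
    """
    universe = frozenset(universe) if universe is not None else None
    rows = []
    n_pairs = len(pathways) * len(tft_sets)
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(n_pairs, 1)))
    for tft_name in tft_sets.names():
        members = tft_sets.members(tft_name)
        for pw in pathways:
            pair_seed = next(seeds)
            sub = intersect_subgraph(pw, members)
            if len(sub) == 0:
                log.info("pair (%s, %s) skipped: empty intersection", tft_name, pw.name)
                continue
            try:
                res = crosstalk_test(
                    sub, concordant, universe=universe,
                    n_perm=n_perm, seed=pair_seed, damping=damping,
                )
            except ValidationError:
                log.info("pair (%s, %s) skipped: no DE evidence", tft_name, pw.name)
                continue
            except NumericalError as exc:
                log.warning("pair (%s, %s) skipped: %s", tft_name, pw.name, exc)
                continue
            rows.append(
                {"tft": tft_name, "pathway": pw.name, "n_shared": len(sub), **res}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = adjust_bh(out["p_perm"].to_numpy())
    else:
        out = pd.DataFrame(
            columns=["tft", "pathway", "n_shared", "tA", "z", "p_perm",
                     "n_de_in_pathway", "n_perm", "seed", "p_fdr"]
        )
    return out


def aggregate_pairs(
    results: dict[tuple[str, str], pd.DataFrame],
    rule: str = "all_experiments",
    subset: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-experiment aggregation of (TFT, pathway) pairs.

    all_experiments: a pair is retained iff significant (p_fdr < alpha)
    with sign-concordant z in every experiment. subset_only: significant
    and concordant in every ``subset`` experiment AND not significant in
    any other experiment.
    """
    if rule not in ("all_experiments", "subset_only"):
        raise ValidationError(f"unknown aggregation rule {rule!r}")
    if rule == "subset_only":
        if not subset:
            raise ValidationError("subset_only rule requires a non-empty subset")
        missing = [e for e in subset if e not in results]
        if missing:
            raise ValidationError(f"subset experiments {missing} not in results")
    pairs: set[tuple[str, str]] = set()
    for df in results.values():
        pairs |= set(zip(df["tft"], df["pathway"]))
    required = list(results) if rule == "all_experiments" else list(subset)
    rows = []
    for tft, pw in sorted(pairs):
        stats = {}
        for exp, df in results.items():
            hit = df[(df["tft"] == tft) & (df["pathway"] == pw)]
            if not hit.empty:
                stats[exp] = (float(hit["z"].iloc[0]), float(hit["p_fdr"].iloc[0]))
        if any(exp not in stats for exp in required):
            continue
        req_z = [stats[exp][0] for exp in required]
        req_sig = all(stats[exp][1] < alpha for exp in required)
        concordant = all(z > 0 for z in req_z) or all(z < 0 for z in req_z)
        if not (req_sig and concordant):
            continue
        if rule == "subset_only":
            others = [e for e in stats if e not in required]
            if any(stats[e][1] < alpha for e in others):
                continue
        rec = {"tft": tft, "pathway": pw,
               "direction": "up" if req_z[0] > 0 else "down"}
        for (line, trt), (z, fdr) in stats.items():
            rec[f"z_{line}_{trt}"] = z
            rec[f"p_fdr_{line}_{trt}"] = fdr
        rows.append(rec)
    return pd.DataFrame(rows)
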