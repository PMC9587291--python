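"""Signed-topology pathway perturbation scoring with a permutation null.

Following the signaling-pathway-impact-analysis (SPIA) model, a pathway
is a signed directed graph whose influence matrix B carries
B[i, j] = sign(j -> i) / outdegree(j): each gene splits its activating
(+1) or inhibitory (-1) influence equally among its downstream targets.
Given per-gene evidence dE (the combined log2 fold change of DE genes,
zero elsewhere), the perturbation factor of each gene solves the linear
fixed point PF = dE + B PF, the accumulated perturbation is
Acc = PF - dE, and the pathway score tA = sum(Acc). A positive (negative)
tA predicts increased (decreased) pathway activity.

Significance comes from a permutation null: each draw reassigns the m
observed nonzero dE values, in shuffled order, to m nodes sampled
uniformly without replacement from the pathway's nodes, and recomputes
tA. The two-sided permutation p-value uses the add-one pseudocount; the
normalized score z is (tA - null mean) / null SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NumericalError, ValidationError
from .diffexpr import adjust_bh
from .types import PathwayTopology

log = logging.getLogger(__name__)

COND_LIMIT = 1e12


def normalize_topology(topology: PathwayTopology) -> tuple[np.ndarray, list[str]]:
    """Influence matrix B with B[i, j] = sign(j->i) / outdegree(j).

    Columns of |B| sum to 1 for nodes with outgoing edges and to 0
    otherwise. Returns (B, node order).
    """
    nodes = list(topology.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    B = np.zeros((len(nodes), len(nodes)))
    outdeg = topology.outdegree
    for src, tgt, sign in topology.edges:
        B[index[tgt], index[src]] = sign / outdeg[src]
    return B, nodes


def accumulate_perturbation(
    B: np.ndarray,
    delta_e: np.ndarray,
    damping: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the propagation system; returns (PF, Acc, tA).

    Raises NumericalError for an ill-conditioned I - B (unresolvable
    feedback loop, e.g. a pure activating 2-cycle); passing ``damping``
    (lambda < 1, applied as B <- lambda * B) is a logged fallback that
    restores solvability.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    if B.shape[0] != B.shape[1] or B.shape[0] != delta_e.shape[0]:
        raise ValidationError("influence matrix and evidence vector shapes disagree")
    if damping is not None:
        if not 0.0 < damping < 1.0:
            raise ValidationError("damping must lie in (0, 1)")
        log.info("applying damping factor %.3g to influence matrix", damping)
        B = damping * B
    if B.size == 0:
        return delta_e.copy(), np.zeros_like(delta_e), 0.0
    A = np.eye(B.shape[0]) - B
    if np.linalg.cond(A) > COND_LIMIT:
        raise NumericalError(
            "unresolvable feedback: I - B is singular or ill-conditioned; "
            "consider a damping factor < 1"
        )
    pf = np.linalg.solve(A, delta_e)
    acc = pf - delta_e
    return pf, acc, float(acc.sum())


def influence_vector(B: np.ndarray, damping: float | None = None) -> np.ndarray:
    """Vector c with tA(dE) = c . dE, i.e. c = (I - B)^-T 1 - 1.

    tA is linear in the evidence, so permutation nulls only need this
    one solve per pathway.
    """
    if damping is not None:
        if not 0.0 < damping < 1.0:
            raise ValidationError("damping must lie in (0, 1)")
        B = damping * B
    if B.size == 0:
        return np.zeros(0)
    A = np.eye(B.shape[0]) - B
    if np.linalg.cond(A) > COND_LIMIT:
        raise NumericalError(
            "unresolvable feedback: I - B is singular or ill-conditioned; "
            "consider a damping factor < 1"
        )
    ones = np.ones(B.shape[0])
    return np.linalg.solve(A.T, ones) - ones


def permutation_null(
    topology: PathwayTopology,
    delta_e_obs: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    damping: float | None = None,
) -> np.ndarray:
    """Null sample of tA under random reassignment of the observed
    evidence values to pathway nodes (uniform, without replacement)."""
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    delta_e_obs = np.asarray(delta_e_obs, dtype=float)
    values = delta_e_obs[delta_e_obs != 0.0]
    m = values.size
    if m == 0:
        raise ValidationError("no DE evidence on this pathway: skip (score undefined)")
    B, _ = normalize_topology(topology)
    c = influence_vector(B, damping=damping)
    n = len(topology.nodes)
    rng = np.random.default_rng(seed)
    # rank of iid uniforms = uniform sample without replacement, vectorised
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
    shuffled = rng.permuted(np.broadcast_to(values, (n_perm, m)), axis=1)
    return np.einsum("ij,ij->i", np.take(c, order), shuffled)


def perturbation_significance(tA_obs: float, null_sample: np.ndarray) -> tuple[float, float]:
    """Normalized score and two-sided permutation p-value.

    p = (1 + #{|tA_null| >= |tA_obs|}) / (1 + n_perm);
    z = (tA_obs - mean(null)) / sd(null), NaN if the null is degenerate.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValidationError("empty null sample")
    n = null_sample.size
    p = (1.0 + np.count_nonzero(np.abs(null_sample) >= abs(tA_obs))) / (1.0 + n)
    sd = float(null_sample.std(ddof=1))
    if sd > 1e-12 * max(1.0, float(np.abs(null_sample).max())):
        z = (tA_obs - float(null_sample.mean())) / sd
    else:
        z = float("nan")
        log.warning("degenerate permutation null (SD = 0); z undefined")
    return z, float(p)


def score_pathway(
    topology: PathwayTopology,
    evidence: pd.Series,
    universe: frozenset[str] | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    damping: float | None = None,
) -> dict:
    """Score one pathway against per-gene log2FC evidence.

    ``evidence`` maps DE gene -> combined log2FC; nodes outside it (or
    outside the detectable ``universe``) carry zero evidence but remain
    in the topology so propagation is not truncated by assay dropout.
    """
    keep = set(evidence.index)
    if universe is not None:
        keep &= set(universe)
    delta_e = np.array(
        [float(evidence[n]) if n in keep else 0.0 for n in topology.nodes]
    )
    B, _ = normalize_topology(topology)
    c = influence_vector(B, damping=damping)
    tA = float(c @ delta_e)
    null = permutation_null(topology, delta_e, n_perm=n_perm, seed=seed, damping=damping)
    z, p = perturbation_significance(tA, null)
    return {
        "tA": tA,
        "z": z,
        "p_perm": p,
        "n_de_in_pathway": int(np.count_nonzero(delta_e)),
        "n_perm": n_perm,
        "seed": seed,
    }


def run_perturbation_collection(
    pathways: list[PathwayTopology],
    concordant,
    universe: frozenset[str] | list[str] | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    damping: float | None = None,
) -> pd.DataFrame:
    """Score every pathway against one experiment's combined DE list.

    Evidence is the mean log2FC of the experiment's DE genes (zero
    elsewhere); pathways with no DE evidence or with unresolvable
    feedback (no damping given) are skipped with a log entry. BH FDR is
    computed across the scored pathways. Per-pathway seeds derive
    deterministically from ``seed``.
    """
    evidence = concordant.table["mean_log2FC"]
    universe = frozenset(universe) if universe is not None else None
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(pathways))]
    for pw, pw_seed in zip(pathways, child_seeds):
        try:
            res = score_pathway(
                pw, evidence, universe=universe, n_perm=n_perm, seed=pw_seed, damping=damping
            )
        except ValidationError:
            log.info("pathway %s skipped: no DE evidence among its nodes", pw.name)
            continue
        except NumericalError as exc:
            log.warning("pathway %s skipped: %s", pw.name, exc)
            continue
        rows.append({"pathway": pw.name, "n_nodes": len(pw.nodes), **res})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = adjust_bh(out["p_perm"].to_numpy())
    else:
        out = pd.DataFrame(
            columns=["pathway", "n_nodes", "tA", "z", "p_perm",
                     "n_de_in_pathway", "n_perm", "seed", "p_fdr"]
        )
    return out


def consistency_filter(
    results: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
    min_significant: int = 3,
    concordant: bool = True,
) -> pd.DataFrame:
    """Cross-experiment aggregation of perturbation results.

    A pathway is retained iff it reaches p_fdr < alpha in at least
    ``min_significant`` experiments and (when ``concordant``) all its
    significant z-scores share one sign. Output: one row per retained
    pathway with per-experiment z and p_fdr columns.
    """
    if not results:
        raise ValidationError("no experiments supplied")
    names: set[str] = set()
    for df in results.values():
        names |= set(df["pathway"])
    rows = []
    for name in sorted(names):
        zs, sig_zs = {}, []
        for exp, df in results.items():
            hit = df[df["pathway"] == name]
            if hit.empty:
                continue
            z = float(hit["z"].iloc[0])
            fdr = float(hit["p_fdr"].iloc[0])
            zs[exp] = (z, fdr)
            if fdr < alpha:
                sig_zs.append(z)
        if len(sig_zs) < min_significant:
            continue
        if concordant and not (all(z > 0 for z in sig_zs) or all(z < 0 for z in sig_zs)):
            continue
        rec = {"pathway": name, "n_significant": len(sig_zs),
               "direction": "up" if sig_zs[0] > 0 else "down"}
        for (line, trt), (z, fdr) in zs.items():
            rec[f"z_{line}_{trt}"] = z
            rec[f"p_fdr_{line}_{trt}"] = fdr
        rows.append(rec)
    return pd.DataFrame(rows)
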