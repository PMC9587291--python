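"""Gene set over-representation analysis with gene-length bias correction.

Long genes accumulate more reads and therefore more power to be called
DE, which inflates naive hypergeometric set tests. The correction
estimates a probability weighting function (PWF) — a monotone fit of
P(DE) against gene length — and replaces the central hypergeometric null
with Wallenius' noncentral hypergeometric distribution whose odds
parameter is the mean PWF weight inside the set over the mean weight
outside. With flat weights (odds 1) the test reduces exactly to the
one-sided Fisher/hypergeometric tail.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression

from .errors import ValidationError
from .diffexpr import adjust_bh
from .types import GeneSetCollection

W_FLOOR = 1e-6


def fit_pwf(de_status: pd.Series, length_bp: pd.Series) -> pd.Series:
    """Monotone probability-of-DE weight per gene as a function of length.

    Isotonic (non-decreasing) regression of the 0/1 DE indicator on gene
    length, floored at 1e-6 and rescaled so the mean weight equals the
    observed DE fraction.
    """
    de_status = pd.Series(de_status).astype(float)
    length_bp = pd.Series(length_bp).reindex(de_status.index).astype(float)
    if length_bp.isna().any():
        raise ValidationError("length_bp missing for some genes in de_status")
    if not set(np.unique(de_status)) <= {0.0, 1.0}:
        raise ValidationError("de_status must be 0/1")
    n = len(de_status)
    n_de = de_status.sum()
    if n_de == 0:
        raise ValidationError("no DE genes: skip over-representation analysis")
    if length_bp.nunique() < 2:
        raise ValidationError("need >= 2 distinct gene lengths to fit a PWF")
    # bin-smooth before the monotone fit: raw isotonic on 0/1 responses
    # overfits the shortest/longest genes (steps pinned at 0 or 1)
    order = np.argsort(length_bp.to_numpy(), kind="mergesort")
    n_bins = int(np.clip(n // 50, 5, 40))
    bins = np.array_split(order, n_bins)
    frac = np.array([de_status.iloc[idx].mean() for idx in bins])
    sizes = np.array([len(idx) for idx in bins], dtype=float)
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(n_bins), frac, sample_weight=sizes)
    w = np.empty(n)
    for idx, val in zip(bins, fitted):
        w[idx] = val
    w = np.maximum(w, W_FLOOR)
    w = w * (n_de / n) / w.mean()
    w = np.maximum(w, W_FLOOR)
    return pd.Series(w, index=de_status.index, name="pwf")


def ora_test(
    set_members: frozenset[str] | set[str],
    de_genes: frozenset[str] | set[str],
    universe: list[str] | frozenset[str],
    pwf: pd.Series | None = None,
) -> float:
    """Upper-tail over-representation p-value for one gene set.

    P(X >= k_obs) where X follows Wallenius' noncentral hypergeometric
    law over drawing |DE| genes from the universe with odds
    mean(w inside set) / mean(w outside set). pwf = None means flat
    weights (plain hypergeometric).
    """
    universe = frozenset(universe)
    de = frozenset(de_genes) & universe
    if not de <= frozenset(de_genes):
        raise ValidationError("de_genes must lie within the universe")
    inset = frozenset(set_members) & universe
    if not inset:
        warnings.warn("gene set does not intersect the universe; p = 1")
        return 1.0
    N = len(universe)
    n_set = len(inset)
    n_de = len(de)
    k_obs = len(inset & de)
    if k_obs == 0:
        return 1.0
    if pwf is None:
        odds = 1.0
    else:
        w = pwf.reindex(list(universe))
        if w.isna().any():
            raise ValidationError("pwf missing weights for some universe genes")
        w_in = w.reindex(list(inset)).mean()
        outside = universe - inset
        w_out = w.reindex(list(outside)).mean() if outside else w_in
        odds = float(w_in / w_out)
    if n_set == N:
        return 1.0
    dist = nchypergeom_wallenius(N, n_set, n_de, odds)
    return float(min(max(dist.sf(k_obs - 1), 0.0), 1.0))


def run_ora_collection(
    collection: GeneSetCollection,
    de_genes: frozenset[str] | set[str],
    universe: list[str] | frozenset[str],
    pwf: pd.Series | None = None,
) -> pd.DataFrame:
    """One ORA row per gene set with BH FDR across the collection."""
    universe = frozenset(universe)
    de = frozenset(de_genes) & universe
    rows = []
    for name in collection.names():
        members = collection.members(name) & universe
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = ora_test(members, de, universe, pwf) if members else 1.0
        rows.append(
            {
                "set_name": name,
                "n_set": len(members),
                "n_de_in_set": len(members & de),
                "n_universe": len(universe),
                "n_de": len(de),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    return out
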