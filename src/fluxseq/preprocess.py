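"""Expression-level preprocessing.

Three stages: counts-per-million (CPM) scaling, a per-cell-line
detectability filter (strictly more than ``min_samples`` samples above a
strict CPM threshold), and a smooth GC/length normalisation offset that
stands in for full conditional-quantile normalisation: per sample, a
natural-cubic-spline regression of log2(CPM + 0.5) on GC fraction and
log10 gene length captures the systematic technical component, which
downstream GLMs subtract as an offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reporting import percentage_of
from .types import CountMatrix, GeneRecord


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: counts / library_size * 1e6, per sample."""
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValidationError("library sizes must be positive")
    return cm.counts / lib * 1e6


@dataclass
class DetectabilityReport:
    """Per-cell-line detectable gene sets with overlap tallies."""

    per_line: dict[str, frozenset[str]]

    @property
    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.per_line.values():
            out |= s
        return out

    @property
    def intersection(self) -> frozenset[str]:
        sets = list(self.per_line.values())
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out

    def summary(self) -> pd.DataFrame:
        """Counts and percentages (all-lines set as a share of the >=1-line set)."""
        n_union, n_inter = len(self.union), len(self.intersection)
        rows = [
            {"category": "detectable_ge1_line", "count": n_union, "percent": 100.0},
            {"category": "detectable_all_lines", "count": n_inter,
             "percent": percentage_of(n_inter, n_union)},
        ]
        for line, s in sorted(self.per_line.items()):
            rows.append({"category": f"detectable_{line}", "count": len(s),
                         "percent": percentage_of(len(s), n_union)})
        return pd.DataFrame(rows)


def detectability_filter(
    cm: CountMatrix,
    cpm_threshold: float = 1.5,
    min_samples: int = 3,
    cell_lines: list[str] | None = None,
) -> DetectabilityReport:
    """A gene is detectable for a cell line iff strictly more than
    ``min_samples`` of that line's samples exceed ``cpm_threshold`` CPM
    (both comparisons strict)."""
    if cpm_threshold <= 0 or min_samples <= 0:
        raise ValidationError("cpm_threshold and min_samples must be positive")
    table = cm.sample_table()
    lines = cell_lines if cell_lines is not None else sorted(table.cell_line.unique())
    if not lines:
        raise ValidationError("no cell lines in design")
    mat = cpm(cm)
    per_line: dict[str, frozenset[str]] = {}
    for line in lines:
        ids = table.index[table.cell_line == line]
        if len(ids) == 0:
            raise ValidationError(f"cell line {line!r} has no samples")
        n_above = (mat[list(ids)] > cpm_threshold).sum(axis=1)
        per_line[line] = frozenset(mat.index[n_above > min_samples])
    return DetectabilityReport(per_line)


def _natural_cubic_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form), ``df`` columns
    excluding the intercept, boundary/interior knots at quantiles."""
    knots = np.quantile(x, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    if len(knots) < 3:  # degenerate covariate: fall back to linear
        return x[:, None] - x.mean()
    xi_K, xi_Km1 = knots[-1], knots[-2]

    def d(xi):
        return (np.clip(x - xi, 0, None) ** 3 - np.clip(x - xi_K, 0, None) ** 3) / (xi_K - xi)

    cols = [x] + [d(k) - d(xi_Km1) for k in knots[:-2]]
    basis = np.column_stack(cols)
    return basis - basis.mean(axis=0)


def gc_length_offsets(
    cm: CountMatrix,
    genes: list[GeneRecord],
    spline_df: int = 5,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Per-sample systematic GC/length component of log2 CPM.

    For each sample, log2(CPM + pseudo) is regressed on natural cubic
    spline bases of GC fraction (``spline_df`` df) and log10 length
    (``spline_df`` df); the fitted values, centred to median zero across
    genes, are returned as a genes x samples offset matrix on the log2
    scale. Subtract from log2 CPM (or pass to the GLM as an offset) to
    remove the technical trend.
    """
    meta = {g.gene_id: g for g in genes}
    missing = [g for g in cm.genes if g not in meta]
    if missing:
        raise ValidationError(f"gene metadata missing for {missing[:3]}{'...' if len(missing) > 3 else ''}")
    gc = np.array([meta[g].gc_fraction for g in cm.genes])
    loglen = np.log10([meta[g].length_bp for g in cm.genes])
    X = np.column_stack([
        np.ones(len(cm.genes)),
        _natural_cubic_basis(gc, spline_df),
        _natural_cubic_basis(loglen, spline_df),
    ])
    if X.shape[0] <= X.shape[1]:
        raise ValidationError(
            f"{X.shape[0]} genes is too few for a {X.shape[1]}-parameter spline fit"
        )
    y = np.log2(cpm(cm).to_numpy() + pseudo)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    fitted = fitted - np.median(fitted, axis=0, keepdims=True)
    return pd.DataFrame(fitted, index=cm.genes, columns=cm.sample_ids)
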