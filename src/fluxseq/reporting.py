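"""Tabular study-overview reporting.

Every number in a report is recomputed from the underlying gene sets at
call time; percentages are shares rounded half-even to one decimal, the
convention used throughout the result tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal

import math

import pandas as pd

from .errors import ValidationError


def percentage_of(part: int, whole: int) -> float:
    """100 * part / whole, rounded half-even to one decimal.

    Exact decimal arithmetic, so printed percentages reproduce integer
    tallies deterministically. whole = 0 yields NaN (reported as NA).
    """
    if part < 0 or whole < 0:
        raise ValidationError("percentage_of expects non-negative counts")
    if whole == 0:
        return math.nan
    q = (Decimal(100) * Decimal(part) / Decimal(whole)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_EVEN
    )
    return float(q)


def report_tallies(detectability, concordant: list) -> pd.DataFrame:
    """Overview table: detectable genes per cell line coverage, DE genes
    per treatment (>=1 vs all cell lines), and up/down tallies shared
    between treatments (direction-inconsistent genes excluded)."""
    from .concordance import tally_overlaps

    rows = []
    union, inter = detectability.union, detectability.intersection
    rows.append(("detectable_ge1_line", len(union), len(union), 100.0))
    rows.append(
        ("detectable_all_lines", len(inter), len(union), percentage_of(len(inter), len(union)))
    )
    frames = [pd.DataFrame(rows, columns=["category", "count", "denominator", "percent"])]
    if len(concordant) >= 2:
        frames.append(tally_overlaps(concordant, "by_treatment").table)
        if len({e.treatment for e in concordant}) >= 2:
            frames.append(tally_overlaps(concordant, "by_direction").table)
    return pd.concat(frames, ignore_index=True)
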