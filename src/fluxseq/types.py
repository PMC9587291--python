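"""Core in-memory containers shared across the pipeline.

Gene identifiers are opaque strings compared exactly (case-sensitive);
no annotation mapping happens anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CONTROL = "control"


@dataclass(frozen=True, order=True)
class SampleDescriptor:
    """One RNA-seq library: cell line x treatment x time (h) x replicate."""

    sample_id: str
    cell_line: str
    treatment: str
    time_h: float
    replicate: int

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"negative time for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1 for {self.sample_id!r}")


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene metadata used for bias modelling and length-aware ORA."""

    gene_id: str
    length_bp: int
    gc_fraction: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValidationError(f"gene {self.gene_id!r}: length_bp must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValidationError(f"gene {self.gene_id!r}: gc_fraction outside [0, 1]")


class CountMatrix:
    """Non-negative integer genes x samples matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one column per sample_id.
    samples
        Descriptors in column order.
    library_sizes
        Per-sample totals; defaults to column sums.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: list[SampleDescriptor],
        library_sizes: pd.Series | None = None,
    ) -> None:
        counts = counts.copy()
        if list(counts.columns) != [s.sample_id for s in samples]:
            raise ValidationError("count matrix columns do not match sample descriptors")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r} in count matrix")
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        else:
            library_sizes = pd.Series(library_sizes).reindex(counts.columns)
            if library_sizes.isna().any():
                raise ValidationError("library_sizes missing for some samples")
        if (library_sizes <= 0).any():
            bad = library_sizes.index[library_sizes <= 0][0]
            raise ValidationError(f"non-positive library size for sample {bad!r}")
        self.counts = counts
        self.samples = list(samples)
        self.library_sizes = library_sizes.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_table(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "cell_line": [s.cell_line for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "time_h": [s.time_h for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        ids = [s.sample_id for s in samples]
        return CountMatrix(self.counts[ids], samples, self.library_sizes[ids])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({len(self.genes)} genes x {len(self.samples)} samples)"


class GeneSetCollection:
    """Named gene sets (e.g. transcription-factor target sets) a la GMT."""

    def __init__(self, sets: dict[str, tuple[str, frozenset[str]]]) -> None:
        for name, (_, members) in sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        self.sets = dict(sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


_SIGN_TOKENS = {
    "+": 1, "+1": 1, "1": 1, "activation": 1,
    "-": -1, "-1": -1, "inhibition": -1,
}


def parse_sign(token: str) -> int:
    try:
        return _SIGN_TOKENS[token.strip()]
    except KeyError:
        raise ValidationError(f"unknown interaction sign token {token!r}") from None


@dataclass
class PathwayTopology:
    """Signed directed gene-gene interaction graph.

    Edges carry +1 (activation) or -1 (inhibition). The out-degree of a
    node is the number of its downstream targets and normalises its
    influence when the topology is converted to an influence matrix.
    """

    name: str
    nodes: tuple[str, ...]
    edges: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError(f"pathway {self.name!r}: duplicate nodes")
        seen: dict[tuple[str, str], int] = {}
        for src, tgt, sign in self.edges:
            if src not in node_set or tgt not in node_set:
                raise ValidationError(
                    f"pathway {self.name!r}: edge {src}->{tgt} endpoint not in node set"
                )
            if sign not in (-1, 1):
                raise ValidationError(f"pathway {self.name!r}: sign must be +1 or -1")
            if (src, tgt) in seen:
                raise ValidationError(
                    f"pathway {self.name!r}: duplicate edge {src}->{tgt}"
                    + (" with conflicting signs" if seen[(src, tgt)] != sign else "")
                )
            seen[(src, tgt)] = sign

    @property
    def outdegree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for src, _, _ in self.edges:
            deg[src] += 1
        return deg

    def induced_subgraph(self, keep: set[str], name: str | None = None) -> "PathwayTopology":
        """Subgraph on ``nodes & keep``; edges with either endpoint removed are dropped."""
        nodes = tuple(n for n in self.nodes if n in keep)
        node_set = set(nodes)
        edges = [(s, t, g) for s, t, g in self.edges if s in node_set and t in node_set]
        return PathwayTopology(name or self.name, nodes, edges)

    def __len__(self) -> int:
        return len(self.nodes)
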