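"""Readers and writers for every on-disk artifact.

All formats are plain text: counts and metadata as TSV, gene sets as GMT,
pathway topologies as signed SIF (``source <TAB> sign <TAB> target``),
simulation truth as JSON. Writers and readers round-trip bit-exactly on
generated data; readers validate strictly and report the offending
location.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .simulate import SimulationTruth
from .types import CountMatrix, GeneRecord, GeneSetCollection, PathwayTopology, SampleDescriptor, parse_sign

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample_id", "cell_line", "treatment", "time_h", "replicate"]
GENE_COLUMNS = ["gene_id", "length_bp", "gc_fraction"]


# ---------------------------------------------------------------- counts

def write_counts_tsv(cm: CountMatrix, counts_path: str | Path, sample_sheet_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.sample_table().to_csv(sample_sheet_path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str, "treatment": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    samples = [
        SampleDescriptor(r.sample_id, r.cell_line, r.treatment, float(r.time_h), int(r.replicate))
        for r in df.itertuples()
    ]
    keys = [(s.cell_line, s.treatment, s.time_h, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (cell_line, treatment, time_h, replicate)")
    return samples


def read_counts_tsv(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Load a genes x samples TSV, validated against its sample sheet."""
    samples = read_sample_sheet(sample_sheet_path)
    by_id = {s.sample_id: s for s in samples}
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise FormatError(f"{path}: samples {unknown} not in sample sheet")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: non-integer count at gene {gene!r}, sample {col!r}")
    return CountMatrix(df.astype("int64"), [by_id[c] for c in df.columns])


# ------------------------------------------------------------- gene metadata

def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "length_bp": [g.length_bp for g in genes],
         "gc_fraction": [repr(g.gc_fraction) for g in genes]}
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene table missing columns {missing}")
    if df.gene_id.duplicated().any():
        dup = df.gene_id[df.gene_id.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    return [GeneRecord(r.gene_id, int(r.length_bp), float(r.gc_fraction)) for r in df.itertuples()]


# -------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> GeneSetCollection:
    """MSigDB-style GMT: ``name <TAB> description <TAB> member...`` per line."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            unique = frozenset(members)
            if len(unique) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated")
            if not unique:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (desc, unique)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# -------------------------------------------------------------- signed SIF

def read_signed_sif(path: str | Path, name: str | None = None) -> PathwayTopology:
    """Signed interaction file: ``source <TAB> sign <TAB> target`` per line.

    Sign tokens: ``+ - +1 -1 activation inhibition``. A line with a single
    field declares an isolated node (standard SIF convention). An empty
    file is a valid empty topology.
    """
    edges: list[tuple[str, str, int]] = []
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    seen_edges: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                if fields[0] not in seen_nodes:
                    seen_nodes.add(fields[0])
                    nodes.append(fields[0])
                continue
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'source<TAB>sign<TAB>target'")
            src, token, tgt = fields
            try:
                sign = parse_sign(token)
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            key = (src, tgt)
            if key in seen_edges:
                detail = "conflicting signs" if seen_edges[key] != sign else "duplicate"
                raise FormatError(f"{path}:{lineno}: {detail} edge {src}->{tgt}")
            seen_edges[key] = sign
            for n in (src, tgt):
                if n not in seen_nodes:
                    seen_nodes.add(n)
                    nodes.append(n)
            edges.append((src, tgt, sign))
    return PathwayTopology(name or Path(path).stem, tuple(nodes), edges)


def write_signed_sif(topology: PathwayTopology, path: str | Path) -> None:
    connected = {n for s, t, _ in topology.edges for n in (s, t)}
    with open(path, "w") as fh:
        for src, tgt, sign in topology.edges:
            fh.write(f"{src}\t{'+' if sign > 0 else '-'}\t{tgt}\n")
        for node in topology.nodes:  # single-field lines keep isolated nodes
            if node not in connected:
                fh.write(f"{node}\n")


def write_pathway_dir(pathways: list[PathwayTopology], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pw in pathways:
        write_signed_sif(pw, directory / f"{pw.name}.sif")


def read_pathway_dir(directory: str | Path) -> list[PathwayTopology]:
    return [read_signed_sif(p) for p in sorted(Path(directory).glob("*.sif"))]


# -------------------------------------------------------------- truth JSON

def write_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    de: dict[str, dict[str, list[str]]] = {}
    for (line, trt), genes in truth.de_genes.items():
        de.setdefault(line, {})[trt] = sorted(genes)
    lfc: dict[str, dict[str, dict[str, float]]] = {}
    for (gene, line, trt), v in truth.true_log2fc.items():
        lfc.setdefault(line, {}).setdefault(trt, {})[gene] = v
    payload = {
        "de_genes": de,
        "true_log2fc": lfc,
        "dispersion": truth.dispersion,
        "baseline_mean": truth.baseline_mean,
        "bias_log2": truth.bias_log2,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        payload = json.load(fh)
    de = {
        (line, trt): frozenset(genes)
        for line, by_trt in payload["de_genes"].items()
        for trt, genes in by_trt.items()
    }
    lfc = {
        (gene, line, trt): float(v)
        for line, by_trt in payload["true_log2fc"].items()
        for trt, by_gene in by_trt.items()
        for gene, v in by_gene.items()
    }
    return SimulationTruth(
        de_genes=de,
        true_log2fc=lfc,
        dispersion={g: float(v) for g, v in payload["dispersion"].items()},
        baseline_mean={g: float(v) for g, v in payload["baseline_mean"].items()},
        bias_log2={g: float(v) for g, v in payload.get("bias_log2", {}).items()},
    )


# ------------------------------------------------------------ result tables

def write_results_tsv(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    """Result table writer: fixed column order, full double precision."""
    if columns is not None:
        df = df[columns]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
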