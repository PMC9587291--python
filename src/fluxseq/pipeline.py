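"""Config-driven end-to-end runs.

One call takes a study (simulated or loaded from disk) through
preprocessing, per-contrast differential expression, time-point
combination, overview tallies, length-aware over-representation,
topology perturbation and TFT crosstalk, writing every result table plus
a provenance manifest (package/library versions, seed, config hash,
output checksums) into a run directory. Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from . import io as fio
from .concordance import ConcordantDE, combine_timepoints
from .crosstalk import aggregate_pairs, run_crosstalk
from .diffexpr import estimate_dispersions, run_contrast
from .ora import fit_pwf, run_ora_collection
from .perturbation import consistency_filter, run_perturbation_collection
from .preprocess import detectability_filter, gc_length_offsets
from .reporting import report_tallies
from .simulate import (
    DEFAULT_CELL_LINES,
    DEFAULT_TIMES,
    DEFAULT_TREATMENTS,
    TruthConfig,
    generate_counts,
    generate_design,
    generate_genes,
    generate_pathways,
    generate_tft_sets,
)
from .types import CONTROL, GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; ``seed`` is mandatory (no silent nondeterminism)."""

    out_dir: str
    seed: int
    # input paths (all four set -> load mode; otherwise simulate)
    counts: str | None = None
    samples: str | None = None
    genes: str | None = None
    pathway_dir: str | None = None
    tft_gmt: str | None = None
    # simulation scale (used when no input paths are given)
    n_genes: int = 2000
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    times: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 3
    truth: TruthConfig = field(default_factory=TruthConfig)
    n_pathways: int = 50
    n_tft_sets: int = 30
    # analysis thresholds (defaults follow the study conventions)
    alpha: float = 0.05
    fc_threshold: float = 1.2
    cpm_threshold: float = 1.5
    min_samples: int = 3
    n_perm: int = 2000
    damping: float | None = None
    subset_experiments: tuple[tuple[str, str], ...] | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed must be set")
        for name in ("alpha", "fc_threshold", "cpm_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.min_samples < 1:
            raise ValidationError("min_samples must be >= 1")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        self.truth.validate()
        paths = [self.counts, self.samples]
        if any(p is not None for p in paths) and not all(p is not None for p in paths):
            raise ValidationError("counts and samples paths must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "truth" in raw and isinstance(raw["truth"], dict):
            truth = dict(raw["truth"])
            for key in ("log2fc_range", "dispersion_range", "mean_range"):
                if key in truth:
                    truth[key] = tuple(truth[key])
            raw["truth"] = TruthConfig(**truth)
        for key in ("cell_lines", "treatments", "times"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("subset_experiments"):
            raw["subset_experiments"] = tuple(tuple(e) for e in raw["subset_experiments"])
        return cls(**raw)

    def canonical_json(self) -> str:
        """Config as canonical JSON; out_dir is excluded so identical
        analyses into different directories hash (and rerun) identically."""
        d = asdict(self)
        d.pop("out_dir")
        return json.dumps(d, sort_keys=True, default=str)


def _seed_for(base: int, label: str) -> int:
    digest = hashlib.sha256(f"{base}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write(df: pd.DataFrame, path: Path) -> None:
    fio.write_results_tsv(df, path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis chain; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------------- inputs
    if config.counts is not None:
        for name in ("counts", "samples"):
            p = Path(getattr(config, name))
            if not p.exists():
                raise ValidationError(f"{name} path does not exist: {p}")
        cm = fio.read_counts_tsv(config.counts, config.samples)
        genes = fio.read_gene_table(config.genes) if config.genes else None
        pathways = fio.read_pathway_dir(config.pathway_dir) if config.pathway_dir else []
        tft = fio.read_gmt(config.tft_gmt) if config.tft_gmt else None
        truth = None
    else:
        log.info("simulating study: %d genes, %d pathways", config.n_genes, config.n_pathways)
        design = generate_design(
            list(config.cell_lines), list(config.treatments),
            list(config.times), config.replicates,
        )
        genes = generate_genes(config.n_genes, _seed_for(config.seed, "genes"))
        cm, truth = generate_counts(design, genes, config.truth, _seed_for(config.seed, "counts"))
        pathways = generate_pathways(
            genes, n_pathways=config.n_pathways, seed=_seed_for(config.seed, "pathways")
        )
        tft = generate_tft_sets(
            genes, pathways, n_sets=config.n_tft_sets, seed=_seed_for(config.seed, "tft")
        )
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        fio.write_counts_tsv(cm, inputs / "counts.tsv", inputs / "samples.tsv")
        fio.write_gene_table(genes, inputs / "genes.tsv")
        fio.write_truth_json(truth, inputs / "truth.json")
        fio.write_pathway_dir(pathways, inputs / "pathways")
        fio.write_gmt(tft, inputs / "tft.gmt")

    # ------------------------------------------------------------ preprocess
    report = detectability_filter(cm, config.cpm_threshold, config.min_samples)
    _write(report.summary(), out / "detectability.tsv")
    offsets = None
    if genes is not None:
        offsets = gc_length_offsets(cm, genes)
    gene_meta = {g.gene_id: g for g in genes} if genes is not None else None

    # ------------------------------------------------- DE and concordance
    table = cm.sample_table()
    lines = sorted(table.cell_line.unique())
    treatments = sorted(t for t in table.treatment.unique() if t != CONTROL)
    times = sorted(t for t in table.time_h.unique() if t > 0)
    if len(times) < 2:
        raise ValidationError("need >= 2 post-baseline time points to combine")

    dispersions = {}
    for line in lines:
        sub = cm.subset_samples(list(table.index[table.cell_line == line]))
        dispersions[line] = estimate_dispersions(sub, offsets=None)

    concordant: list[ConcordantDE] = []
    for line in lines:
        for trt in treatments:
            per_time = []
            for t in times:
                de = run_contrast(
                    cm, line, trt, t, dispersions[line],
                    offsets=offsets, fc_threshold=config.fc_threshold,
                )
                tab = de.table.reset_index()
                _write(tab, out / f"de_{line}_{trt}_{t:g}h.tsv")
                per_time.append(de)
            comb = combine_timepoints(per_time[0], per_time[1], alpha=config.alpha)
            _write(comb.table.reset_index(), out / f"concordant_{line}_{trt}.tsv")
            concordant.append(comb)

    # ----------------------------------------------------------- tallies
    _write(report_tallies(report, concordant), out / "report.tsv")

    # ----------------------------------------------- enrichment & topology
    pert_results: dict[tuple[str, str], pd.DataFrame] = {}
    cross_results: dict[tuple[str, str], pd.DataFrame] = {}
    for comb in concordant:
        exp = comb.experiment
        tag = f"{exp[0]}_{exp[1]}"
        universe = report.per_line[exp[0]]
        de_set = comb.genes & universe
        if tft is not None and gene_meta is not None and de_set:
            status = pd.Series(
                [1.0 if g in de_set else 0.0 for g in sorted(universe)],
                index=sorted(universe),
            )
            lengths = pd.Series(
                {g: gene_meta[g].length_bp for g in sorted(universe) if g in gene_meta}
            )
            try:
                pwf = fit_pwf(status, lengths)
            except ValidationError as exc:
                log.info("ORA skipped for %s: %s", tag, exc)
                pwf = None
            if pwf is not None:
                _write(
                    run_ora_collection(tft, de_set, universe, pwf),
                    out / f"ora_tft_{tag}.tsv",
                )
                if pathways:
                    pw_sets = GeneSetCollection(
                        {p.name: (f"pathway membership {p.name}", frozenset(p.nodes))
                         for p in pathways}
                    )
                    _write(
                        run_ora_collection(pw_sets, de_set, universe, pwf),
                        out / f"ora_pathways_{tag}.tsv",
                    )
        if pathways:
            pert = run_perturbation_collection(
                pathways, comb, universe=universe,
                n_perm=config.n_perm, seed=_seed_for(config.seed, f"pert:{tag}"),
                damping=config.damping,
            )
            _write(pert, out / f"perturbation_{tag}.tsv")
            pert_results[exp] = pert
        if pathways and tft is not None:
            cross = run_crosstalk(
                pathways, tft, comb, universe=universe,
                n_perm=config.n_perm, seed=_seed_for(config.seed, f"cross:{tag}"),
                damping=config.damping,
            )
            _write(cross, out / f"crosstalk_{tag}.tsv")
            cross_results[exp] = cross

    if pert_results:
        _write(
            consistency_filter(pert_results, alpha=config.alpha),
            out / "perturbation_consistent.tsv",
        )
    if cross_results:
        _write(
            aggregate_pairs(cross_results, "all_experiments", alpha=config.alpha),
            out / "crosstalk_all_experiments.tsv",
        )
        if config.subset_experiments:
            _write(
                aggregate_pairs(
                    cross_results, "subset_only",
                    subset=[tuple(e) for e in config.subset_experiments],
                    alpha=config.alpha,
                ),
                out / "crosstalk_subset_only.tsv",
            )

    # ----------------------------------------------------------- manifest
    checksums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "fluxseq_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "config": json.loads(config.canonical_json()),
        "outputs_sha256": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
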