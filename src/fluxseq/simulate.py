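"""Synthetic multi-condition RNA-seq study generator with known ground truth.

Emulates a time-course autophagy-induction design: three cell lines, two
treatments (amino-acid starvation, mTOR inhibition) plus an untreated
control arm, several time points and replicated libraries. Counts are
negative-binomially distributed with per-gene dispersion, designated
true-DE genes carry treatment-specific log2 fold changes applied at every
post-baseline time point (optionally made time-discordant), and a smooth
GC/length expression bias plus log-normal library-size factors give the
normalisation stages something real to remove.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import CONTROL, CountMatrix, GeneRecord, GeneSetCollection, PathwayTopology, SampleDescriptor

DEFAULT_CELL_LINES = ("HeLa", "HEK293", "SHSY5Y")
DEFAULT_TREATMENTS = (CONTROL, "starvation", "mtor_inhibition")
DEFAULT_TIMES = (0.0, 15.0, 30.0)
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class TruthConfig:
    """Knobs of the count generator.

    frac_de
        Fraction of genes that are truly DE per (cell line, treatment) arm.
    log2fc_range
        Magnitude range of true log2 fold changes; signs are random.
    dispersion_range
        NB dispersion phi drawn log-uniformly; Var = mu + phi * mu^2.
    mean_range
        Baseline expected counts drawn log-uniformly.
    bias_strength
        Amplitude (log2 units) of the smooth GC/length expression bias.
    libsize_sd
        SD of the log-normal per-sample library size factor.
    discordant_frac
        Fraction of DE genes whose effect flips sign at the last
        post-baseline time point (exercises the concordance filter).
    """

    frac_de: float = 0.1
    log2fc_range: tuple[float, float] = (0.5, 2.5)
    dispersion_range: tuple[float, float] = (0.05, 0.4)
    mean_range: tuple[float, float] = (10.0, 1000.0)
    bias_strength: float = 0.5
    libsize_sd: float = 0.2
    discordant_frac: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValidationError("frac_de must be in [0, 1]")
        if not 0.0 <= self.discordant_frac <= 1.0:
            raise ValidationError("discordant_frac must be in [0, 1]")
        for name in ("log2fc_range", "dispersion_range", "mean_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: lower bound exceeds upper bound")
        if self.dispersion_range[0] < 0:
            raise ValidationError("dispersions must be non-negative")
        if self.mean_range[0] <= 0:
            raise ValidationError("baseline means must be positive")
        if self.libsize_sd < 0:
            raise ValidationError("libsize_sd must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated count matrix."""

    de_genes: dict[tuple[str, str], frozenset[str]]
    true_log2fc: dict[tuple[str, str, str], float]  # (gene, cell_line, treatment)
    dispersion: dict[str, float]
    baseline_mean: dict[str, float]
    bias_log2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (gene, line, trt), fc in self.true_log2fc.items():
            if fc == 0.0 and gene in self.de_genes.get((line, trt), frozenset()):
                raise ValidationError(f"DE gene {gene!r} has zero true log2FC")
        for gene, phi in self.dispersion.items():
            if phi <= 0:
                raise ValidationError(f"gene {gene!r}: dispersion must be > 0")


def generate_design(
    cell_lines: list[str] = list(DEFAULT_CELL_LINES),
    treatments: list[str] = list(DEFAULT_TREATMENTS),
    times: list[float] = list(DEFAULT_TIMES),
    replicates: int = DEFAULT_REPLICATES,
) -> list[SampleDescriptor]:
    """Full-factorial sample sheet, deterministically ordered.

    ``treatments`` must include the control arm so every (cell line, time)
    stratum has untreated reference samples.
    """
    if not cell_lines or not treatments or not times:
        raise ValidationError("cell_lines, treatments and times must be non-empty")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if CONTROL not in treatments:
        raise ValidationError(f"treatments must include {CONTROL!r}")
    design = []
    for line, trt, t, rep in itertools.product(
        cell_lines, treatments, sorted(times), range(1, replicates + 1)
    ):
        sid = f"{line}_{trt}_{t:g}h_r{rep}"
        design.append(SampleDescriptor(sid, line, trt, float(t), rep))
    return design


def generate_genes(n_genes: int, seed: int) -> list[GeneRecord]:
    """Gene universe with log-uniform lengths in [200, 100000] bp and
    beta-distributed GC fractions squeezed into [0.3, 0.7]."""
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.uniform(np.log(200), np.log(100_000), n_genes))
    gc = 0.3 + 0.4 * rng.beta(4.0, 4.0, n_genes)
    width = len(str(n_genes))
    return [
        GeneRecord(f"G{i + 1:0{width}d}", int(round(l)), float(g))
        for i, (l, g) in enumerate(zip(lengths, gc))
    ]


def _bias_log2(genes: list[GeneRecord], strength: float) -> np.ndarray:
    """Smooth expression bias: quadratic in GC, log-linear in length, centred."""
    gc = np.array([g.gc_fraction for g in genes])
    loglen = np.log10([g.length_bp for g in genes])
    b = strength * (1.0 - 8.0 * (gc - 0.5) ** 2) + strength * 0.4 * (loglen - np.median(loglen))
    return b - b.mean()


def generate_counts(
    design: list[SampleDescriptor],
    genes: list[GeneRecord],
    config: TruthConfig = TruthConfig(),
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate NB counts for a design with planted DE effects.

    counts[g, s] ~ NB(mean, phi_g) with
    mean = baseline_g * 2^(log2FC if s treated & g DE) * 2^bias(GC, length) * sf_s
    and Var = mu + phi * mu^2. Treatment effects act at every time > 0;
    with ``discordant_frac`` > 0 a fraction of DE genes flips sign at the
    last time point.
    """
    if not design:
        raise ValidationError("design is empty")
    if not genes:
        raise ValidationError("gene list is empty")
    config.validate()
    rng = np.random.default_rng(seed)
    n_g, n_s = len(genes), len(design)
    gene_ids = [g.gene_id for g in genes]

    lo, hi = config.mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), n_g))
    d_lo, d_hi = config.dispersion_range
    d_lo = max(d_lo, 1e-12)  # phi -> 0 expressible but kept positive
    d_hi = max(d_hi, d_lo)
    phi = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi), n_g))
    bias = _bias_log2(genes, config.bias_strength)

    arms = sorted({(s.cell_line, s.treatment) for s in design if s.treatment != CONTROL})
    n_de = int(round(config.frac_de * n_g))
    de_genes: dict[tuple[str, str], frozenset[str]] = {}
    true_lfc: dict[tuple[str, str, str], float] = {}
    lfc_mat: dict[tuple[str, str], np.ndarray] = {}
    discord: dict[tuple[str, str], np.ndarray] = {}
    f_lo, f_hi = config.log2fc_range
    for arm in arms:
        idx = rng.choice(n_g, size=n_de, replace=False) if n_de else np.array([], dtype=int)
        mag = rng.uniform(f_lo, f_hi, n_de)
        sign = rng.choice([-1.0, 1.0], n_de)
        vec = np.zeros(n_g)
        vec[idx] = mag * sign
        lfc_mat[arm] = vec
        flip = np.zeros(n_g, dtype=bool)
        if config.discordant_frac > 0 and n_de:
            n_flip = int(round(config.discordant_frac * n_de))
            flip[rng.choice(idx, size=n_flip, replace=False)] = True
        discord[arm] = flip
        de_genes[arm] = frozenset(gene_ids[i] for i in idx)
        for i in idx:
            true_lfc[(gene_ids[i], arm[0], arm[1])] = float(vec[i])

    sf = np.exp(rng.normal(0.0, config.libsize_sd, n_s)) if config.libsize_sd else np.ones(n_s)
    t_max = max(s.time_h for s in design)

    mean = np.empty((n_g, n_s))
    base_biased = baseline * 2.0 ** bias
    for j, s in enumerate(design):
        col = base_biased * sf[j]
        if s.treatment != CONTROL and s.time_h > 0:
            arm = (s.cell_line, s.treatment)
            lfc = lfc_mat[arm].copy()
            if s.time_h == t_max:
                lfc[discord[arm]] *= -1.0
            col = col * 2.0 ** lfc
        mean[:, j] = col

    # NB via Poisson-gamma mixture; phi -> 0 degenerates to Poisson
    shape = 1.0 / np.maximum(phi, 1e-12)
    lam = mean * rng.gamma(shape[:, None], 1.0, size=mean.shape) / shape[:, None]
    counts = rng.poisson(lam)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=[s.sample_id for s in design]),
        design,
    )
    truth = SimulationTruth(
        de_genes=de_genes,
        true_log2fc=true_lfc,
        dispersion=dict(zip(gene_ids, phi.astype(float))),
        baseline_mean=dict(zip(gene_ids, baseline.astype(float))),
        bias_log2=dict(zip(gene_ids, bias.astype(float))),
    )
    return cm, truth


def generate_pathways(
    genes: list[GeneRecord],
    n_pathways: int = 50,
    size_range: tuple[int, int] = (10, 60),
    edge_prob: float = 0.05,
    activation_frac: float = 0.75,
    seed: int = 0,
) -> list[PathwayTopology]:
    """Random signed directed pathway topologies over the gene universe."""
    if n_pathways < 0:
        raise ValidationError("n_pathways must be >= 0")
    if not 0.0 <= edge_prob <= 1.0 or not 0.0 <= activation_frac <= 1.0:
        raise ValidationError("edge_prob and activation_frac must be in [0, 1]")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValidationError("invalid size_range")
    if hi > len(genes):
        raise ValidationError("pathway size_range exceeds gene universe")
    rng = np.random.default_rng(seed)
    ids = np.array([g.gene_id for g in genes])
    width = max(3, len(str(n_pathways)))
    out = []
    for p in range(n_pathways):
        k = int(rng.integers(lo, hi + 1))
        nodes = tuple(ids[rng.choice(len(ids), size=k, replace=False)])
        adj = rng.random((k, k)) < edge_prob
        np.fill_diagonal(adj, False)
        signs = np.where(rng.random((k, k)) < activation_frac, 1, -1)
        edges = [
            (nodes[i], nodes[j], int(signs[i, j]))
            for i, j in zip(*np.nonzero(adj))
        ]
        out.append(PathwayTopology(f"PW{p + 1:0{width}d}", nodes, edges))
    return out


def generate_tft_sets(
    genes: list[GeneRecord],
    pathways: list[PathwayTopology],
    n_sets: int = 30,
    size_range: tuple[int, int] = (20, 100),
    pathway_overlap_frac: float = 0.3,
    seed: int = 0,
) -> GeneSetCollection:
    """Transcription-factor target sets partially overlapping pathway memberships.

    Each set draws ``pathway_overlap_frac`` of its members from one pathway
    (chosen round-robin) and the remainder from the rest of the universe, so
    pathway x TFT intersections are non-empty by construction when the
    fraction is positive.
    """
    if not 0.0 <= pathway_overlap_frac <= 1.0:
        raise ValidationError("pathway_overlap_frac must be in [0, 1]")
    lo, hi = size_range
    if lo < 1 or hi < lo or hi > len(genes):
        raise ValidationError("invalid size_range for TFT sets")
    rng = np.random.default_rng(seed)
    ids = np.array([g.gene_id for g in genes])
    width = max(3, len(str(n_sets)))
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        if pathways and pathway_overlap_frac > 0:
            pw = pathways[i % len(pathways)]
            n_from_pw = min(int(round(pathway_overlap_frac * size)), len(pw.nodes))
            picked = rng.choice(len(pw.nodes), size=n_from_pw, replace=False)
            members.update(pw.nodes[j] for j in picked)
        rest = ids[~np.isin(ids, sorted(members))]
        n_rest = min(size - len(members), len(rest))
        if n_rest > 0:
            members.update(rest[rng.choice(len(rest), size=n_rest, replace=False)])
        name = f"TFT{i + 1:0{width}d}"
        sets[name] = (f"synthetic TF target set {name}", frozenset(members))
    return GeneSetCollection(sets)
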