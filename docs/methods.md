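# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical and design decisions a maintainer should know
about. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study model and synthetic data

The generator emulates a factorial induction study: cell lines ×
treatments (an untreated control arm is mandatory) × time points ×
replicates. Counts for gene *g* in sample *s* are negative binomial,

    y_gs ~ NB(μ_gs, φ_g),    Var = μ + φ μ²,

drawn as a Poisson–gamma mixture, with

    μ_gs = baseline_g · 2^(Δ_gs) · 2^(bias_g) · sf_s .

* `baseline_g` — log-uniform on `mean_range` (default 10–1000 expected
  counts). The default spans weakly to strongly expressed genes; at the
  low end the per-contrast fold-change standard error at three
  replicates is ≈0.5 on the log2 scale, which is what real 3-replicate
  designs look like.
* `φ_g` — log-uniform on `dispersion_range` (default 0.05–0.4, the
  range typical of cell-line RNA-seq). `(0, 0)` gives exact Poisson
  counts for limit checks.
* `Δ_gs` — for each (cell line, treatment≠control) arm, a fraction
  `frac_de` (default 0.1) of genes receives a log2 effect with magnitude
  uniform on `log2fc_range` (default 0.5–2.5) and random sign, applied
  at every post-baseline time point. `discordant_frac` flips the sign of
  that fraction of effects at the last time point, to exercise the
  concordance filter's rejection path.
* `bias_g` — a smooth technical artefact: quadratic in GC fraction,
  log-linear in gene length, amplitude `bias_strength` (log2 units,
  default 0.5), mean-centred. It is constant across samples.
* `sf_s` — log-normal library-size factor (σ = 0.2), so counts per
  million and raw counts genuinely differ.

Gene lengths are log-uniform on 200–100 000 bp and GC fractions
beta-distributed on [0.3, 0.7]. Pathways are random signed directed
graphs (edge signs +1 with probability `activation_frac`); TFT sets draw
a configurable fraction of members from one pathway and the rest from
the whole universe, so pathway × TFT intersections exist by
construction.

What the generator does **not** emulate: batch effects beyond library
size, sample-to-sample variation of the GC/length bias, isoform
structure, count outliers, correlated genes within pathways, and
realistic pathway topology (hubs, feedback structure beyond what random
graphs produce). Tests passing on this generator therefore demonstrate
the *statistical contracts* of each stage — calibration, recovery,
propagation arithmetic — not robustness to every artefact of real data.

## Detectability and GC/length offsets

Detectability is per cell line: strictly more than `min_samples`
(default 3) samples strictly above `cpm_threshold` (default 1.5 CPM).
Both comparisons are strict, so a gene at exactly the threshold, or in
exactly `min_samples` samples, is not detectable. CPM uses raw counts;
whether to filter before or after normalisation is genuinely open, and
raw CPM was chosen because the filter should describe the assay, not
the model.

The GC/length correction replaces full conditional-quantile
normalisation with a per-sample regression offset: log2(CPM + 0.5) on
natural cubic spline bases (5 df each) of GC fraction and log10 length,
fitted by least squares; fitted values are centred to median zero per
sample and returned as a genes × samples log2 offset matrix, which the
GLM consumes after conversion to the natural log. This captures the
stated purpose of the heavier method — removing smooth GC/length
artefacts — with far less machinery, and is exact enough that on
synthetic data a strongly injected bias is recovered at correlation
above 0.8 and more than half its variance is removed (see
`tests/test_preprocess.py`).

One caveat discovered during development and worth keeping in mind: the
per-sample fit also absorbs whatever *chance* correlation exists between
baseline expression and the spline bases (RMS ≈ 0.15 log2 units at
2000 genes). This component is identical in every sample, so it cancels
in any treatment-vs-control contrast and is harmless for DE; the null
test therefore checks that offsets carry no *sample-specific* component
rather than that they vanish.

## Differential expression

Dispersion: per gene, the Cox–Reid adjusted profile likelihood of φ is
maximised on a log grid (bounded search, groups = design cells), then
shrunk on the log scale toward a lowess trend on log mean count with
prior weight 10 against the residual degrees of freedom. The prior
weight follows the moderation strength conventional in empirical-Bayes
DE tools; recovery is within ±25% at 10 replicates and the Poisson
limit is detected (tests). Constant or all-zero genes land on the floor
(1e-8) without failing.

The GLM is fitted by IRLS (log link, fixed φ, offsets; tolerance 1e-8
on the relative deviance change, 100 iterations max). The linear
predictor is clipped to ±30 to survive all-zero groups. In the φ→0
limit the fit matches an independent Poisson GLM to 1e-6
(cross-checked against statsmodels in the tests). Genes whose fit does
not converge are reported with p = 1 rather than dropped, keeping the
gene universe stable for enrichment.

Inference replaces the quasi-likelihood F-test of the usual count-GLM
stack with a Wald threshold test (TREAT-style composite null at
±τ = log2 fc_threshold, default fold change 1.2). The reference
distribution is Student t with df = residual df + dispersion prior
weight, a moderated-t analogue: with a plain normal reference the
3-replicate test is anti-conservative, and with df = residual df alone
it is far too conservative; adding the prior weight reflects the
information actually borrowed by the dispersion shrinkage. On null data
the raw rejection rate at 0.05 lands near 0.05 (acceptance tests), and
the threshold test is strictly more conservative than the τ = 0 test by
construction.

The design matrix per contrast is intercept + treatment within one cell
line at one time point, i.e. treatment vs control at that time, with
≥2 replicates per group required.

## Concordance and ranking

`combine_timepoints` keeps genes with P_FDR < α at both post-baseline
time points and equal fold-change sign; the combined effect is the mean
log2FC, the combined significance the maximum P_FDR. Consequently the
package's single fold-change estimate per experiment is that
two-time-point mean, and recovery of planted effects is evaluated
against it. `rank_max_fdr` sorts by maximum P_FDR across the selected
experiments, requires presence and directional agreement in all of
them, optionally requires the complementary experiments' mean log2FC
(missing entries contribute zero) to point the opposite way — a zero
mean is "not opposite" and excludes the gene — and breaks ties by
gene identifier, since any deterministic tie order is defensible and
this one is reproducible. Overlap tallies exclude genes significantly
up in one experiment and down in another before any up/down counting;
all percentages are exact decimal arithmetic rounded half-even to one
decimal (`percentage_of`), so printed tables recompute from the
underlying sets.

## Length-aware over-representation

The probability weighting function is a monotone fit of the 0/1 DE
indicator against gene length: genes are ordered by length, grouped
into ~n/50 equal-occupancy bins (5–40), and bin DE fractions are pooled
by isotonic regression, floored at 1e-6 and rescaled to mean equal to
the DE fraction. Binning before the monotone fit matters: raw isotonic
regression on 0/1 responses pins the extremes of the length range at 0
or 1 and badly overstates the bias. The enrichment p-value is the upper
tail of Wallenius' noncentral hypergeometric distribution
(scipy's implementation) with odds = mean weight inside the set / mean
weight outside — the mean-weight approximation used by length-aware
ORA tools. Flat weights reduce to the central hypergeometric exactly
(verified against brute-force enumeration for every configuration with
N ≤ 12), and biased tails match a 10⁶-draw sequential weighted-urn
simulation within Monte-Carlo error (acceptance tests).

## Pathway perturbation

With influence matrix B[i,j] = sign(j→i)/N_ds(j), perturbation factors
solve (I − B)·PF = ΔE directly; Acc = PF − ΔE and tA = ΣAcc. The solve
is refused when cond(I − B) > 1e12 — e.g. a pure activating 2-cycle,
where the propagation sum diverges — and callers may enable a damping
factor λ < 1 (B ← λB) as an explicitly logged fallback; the pipeline
skips such pathways by default rather than silently damping. Because tA
is linear in ΔE (tA = cᵀΔE with c = (I − B)⁻ᵀ1 − 1), the permutation
null needs one solve per pathway.

The permutation null reassigns the pathway's m observed non-zero ΔE
values, in shuffled order, to m nodes drawn uniformly without
replacement from the pathway's nodes, and recomputes tA. The two-sided
p-value uses the add-one pseudocount, p = (1 + #{|tA_null| ≥ |tA_obs|})
/ (1 + n_perm), so p ≥ 1/(n_perm + 1) and the test is never
anti-conservative by resolution. The normalized score is
z = (tA − mean_null)/sd_null; mean/SD (not median/MAD) because the null
is a mean-like statistic that is well behaved at n_perm = 2000, the
default. A null with zero spread (e.g. a single evidence value on an
edgeless subgraph) yields z = NaN, flagged, with p still defined.
Alternative permutation schemes (permuting gene labels genome-wide, or
drawing ΔE values from the full DE pool) are defensible; value-to-node
permutation within the pathway was chosen because it conditions on both
the pathway's topology and its observed evidence magnitudes, isolating
exactly the question "does *where* the evidence sits matter?".

Undetectable genes keep their topology roles with ΔE = 0 — propagation
should not be truncated by assay dropout. Multiplicity: BH across
pathways within an experiment. The cross-experiment consistency filter
retains pathways with ≥3 significant signals, all of one sign.

## TFT crosstalk

The pathway topology is restricted to genes shared with the TFT set as
an *induced* subgraph: edges survive only if both endpoints are
retained, and indirect paths through removed genes are not contracted.
Contraction would invent regulatory claims (an A→B→C chain with B
removed says nothing direct about A→C); the induced subgraph only ever
weakens propagation, which is the conservative direction. Scoring and
significance are identical to whole-pathway perturbation; BH is taken
over all scored (TFT, pathway) pairs within an experiment, the widest
defensible family. Aggregation rules: `all_experiments` (significant
and z-sign-concordant everywhere) and `subset_only` (significant and
concordant in a named experiment subset, not significant anywhere
else).

## Pipeline, determinism and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-stage and per-pathway seeds from the master seed by hashing stage
labels through `SeedSequence`, so adding a pathway never shifts another
pathway's null. Identical config + seed reproduces every output file
byte for byte (the manifest stores output checksums and a config hash
that excludes the output directory). Result tables are TSV at full
double precision; rounding happens only in report percentages.

Defaults for simulated studies are 2000 genes, 50 pathways and 30 TFT
sets — large enough for stable calibration estimates (a ±0.004
Monte-Carlo band on a 5% rejection rate at 12 000 null tests) while
keeping a full run in minutes on one CPU; the test suite uses smaller
universes (150–500 genes) chosen the same way, and the acceptance
script states its sizes in its output. The full-study-scale objects
these stand in for (annotation-wide universes, hundreds of pathways and
TFT sets) change only runtime, not any contract being tested.

## Known limitations

* The quasi-likelihood F-test of the reference DE stack is approximated
  by a moderated Wald threshold test; exact numerical agreement with
  edgeR is out of scope by design.
* The PWF uses binned isotonic rather than spline regression; it is
  piecewise constant across length bins.
* Wallenius odds use mean weights, inheriting the approximation of the
  tools this stage mirrors.
* The permutation scheme is this package's definition (documented
  above), not a claim about any other implementation's procedure.
* No combined global p-value (perturbation × over-representation) is
  computed; the two lines of evidence are reported separately.
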