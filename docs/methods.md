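# Methods

This note documents the models, parameter choices, and numerical decisions
behind `erymix`, and what the synthetic benchmark does and does not show
about real data.

## Synthetic stage-resolved proteome

The generator (`erymix.simulate`) emulates a bulk DIA proteome of an
ordered five-stage erythroid differentiation series measured in four
biological replicates.  Its components:

**Temporal archetypes.**  Every background protein follows one of six
temporal co-expression shapes — monotone-up, monotone-down, early-peak,
late-peak, transient-mid, U-shaped — parameterized as unit-range curves
over the stage axis (Gaussian bumps of width 0.30 on the normalized axis
for the peaked shapes, linear ramps for the monotone ones).  Each protein
draws a log2 amplitude uniform on [0.5, 5], so the background spans
near-flat to strongly stage-specific profiles, and a baseline abundance
log-uniform over 10² – 10⁵·⁵ copies per cell.  The abundance ceiling is
deliberately compressed relative to the most extreme real proteomes (no
hemoglobin-like outliers): in an unweighted least-squares deconvolution a
single hyperabundant protein dominates the fit, and the benchmark is meant
to compare marker panels, not individual outliers.  This is a known
limitation of the emulation.

**Replicate noise.**  Intensities are log-normal around the stage mean
with `sigma = sqrt(ln(1 + CV²))` and unit mean, so the within-stage CV of
linear intensities equals the configured `noise_cv` (default 0.15, chosen
so that most proteins fall below 20% CV as in well-behaved DIA
quadruplicates).  Noise is independent per protein and sample; real
replicates also carry correlated, sample-level structure that this model
omits.

**Dropout.**  Missingness is logistic in log2 intensity (missing with
probability `sigmoid(steepness · (midpoint − log2 I))`), i.e. left-censored
MNAR — the premise of down-shifted-normal imputation.  By default the
midpoint sits at the 6% quantile of the realized intensities with
steepness 0.8, giving roughly 5–8% missing values concentrated in the
lowest abundance decile, consistent with DIA's high data completeness.

**Histones.**  A configurable set of abundant histone-like proteins
(default 10, masses 11–22 kDa) declines multiplicatively across stages
(default 0.8 per stage), emulating the histone loss that accompanies
chromatin condensation during terminal maturation.  All planted copy
numbers are anchored so that, at the first stage, summed histone mass
equals the DNA mass of a diploid genome — exactly the proteomic ruler's
calibration assumption, which makes ruler round trips exact on noiseless
data with constant histone content.

**Planted markers.**  Three curated-style panels are planted — `sorting`
(5 proteins), `known` (22), `slc` (18), matching the sizes of typical
curated erythroid marker sets.  A marker is a bump at its assigned stage
with a fixed on/off contrast of 5 log2 units; its *separability* score
(sorting 0.65, known 0.60, slc 0.70) controls how cleanly the on-stage
signal stands above the off-target leakage into neighbouring stages, not
how abundant it is.  Two structural features mirror the biology of curated
panels: historically known markers over-represent the extreme stages
(`known` covers stages at weights 0.25/0.1/0.1/0.1/0.45), and all markers
resolve the middle of the axis less cleanly than the extremes (separability
attenuated by up to 20% at the centre), because intermediate precursor
stages differ less at the proteome level.  Marker base abundances are
drawn narrowly (10³·⁸ – 10⁴·²) so that no single panel's markers dominate
the unweighted least-squares fit of the combined panel.

## Preprocessing and profiling

**Completeness filter.**  A protein is kept if at least a fraction
(default 0.75, i.e. 3 of 4 replicates) of one stage's replicates observed
it, in at least one stage.  The strict variant (1.0) is used before ruler
estimation.

**Imputation.**  Missing log2 intensities are drawn per sample column from
`Normal(mean − 1.8·sd, (0.3·sd)²)` of that column's observed values.  The
down-shift is defined per column because it is only meaningful relative to
each sample's own intensity distribution.  Observed values are never
altered; a column with fewer than two observations is an error.

**Stage ANOVA.**  A one-way F statistic per protein, with an
S0-regularized denominator `(sqrt(MSW) + s0)²` (default s0 = 0.1) that
damps the significance of proteins with tiny residual variance — the
multi-group analogue of the S0 trick in moderated t statistics, and the
reason zero-variance proteins get a finite statistic.  Significance is
assessed by permutation: stage labels are permuted across samples
(default 250 rounds), permuted statistics are pooled over proteins, and
`q(t) = (expected null exceedances per permutation) / (observed
exceedances)`, monotonized step-up so q never decreases with significance
and clipped to [0, 1].  A parametric p-value from the F distribution is
reported alongside for reference (exact only at s0 = 0).  Zero-variance
proteins are assigned q = 1 by convention.

**Temporal clustering.**  Stage medians over replicates are z-scored per
protein and clustered hierarchically with Euclidean distance, cutting the
tree into six flat clusters.  Ward linkage is the default: on data of this
kind, average linkage chains outlying profiles into singleton clusters and
collapses the temporal structure, while Ward recovers balanced shape
clusters (with zero noise it recovers the planted archetype partition
exactly).  Cluster labels are renumbered along the maturation axis by the
stage at which each cluster's mean profile peaks, so labels are stable and
meaningful.

## Marker panels

All panels except `any20` are restricted to ANOVA q < 0.01.
`cluster_top3` takes the three smallest-q proteins of each temporal
cluster (ties broken by larger F, then lexicographic id — panels are fully
deterministic); `combined` is the deduplicated union of the curated panels
and `cluster_top3`; `any20` draws 20 proteins uniformly from the
unfiltered list excluding every other panel, reproducibly under its seed.

## Deconvolution benchmark

Signatures average the linear intensities of replicates 2 and 4 per stage;
mixtures are synthesized from the averaged replicates 1 and 3, so the
benchmark carries genuine replicate noise rather than fitting a signature
to itself.  A guard rejects matrices that look log-transformed (all values
below 64).  Markers unobserved in the signature replicates of a stage are
dropped from the signature; markers missing from the mixture sources are
dropped from that mixture's system rather than zero-filled.

Mixing ratios are flat-Dirichlet (uniform on the simplex, exchangeable
across stages), 500 per run, shared across panels so comparisons are
paired per mixture.

Fraction estimation is two-pass non-negative least squares (active-set
solver).  After the first pass, markers are ranked by
`|I_k·â − i_mix,k| / ‖I_k‖₂` — the absolute residual scaled by the
signature row norm, so abundant markers cannot monopolize retention — and
the best 90% are kept (never fewer than the number of stages); the second
pass re-solves on the retained markers and the solution is divided by its
L1 norm.  Two numerical edge cases: if the first pass already fits
perfectly (residual below 1e-9 of the target norm) the ranking is pure
numerical noise and a refit on the flat residual landscape can wander, so
iteration 2 keeps the iteration-1 solution; a signature losing full column
rank triggers a warning (inside `evaluate_panels`, such a panel is skipped).

**Error metric.**  With unit spacing between consecutive stages the
weighted error is `Σ_{k<K} |C_k(a) − C_k(â)|` over cumulative sums — the
1-D Wasserstein distance, a true metric under which moving mass one stage
costs exactly the mass moved, and four stages four times that.  Stage
spacing is configurable for non-uniform developmental distances.  Controls:
`uniform` = 1/K per stage, `center` = one-hot at stage ⌈K/2⌉, `random` = a
fresh simplex draw per mixture, independent of the truth.

**What a single dataset can and cannot show.**  A panel's mean error over
the 500 mixtures is dominated not by per-mixture noise but by a *fixed*
bias: the replicate split means the signature and the mixture sources
disagree by one realization of replicate noise, identical for all 500
mixtures.  A panel with ~4 markers per stage carries a per-stage bias of
roughly `CV/√(2·markers-per-stage)`, and whichever panel drew the luckiest
bias wins that dataset.  The union (`combined`) pools the most markers and
has the lowest *expected* error, but on any one dataset a lucky
constituent can edge it out.  Claims about panel ordering are therefore
made in expectation, averaged over replicate generated datasets (the
acceptance checks use 20); single-dataset summaries, like the README
example, show one draw of that distribution.

## Proteomic ruler

Per sample, `copies_p = I_p · m_DNA · N_A / (Σ_h I_h · MW_p)` with
`m_DNA = ploidy × 3.25 pg` (haploid human genome mass; overridable).  The
core assumption is that MS intensity is proportional to protein mass
within a sample, and that histone mass per cell equals DNA mass.  Total
protein mass per cell is `Σ_p copies_p·MW_p/N_A` and cell volume divides
that by the assumed total protein concentration (200 g/L), so
volume × concentration = mass holds exactly by construction.  Copies are
invariant under per-sample rescaling and total mass is linear in ploidy.
When the generator's histone content declines across stages, per-sample
anchoring re-normalizes each stage — the estimates then drift upward
relative to the planted truth at late stages, which is precisely the bias
the method suffers on real maturing erythroblasts; round-trip validation
therefore uses constant histone content.  `summarize_copies` reports both
median and mean per protein set and stage (replicate mean ± SEM), since
either summary may be wanted for "total molecules per cell"-style figures.

## Pipeline and reproducibility

One master seed spawns per-stage child seeds through numpy's
`SeedSequence` with fixed per-stage spawn keys, so adding a stage never
perturbs earlier stages' randomness and the manifest's recorded seeds
suffice to reproduce every artifact bit for bit.  Default problem sizes —
4,000 proteins, 500 mixtures, 250 permutations — run in seconds; the
acceptance script's panel-ordering study uses 2,000-protein datasets with
150 mixtures per dataset, which leaves the expected ordering margins
unchanged while keeping 20 replicates cheap.

## Known limitations

- All distributional choices of the generator are stand-ins: the study
  system it emulates publishes no generative model.  Passing benchmarks
  here show the pipeline's correctness and the method's behaviour under
  controlled conditions, not performance on any particular real proteome.
- Replicate noise is independent per protein; correlated (co-regulation,
  batch) structure is not modelled.
- The abundance ceiling excludes hemoglobin-scale outliers (see above).
- Real bulk samples of unknown composition can be deconvolved with the
  same functions, but no validation beyond the synthetic benchmark is
  provided.
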