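# erymix

Stage-resolved analysis of erythroid maturation proteomes: synthetic
DIA-style data generation, stage-specific marker selection, reference-based
*in silico* mixture deconvolution over an ordered developmental axis, and
histone proteomic-ruler copy-number estimation.

## The problem

Human erythropoiesis runs through an ordered series of precursor stages
(progenitors → ProE/EBaso → LBaso → Poly → Ortho).  Bulk samples drawn from
such a culture are mixtures of stages, and a recurring analysis question is
whether a small panel of marker proteins can *deconvolve* a bulk proteome —
estimate what fraction of cells came from each stage.  `erymix` implements
the full computational benchmark for that question, driven entirely by a
synthetic-data generator with known ground truth, so every step is testable
without any external download.

## The model

For marker protein *k* with signature intensity `I_ik` in stage *i*, a bulk
sample mixed with stage fractions `a_i` has intensity

```
I_mix,k = Σ_i I_ik · a_i ,      Σ_i a_i = 1 ,  a_i ≥ 0 .
```

Given a signature matrix **I** (markers × stages, averaged non-logged
intensities from held-out replicates) and a mixture vector **i**_mix, the
fractions are estimated by non-negative least squares
(`min ‖I·â − i_mix‖₂, â ≥ 0`), refined in a second pass on the best-fitting
90% of markers, and L1-normalized onto the simplex.  Accuracy is scored with
an ordinal weighted error — the 1-D earth-mover (Wasserstein-1) distance
between true and estimated fraction vectors — so confusing neighbouring
stages costs less than confusing distant ones.  Three baselines calibrate
the scale: a random simplex draw, the uniform vector (0.2 per stage), and a
one-hot vector at the middle stage.

Six marker panels are compared: three curated sets (FACS `sorting` markers,
literature-`known` markers, and a solute-carrier `slc` set), a data-driven
`cluster_top3` panel (the three most significant proteins of each of six
temporal expression clusters from a permutation-FDR stage ANOVA), their
deduplicated union (`combined`), and a random `any20` negative control.

Separately, the histone proteomic ruler converts intensities to per-cell
copy numbers by anchoring the summed histone signal to the DNA mass of a
diploid genome: `copies_p = I_p · m_DNA · N_A / (Σ_h I_h · MW_p)`.

## Worked example

```
erymix run-all --seed 0 --out runs/demo
```

generates a default synthetic proteome (4,000 proteins, 5 stages × 4
replicates, 15% replicate CV, abundance-dependent dropout), preprocesses it
(completeness filter, down-shifted-normal imputation, S0-regularized stage
ANOVA with permutation FDR, clustering into six temporal profiles),
assembles the six panels, benchmarks them on 500 random mixtures, runs the
ruler, and prints the per-panel error summary:

```
                    min      q1  median    mean      q3     max
sorting          0.0215  0.0632  0.0887  0.0920  0.1184  0.2230
known            0.0168  0.0569  0.0758  0.0808  0.1009  0.2698
cluster_top3     0.0153  0.0612  0.0829  0.1029  0.1272  0.4032
slc              0.0143  0.0305  0.0393  0.0409  0.0513  0.1208
combined         0.0240  0.0438  0.0556  0.0592  0.0717  0.1201
any20            0.1317  0.2890  0.3437  0.3640  0.4279  0.7893
control_random   0.0638  0.5137  0.7565  0.8282  1.0447  2.3321
control_uniform  0.1235  0.3949  0.5299  0.5914  0.7322  1.6756
control_center   0.1476  0.9818  1.2025  1.1934  1.4111  1.9566
```

Reading this: an error of 0.06 means that, on average, the equivalent of 6%
of the cell mass was misplaced by one stage.  The informative panels sit
far below the uninformed baselines (`any20` and the controls); the
`combined` panel is the most reliable in expectation, although on any
single dataset one constituent panel can edge it out by luck of the
replicate noise (here `slc` — see `docs/methods.md` for why).  The run
directory contains every artifact as TSV plus a `manifest.json` with all
seeds; re-running with the same seed reproduces all outputs byte for byte.

Library use mirrors the CLI:

```python
import erymix as em

matrix, truth = em.generate_proteome(em.SynthConfig(seed=0))
filtered = em.filter_completeness(matrix)
stats = em.anova_stage_test(em.impute_missing(filtered.log2(), seed=1),
                            filtered.design(), seed=2)
stats = em.cluster_profiles(stats)
panels = em.assemble_panels(stats, truth.marker_panels, filtered.protein_ids, seed=3)
report = em.evaluate_panels(matrix, panels, em.generate_ratios(seed=4))
print(report.summary())
```

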