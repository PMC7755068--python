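# wheatgp

Multi-environment genomic prediction and association mapping for **anther
extrusion** in hybrid wheat breeding.

Hybrid wheat seed production depends on male parents that shed pollen
outside the floret. Anther extrusion — measured either as the extruded
anther count percentage (AC, `extruded / total × 100`) or as a 1–10 visual
score (VS) — is quantitative, strongly affected by genotype-by-environment
(G×E) interaction, and expensive to phenotype, which makes it a natural
target for genomic selection. `wheatgp` implements the full desk analysis
of a multi-environment trial of breeding lines:

* **Kernels** — marker QC (polymorphism, MAF, missingness, map presence),
  the genomic relationship matrix `G ∝ XX′ / (2 Σ 2pₘ(1−pₘ))` from centered
  allele doses (the common VanRaden scaling `Σ 2pₘ(1−pₘ)` is a switch), the
  pedigree numerator relationship matrix **A** by the tabular method, and
  record-level G×E covariances as Hadamard products
  `(Z_L K Z_L′) ∘ (Z_E Z_E′)`.
* **Models** — seven nested random-effect reaction-norm models for records
  `y_ij = μ + E_j + L_i [+ g_i + a_i + gE_ij + aE_ij] + ε_ij`, from the
  baseline environment+line model (1) through the full
  `E + L + G + A + G×E + A×E` model (7), fitted by a Gibbs sampler with one
  Gaussian block per kernel term and masked-response data augmentation.
  A deterministic Henderson-style solver at fixed variance components
  serves as an independent oracle.
* **Cross-validation** — CV1 (lines never phenotyped anywhere), CV2
  (sparse testing: line × environment cells missing), and CV0
  (leave-one-environment-out), scored by within-environment Pearson
  correlation between predicted and observed values.
* **Phenotypes** — per-trial BLUEs (genotype fixed, replicates random),
  REML variance components for within-trial, combined
  (`μ + G + E + G×E + ε`), and environments-as-replicates designs, and
  broad-sense heritability
  `H² = σ²_G / (σ²_G + σ²_e/r)` within a trial and
  `H² = σ²_G / (σ²_G + σ²_GE/l + σ²_e/(l·r))` across trials.
* **GWAS** — Q+K mixed-linear-model scan (PC covariates, kinship, P3D
  variance components, per-marker GLS Wald tests), Bonferroni threshold
  `−log₁₀(α/n)`, and LD decay over genetic distance in a sliding window of
  adjacent markers.
* **Synthetic data** — a pedigree-structured breeding-population generator
  (random crossing from founders, gene dropping with Haldane recombination,
  reaction-norm phenotypes with exact realized variance components) so that
  every stage is testable without external data.

## Worked example

```python
import wheatgp as wg

# a 600-line, 3-environment trial at the combined anther-count variance
# components (sigma2_G=211.09, sigma2_E=182.70, sigma2_GxE=80.45,
# sigma2_e=185.03), 2,000 SNPs
sim = wg.simulate_dataset(wg.SimConfig(n_lines=600, n_markers=2000, seed=1))

vc = wg.estimate_variance_components(sim.records, "AC", design="combined")
print(round(vc.var_G, 1), round(vc.var_E, 1),
      round(vc.var_GE, 1), round(vc.var_e, 1))
# 209.0 179.7 75.1 185.4        <- REML recovers the generating components

h2 = wg.broad_sense_heritability(
    wg.VarianceComponents(var_G=254.34, var_e=290.82, n_env=1, n_rep=4,
                          grand_mean=47.16), "within")
print(round(h2, 2))
# 0.78                          <- trial-level heritability of anther count

blues = wg.compute_blues(sim.records, "AC")
rec = (blues.rename(columns={"blue": "value"}).assign(replicate="blue")
       [["line", "environment", "replicate", "trait", "value"]])
G = wg.genomic_relationship(
    wg.impute_missing(wg.filter_markers(sim.markers)), scale="vanraden")

fit = wg.ReactionNormGBLUP(model=3, n_iter=2500, burn_in=500, seed=7)
fit.fit(rec, g=G)
print({k: round(v, 1) for k, v in fit.var_components_.items()})
# {'E': 129.5, 'L': 58.8, 'G': 136.2, 'GxE': 69.7, 'residual': 40.7}
```

The model-3 fit splits the BLUE-level variance into environment, iid line,
genomic, genomic-by-environment, and residual parts; the `GxE` posterior
mean (69.7) recovers the simulated interaction variance (80.45) within its
posterior uncertainty, and the residual (40.7) tracks the replicate-mean
error `σ²_e / r ≈ 185/5 = 37`.

A command-line pipeline mirrors the library:

```bash
wheatgp simulate --seed 1 --out-dir out/sim
wheatgp kernels --markers out/sim/markers.csv --pedigree out/sim/pedigree.csv \
        --scale vanraden --out-g out/G.csv --out-a out/A.csv
wheatgp cv --scheme cv2 --models 1-3 --phenotypes out/sim/phenotypes.csv \
        --g-kernel out/G.csv --out out/cv.tsv
wheatgp gwas --phenotype-blues out/blues.csv --markers out/sim/markers.csv \
        --map out/sim/map.csv --out out/gwas
```

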