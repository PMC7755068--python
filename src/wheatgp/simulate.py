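"""Synthetic breeding-population generator.

Emulates the statistical structure of a multi-environment wheat trial:

* a pedigree built by random crossing from a founder pool,
* biallelic SNP genotypes gene-dropped through the pedigree with
  recombination following map distances (Haldane mapping, no interference),
* multi-environment phenotypes
  y_ijk = mu + E_j + g_i + gE_ij + eps_ijk,
  where the line value g_i has a marker-driven additive part (fraction
  ``prop_additive_marked`` of var_G, built from random marker effects) plus
  an independent line residual, and the genotype-by-environment deviation
  gE_ij is built from environment-specific marker effects, so its
  covariance is genomically structured within an environment and zero
  across environments (the reaction-norm structure the downstream models
  assume).

Every simulated effect vector is centered and rescaled so its realized
variance equals the requested component exactly, which makes
variance-component recovery tests sharp rather than confounded with
sampling noise of the effects themselves.

Default variance components reproduce the combined anther-count analysis of
the motivating dataset (var_G = 211.09, var_E = 182.70, var_GE = 80.45,
var_e = 185.03) for 603 lines in 3 environments with 5 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MarkerMatrix, Pedigree, validate_map
from .exceptions import DimensionError, InvalidConfigError

GRAND_MEAN_DEFAULT = 57.31  # combined anther-count grand mean


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator."""

    n_founders: int = 50
    n_lines: int = 603
    n_generations: int = 4
    n_markers: int = 10_000
    n_chromosomes: int = 21
    map_length_cM: float = 150.0
    n_environments: int = 3
    n_replicates: int = 5
    var_G: float = 211.09
    var_E: float = 182.70
    var_GE: float = 80.45
    var_e: float = 185.03
    prop_additive_marked: float = 0.7
    n_qtl: int = 0
    missing_rate: float = 0.0
    grand_mean: float = GRAND_MEAN_DEFAULT
    trait: str = "AC"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_G", "var_E", "var_GE", "var_e"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.prop_additive_marked <= 1.0:
            raise InvalidConfigError("prop_additive_marked must be in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise InvalidConfigError("n_qtl cannot exceed n_markers")
        if self.n_founders < 2:
            raise InvalidConfigError("need at least 2 founders")
        if self.missing_rate < 0 or self.missing_rate >= 1:
            raise InvalidConfigError("missing_rate must be in [0, 1)")


@dataclass
class SimOutput:
    """Everything the generator knows about one synthetic dataset."""

    pedigree: Pedigree
    markers: MarkerMatrix
    gmap: pd.DataFrame
    records: pd.DataFrame
    true_values: pd.DataFrame      # lines x environments genetic values g + gE
    env_effects: pd.Series         # E_j
    true_qtl: pd.DataFrame = field(default_factory=pd.DataFrame)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent substream per pipeline stage from one integer seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_pedigree(n_founders: int, n_lines: int, generations: int,
                      seed: int = 0) -> Pedigree:
    """Random-mating pedigree: founders plus `generations` crossing rounds.

    Parents of each non-founder are a random distinct pair drawn from all
    previously created individuals, so the population accumulates full-sib,
    half-sib and deeper relationships.
    """
    if n_founders < 2:
        raise InvalidConfigError("need at least 2 founders")
    if n_lines < n_founders:
        raise InvalidConfigError("n_lines must be >= n_founders")
    n_offspring = n_lines - n_founders
    if n_offspring > 0 and generations < 1:
        raise InvalidConfigError("crosses require generations >= 1")
    rng = _stage_rng(seed, 0)
    width = max(4, len(str(n_lines)))
    founders = [f"FND{i + 1:0{width}d}" for i in range(n_founders)]
    lines = list(founders)
    parent1 = [None] * n_founders
    parent2 = [None] * n_founders
    if n_offspring:
        per_gen = np.full(generations, n_offspring // generations)
        per_gen[: n_offspring % generations] += 1
        counter = 0
        for g, size in enumerate(per_gen):
            pool = list(lines)  # everything created so far
            for _ in range(size):
                counter += 1
                pa, pb = rng.choice(len(pool), size=2, replace=False)
                lines.append(f"LIN{counter:0{width}d}")
                parent1.append(pool[pa])
                parent2.append(pool[pb])
    return Pedigree(lines, parent1, parent2)


def make_genetic_map(n_markers: int, n_chromosomes: int = 21,
                     map_length_cM: float = 150.0,
                     seed: int = 0) -> pd.DataFrame:
    """Uniform-random marker positions on equal-length chromosomes."""
    rng = _stage_rng(seed, 1)
    chrom_sizes = np.full(n_chromosomes, n_markers // n_chromosomes)
    chrom_sizes[: n_markers % n_chromosomes] += 1
    rows = []
    i = 0
    for c, size in enumerate(chrom_sizes):
        pos = np.sort(rng.uniform(0.0, map_length_cM, size=size))
        for p in pos:
            i += 1
            rows.append((f"M{i:06d}", f"chr{c + 1}", float(p), float(p) * 4.0))
    return pd.DataFrame(rows, columns=["marker", "chromosome", "cM", "Mb"])


def _recomb_fractions(gmap: pd.DataFrame) -> np.ndarray:
    """Haldane recombination fraction between adjacent markers.

    r = 0.5 (1 - exp(-2 d / 100)) within a chromosome, 0.5 across
    chromosome boundaries; entry j is the fraction between markers j-1, j.
    """
    cm = gmap["cM"].to_numpy(dtype=float)
    chrom = gmap["chromosome"].to_numpy()
    r = np.empty(len(gmap))
    r[0] = 0.5
    d = np.abs(np.diff(cm))
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    r[1:][chrom[1:] != chrom[:-1]] = 0.5
    return r


def _meiosis(hap_a, hap_b, r, rng):
    """One gamete from a parent's two haplotypes with crossover prob r."""
    switch = rng.random(len(r)) < r
    strand = np.bitwise_xor.accumulate(switch) ^ (rng.random() < 0.5)
    return np.where(strand, hap_b, hap_a)


def simulate_markers(pedigree: Pedigree, n_markers: int, gmap: pd.DataFrame,
                     missing_rate: float = 0.0, seed: int = 0,
                     founder_doses: np.ndarray | None = None) -> MarkerMatrix:
    """Gene-drop biallelic SNPs through the pedigree.

    Founder haplotype alleles are Bernoulli draws at per-marker frequencies
    p_m ~ Uniform(0.1, 0.9) (marker-independent, so founder LD is nil;
    linkage disequilibrium in descendants arises from co-inheritance).
    ``founder_doses`` overrides the founder genotypes (dose 1 founders are
    made heterozygous) — used to set up designed LD patterns.
    """
    gmap = validate_map(gmap)
    if len(gmap) != n_markers:
        raise DimensionError(
            f"map has {len(gmap)} markers but n_markers={n_markers}"
        )
    rng = _stage_rng(seed, 2)
    r = _recomb_fractions(gmap)
    founders = pedigree.founders
    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if founder_doses is not None:
        founder_doses = np.asarray(founder_doses)
        if founder_doses.shape != (len(founders), n_markers):
            raise DimensionError("founder_doses must be n_founders x n_markers")
        for i, line in enumerate(founders):
            d = founder_doses[i]
            a = (d >= 1).astype(np.int8)
            b = (d >= 2).astype(np.int8)
            haps[line] = (a, b)
    else:
        p = rng.uniform(0.1, 0.9, size=n_markers)
        for line in founders:
            haps[line] = (
                (rng.random(n_markers) < p).astype(np.int8),
                (rng.random(n_markers) < p).astype(np.int8),
            )
    for k, line in enumerate(pedigree.lines):
        if line in haps:
            continue
        pa = pedigree.parent1[k]
        pb = pedigree.parent2[k]
        gam_a = _meiosis(*haps[pa], r, rng) if pa is not None else (
            rng.random(n_markers) < 0.5).astype(np.int8)
        gam_b = _meiosis(*haps[pb], r, rng) if pb is not None else (
            rng.random(n_markers) < 0.5).astype(np.int8)
        haps[line] = (gam_a, gam_b)
    doses = np.empty((len(pedigree), n_markers))
    for i, line in enumerate(pedigree.lines):
        a, b = haps[line]
        doses[i] = a.astype(float) + b.astype(float)
    if missing_rate > 0:
        mask = rng.random(doses.shape) < missing_rate
        doses[mask] = np.nan
    return MarkerMatrix(
        np.asarray(pedigree.lines, dtype=object),
        gmap["marker"].to_numpy(dtype=object),
        doses,
    )


def _center_scale(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center x and rescale so its sample variance equals target_var."""
    x = x - x.mean()
    v = x.var(ddof=1) if len(x) > 1 else 0.0
    if target_var == 0.0 or v == 0.0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_phenotypes(cfg: SimConfig, markers: MarkerMatrix,
                        pedigree: Pedigree) -> SimOutput:
    """Multi-environment phenotypes with known variance decomposition.

    See the module docstring for the generative model. Marker effects are
    drawn iid normal over all markers (or over ``n_qtl`` planted markers
    when n_qtl > 0, with the QTL panel and effects reported in
    ``true_qtl``).
    """
    missing_lines = set(pedigree.lines) - set(markers.line_ids)
    if missing_lines:
        raise DimensionError(
            f"markers do not cover pedigree lines: {sorted(missing_lines)[:5]}"
        )
    rng = _stage_rng(cfg.seed, 3)
    lines = list(pedigree.lines)
    m = markers.subset_lines(lines)
    doses = m.doses.copy()
    if np.isnan(doses).any():
        p = np.nanmean(doses, axis=0) / 2.0
        idx = np.where(np.isnan(doses))
        doses[idx] = (2.0 * p)[idx]
    Xc = doses - doses.mean(axis=0)
    n_lines = len(lines)
    n_env = cfg.n_environments
    envs = [f"env{j + 1}" for j in range(n_env)]

    if cfg.n_qtl > 0:
        qtl_idx = rng.choice(m.n_markers, size=cfg.n_qtl, replace=False)
    else:
        qtl_idx = np.arange(m.n_markers)
    B = Xc[:, qtl_idx]

    var_marked = cfg.prop_additive_marked * cfg.var_G
    beta = rng.standard_normal(len(qtl_idx))
    g_marked = _center_scale(B @ beta, var_marked)
    g_resid = _center_scale(
        rng.standard_normal(n_lines), (1.0 - cfg.prop_additive_marked) * cfg.var_G
    )
    g = g_marked + g_resid

    E = _center_scale(rng.standard_normal(n_env), cfg.var_E) if n_env > 1 else (
        np.zeros(n_env)
    )

    gE = np.zeros((n_lines, n_env))
    if cfg.var_GE > 0:
        for j in range(n_env):
            beta_j = rng.standard_normal(len(qtl_idx))
            gE[:, j] = _center_scale(B @ beta_j, cfg.var_GE)

    n_rec = n_lines * n_env * cfg.n_replicates
    eps = _center_scale(rng.standard_normal(n_rec), cfg.var_e)

    rows = []
    k = 0
    for j, env in enumerate(envs):
        for i, line in enumerate(lines):
            for rep in range(cfg.n_replicates):
                value = cfg.grand_mean + E[j] + g[i] + gE[i, j] + eps[k]
                rows.append((line, env, f"r{rep + 1}", cfg.trait, value))
                k += 1
    records = pd.DataFrame(rows, columns=["line", "environment", "replicate",
                                          "trait", "value"])
    true_values = pd.DataFrame(g[:, None] + gE, index=lines, columns=envs)
    true_qtl = pd.DataFrame({
        "marker": m.marker_ids[qtl_idx],
        "effect": beta * (np.std(g_marked, ddof=1) /
                          max(np.std(B @ beta, ddof=1), 1e-300)
                          if np.std(B @ beta, ddof=1) > 0 else 0.0),
    }) if cfg.n_qtl > 0 else pd.DataFrame(columns=["marker", "effect"])
    return SimOutput(
        pedigree=pedigree,
        markers=markers,
        gmap=pd.DataFrame(),
        records=records,
        true_values=true_values,
        env_effects=pd.Series(E, index=envs),
        true_qtl=true_qtl,
    )


def simulate_dataset(cfg: SimConfig) -> SimOutput:
    """Full pipeline: pedigree -> map -> markers -> phenotypes."""
    ped = simulate_pedigree(cfg.n_founders, cfg.n_lines, cfg.n_generations,
                            seed=cfg.seed)
    gmap = make_genetic_map(cfg.n_markers, cfg.n_chromosomes,
                            cfg.map_length_cM, seed=cfg.seed)
    markers = simulate_markers(ped, cfg.n_markers, gmap,
                               missing_rate=cfg.missing_rate, seed=cfg.seed)
    out = simulate_phenotypes(cfg, markers, ped)
    out.gmap = gmap
    return out
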