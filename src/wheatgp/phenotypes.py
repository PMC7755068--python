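"""Phenotypic analysis: anther-extrusion percentages, per-trial BLUEs,
variance components, broad-sense heritability, and trait correlations.

Trait conventions
-----------------
Anther count (AC) is the percentage of extruded anthers per spike,
``extruded / total * 100``, in [0, 100]. The visual score (VS) is a 1-10
ordinal field score with, typically, a single observation per environment,
so environments act as replicates in its variance-component analysis.

Variance components are REML estimates of all-random models:

* ``combined``   : y = mu + G + E + GxE + eps   (>= 2 environments)
* ``within-env`` : y = mu + G + rep + eps       (one environment)
* ``env-as-replicate`` : y = mu + G + eps, environments as replicates

Broad-sense heritability at the trial-mean level:

* within environment:  H2 = s2_G / (s2_G + s2_e / r)
* across environments: H2 = s2_G / (s2_G + s2_GE / l + s2_e / (l r))

with r replicates per environment and l environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _reml
from .containers import validate_records
from .exceptions import (
    InsufficientOverlapError,
    InvalidConfigError,
    StructureError,
    ValidationError,
)

logger = logging.getLogger(__name__)


def anther_extrusion_percent(extruded, total):
    """Anther extrusion percentage: extruded / total * 100.

    Accepts scalars or arrays; totals must be positive and extruded counts
    must lie in [0, total].
    """
    extruded = np.asarray(extruded, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValidationError("total anther count must be > 0")
    if np.any(extruded < 0) or np.any(extruded > total):
        raise ValidationError("extruded count must lie in [0, total]")
    out = extruded / total * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class VarianceComponents:
    """REML variance components for one trait/design."""

    var_G: float
    var_e: float
    n_env: int
    n_rep: float
    grand_mean: float
    var_E: float | None = None
    var_GE: float | None = None
    var_rep: float | None = None
    design: str = "combined"
    significance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("var_G", "var_e"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValidationError("n_env and n_rep must be >= 1")


def broad_sense_heritability(vc: VarianceComponents, scope: str = "within") -> float:
    """Broad-sense heritability from variance components.

    ``scope="within"`` uses H2 = s2_G/(s2_G + s2_e/r); ``scope="across"``
    uses H2 = s2_G/(s2_G + s2_GE/l + s2_e/(l r)).
    """
    r = float(vc.n_rep)
    l = int(vc.n_env)
    if r <= 0 or l <= 0:
        raise InvalidConfigError("replication and environment counts must be > 0")
    if scope == "within":
        denom = vc.var_G + vc.var_e / r
    elif scope == "across":
        if vc.var_GE is None:
            raise InvalidConfigError("across-environment H2 requires var_GE")
        denom = vc.var_G + vc.var_GE / l + vc.var_e / (l * r)
    else:
        raise InvalidConfigError(f"unknown scope {scope!r}")
    if denom == 0.0:
        return 0.0
    h2 = vc.var_G / denom
    return float(min(max(h2, 0.0), 1.0))


def compute_blues(records: pd.DataFrame, trait: str,
                  environment=None) -> pd.DataFrame:
    """Per-environment BLUEs of genotype means.

    Model per environment: value = genotype_i (fixed) + replicate (random)
    + error, solved by GLS at REML variance components. With balanced
    replication the BLUE equals the per-line arithmetic mean. Lines without
    records are simply absent (logged), not an error.

    Returns a BlueTable: columns line, trait, environment, blue, se.
    """
    rec = validate_records(records)
    rec = rec[rec["trait"] == trait]
    if environment is not None:
        envs = [environment]
    else:
        envs = sorted(rec["environment"].unique())
    tables = []
    for env in envs:
        sub = rec[rec["environment"] == env]
        if sub.empty:
            logger.warning("no %s records in environment %s", trait, env)
            continue
        tables.append(_blues_one_env(sub, trait, env))
    if not tables:
        return pd.DataFrame(columns=["line", "trait", "environment", "blue", "se"])
    return pd.concat(tables, ignore_index=True)


def _blues_one_env(sub: pd.DataFrame, trait: str, env) -> pd.DataFrame:
    lines = sorted(sub["line"].unique())
    reps = sorted(sub["replicate"].unique())
    y = sub["value"].to_numpy(dtype=float)
    lpos = {l: i for i, l in enumerate(lines)}
    rpos = {r: i for i, r in enumerate(reps)}
    n = len(sub)
    X = np.zeros((n, len(lines)))
    X[np.arange(n), [lpos[l] for l in sub["line"]]] = 1.0
    if len(reps) < 2 or n == len(lines):
        # no replication structure to estimate; BLUE = per-line mean
        means = sub.groupby("line")["value"].agg(["mean", "std", "count"])
        means = means.reindex(lines)
        se = means["std"] / np.sqrt(means["count"])
        blue = means["mean"].to_numpy()
        se = se.to_numpy()
    else:
        Z = np.zeros((n, len(reps)))
        Z[np.arange(n), [rpos[r] for r in sub["replicate"]]] = 1.0
        _, beta, cov_beta = _reml.reml_lowrank_iid(y, X, Z)
        blue = beta
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    return pd.DataFrame({
        "line": lines,
        "trait": trait,
        "environment": env,
        "blue": blue,
        "se": se,
    })


def estimate_variance_components(records: pd.DataFrame, trait: str,
                                 design: str = "combined",
                                 environment=None,
                                 lrt: bool = False) -> VarianceComponents:
    """REML variance components under one of three all-random designs.

    ``design="combined"`` fits y = mu + G + E + GxE + eps over all
    environments; ``"within-env"`` fits y = mu + G + rep + eps inside one
    environment (pass ``environment=`` when several are present);
    ``"env-as-replicate"`` fits y = mu + G + eps treating environments as
    replicates (the visual-score case).

    Balanced complete grids use an exact sufficient-statistic reduction of
    the restricted likelihood; unbalanced data use the dense generic path.
    With ``lrt=True`` each component is tested against zero by a
    restricted-likelihood-ratio test (0.5 chi2_0 + 0.5 chi2_1 reference),
    and components with p < 0.01 are starred in ``significance``.
    """
    rec = validate_records(records)
    rec = rec[rec["trait"] == trait]
    if rec.empty:
        raise StructureError(f"no records for trait {trait!r}")
    if design == "within-env":
        if environment is None:
            envs = rec["environment"].unique()
            if len(envs) != 1:
                raise StructureError(
                    "within-env design with several environments: pass environment="
                )
            environment = envs[0]
        rec = rec[rec["environment"] == environment]
        return _vc_within(rec, trait, lrt)
    if design == "combined":
        if rec["environment"].nunique() < 2:
            raise StructureError("combined design requires >= 2 environments")
        return _vc_combined(rec, trait, lrt)
    if design == "env-as-replicate":
        return _vc_env_as_rep(rec, trait, lrt)
    raise InvalidConfigError(f"unknown design {design!r}")


def _check_levels(rec, factor, name):
    k = rec[factor].nunique()
    if k < 2:
        raise StructureError(f"factor {name!r} has {k} level(s); need >= 2")
    return k


def _lrt_pvalue(nll_full: float, nll_drop: float) -> float:
    """Restricted LRT of one variance against 0 (boundary mixture)."""
    stat = max(nll_drop - nll_full, 0.0)
    return 0.5 * stats.chi2.sf(stat, df=1) if stat > 0 else 1.0


def _vc_combined(rec: pd.DataFrame, trait: str, lrt: bool) -> VarianceComponents:
    g = _check_levels(rec, "line", "genotype")
    e = _check_levels(rec, "environment", "environment")
    cell = rec.groupby(["line", "environment"])["value"]
    counts = cell.count().unstack().to_numpy(dtype=float)
    balanced = (not np.isnan(counts).any()) and (counts == counts.flat[0]).all()
    mu = float(rec["value"].mean())
    if balanced:
        r = int(counts.flat[0])
        y = rec["value"].to_numpy(dtype=float)
        cm = cell.mean().unstack().to_numpy()       # g x e cell means
        line_m = cm.mean(axis=1)
        env_m = cm.mean(axis=0)
        grand = cm.mean()
        ss_G = e * r * float(((line_m - grand) ** 2).sum())
        ss_E = g * r * float(((env_m - grand) ** 2).sum())
        inter = cm - line_m[:, None] - env_m[None, :] + grand
        ss_GE = r * float((inter ** 2).sum())
        ss_within = float((y ** 2).sum()) - r * float((cm ** 2).sum())
        coeffs = np.array([
            [e * r, 0.0, r, 1.0],
            [0.0, g * r, r, 1.0],
            [0.0, 0.0, r, 1.0],
        ])
        ss = np.array([ss_G, ss_E, ss_GE])
        df = np.array([g - 1.0, e - 1.0, (g - 1.0) * (e - 1.0)])
        extra_df = g * e * (r - 1.0)

        def fit(active=(0, 1, 2, 3)):
            sub = coeffs[:, list(active)]
            th, nll = _reml.reml_balanced_classes(
                ss, df, sub, extra_ss=max(ss_within, 0.0), extra_df=extra_df,
                residual_index=len(active) - 1)
            full = np.zeros(4)
            full[list(active)] = th
            return full, nll

        theta, nll = fit()
        sig = {}
        if lrt:
            for i, name in enumerate(["var_G", "var_E", "var_GE"]):
                _, nll0 = fit(tuple(j for j in range(4) if j != i))
                sig[name] = _lrt_pvalue(nll, nll0)
        vG, vE, vGE, ve = theta
    else:
        if len(rec) > 4000:
            raise StructureError(
                "unbalanced combined REML limited to 4000 records; "
                "collapse to cell means first"
            )
        from .kernels import incidence_matrices
        inc = incidence_matrices(rec)
        cell_ids = pd.factorize(
            rec["line"].astype(str) + "\x1f" + rec["environment"].astype(str)
        )[0]
        Zc = np.zeros((len(rec), cell_ids.max() + 1))
        Zc[np.arange(len(rec)), cell_ids] = 1.0
        structures = [inc.Z_L @ inc.Z_L.T, inc.Z_E @ inc.Z_E.T, Zc @ Zc.T]
        y = rec["value"].to_numpy(dtype=float)
        theta, beta, nll = _reml.reml_dense(y, np.ones((len(y), 1)), structures)
        vG, vE, vGE, ve = theta
        mu = float(beta[0])
        sig = {}
        if lrt:
            for i, name in enumerate(["var_G", "var_E", "var_GE"]):
                sub = [s for j, s in enumerate(structures) if j != i]
                _, _, nll0 = _reml.reml_dense(y, np.ones((len(y), 1)), sub)
                sig[name] = _lrt_pvalue(nll, nll0)
        r = float(len(rec)) / (g * e)
    return VarianceComponents(
        var_G=float(vG), var_E=float(vE), var_GE=float(vGE), var_e=float(ve),
        n_env=e, n_rep=float(r), grand_mean=mu, design="combined",
        significance=sig,
    )


def _vc_within(rec: pd.DataFrame, trait: str, lrt: bool) -> VarianceComponents:
    g = _check_levels(rec, "line", "genotype")
    if rec["value"].nunique() == 1:
        return VarianceComponents(var_G=0.0, var_e=0.0, var_rep=0.0, n_env=1,
                                  n_rep=max(rec.groupby("line").size().mean(), 1.0),
                                  grand_mean=float(rec["value"].iloc[0]),
                                  design="within-env")
    nrep = _check_levels(rec, "replicate", "replicate")
    counts = rec.groupby(["line", "replicate"])["value"].count().unstack()
    balanced = (not counts.isna().any().any()) and (counts.to_numpy() == 1).all()
    mu = float(rec["value"].mean())
    if balanced:
        cm = rec.pivot_table(index="line", columns="replicate", values="value").to_numpy()
        line_m = cm.mean(axis=1)
        rep_m = cm.mean(axis=0)
        grand = cm.mean()
        ss_G = nrep * float(((line_m - grand) ** 2).sum())
        ss_R = g * float(((rep_m - grand) ** 2).sum())
        inter = cm - line_m[:, None] - rep_m[None, :] + grand
        ss_res = float((inter ** 2).sum())
        coeffs = np.array([
            [nrep, 0.0, 1.0],
            [0.0, g, 1.0],
            [0.0, 0.0, 1.0],
        ])
        ss = np.array([ss_G, ss_R, ss_res])
        df = np.array([g - 1.0, nrep - 1.0, (g - 1.0) * (nrep - 1.0)])
        theta, nll = _reml.reml_balanced_classes(ss, df, coeffs)
        sig = {}
        if lrt:
            for i, name in enumerate(["var_G", "var_rep"]):
                sub = coeffs[:, [j for j in range(3) if j != i]]
                _, nll0 = _reml.reml_balanced_classes(ss, df, sub)
                sig[name] = _lrt_pvalue(nll, nll0)
        vG, vR, ve = theta
        r_eff = float(nrep)
    else:
        from .kernels import incidence_matrices
        inc = incidence_matrices(rec)
        rep_ids = pd.factorize(rec["replicate"])[0]
        Zr = np.zeros((len(rec), rep_ids.max() + 1))
        Zr[np.arange(len(rec)), rep_ids] = 1.0
        y = rec["value"].to_numpy(dtype=float)
        structures = [inc.Z_L @ inc.Z_L.T, Zr @ Zr.T]
        theta, beta, nll = _reml.reml_dense(y, np.ones((len(y), 1)), structures)
        vG, vR, ve = theta
        mu = float(beta[0])
        sig = {}
        if lrt:
            _, _, nll0 = _reml.reml_dense(y, np.ones((len(y), 1)), structures[1:])
            sig["var_G"] = _lrt_pvalue(nll, nll0)
        r_eff = float(len(rec)) / g
    return VarianceComponents(
        var_G=float(vG), var_e=float(ve), var_rep=float(vR), n_env=1,
        n_rep=r_eff, grand_mean=mu, design="within-env", significance=sig,
    )


def _vc_env_as_rep(rec: pd.DataFrame, trait: str, lrt: bool) -> VarianceComponents:
    g = _check_levels(rec, "line", "genotype")
    l = _check_levels(rec, "environment", "environment")
    counts = rec.groupby("line")["value"].count()
    mu = float(rec["value"].mean())
    if rec["value"].nunique() == 1:
        return VarianceComponents(var_G=0.0, var_e=0.0, n_env=l, n_rep=float(l),
                                  grand_mean=mu, design="env-as-replicate")
    if (counts == l).all():
        cm = rec.pivot_table(index="line", columns="environment",
                             values="value", aggfunc="mean").to_numpy()
        line_m = cm.mean(axis=1)
        grand = cm.mean()
        ss_G = l * float(((line_m - grand) ** 2).sum())
        ss_within = float(((cm - line_m[:, None]) ** 2).sum())
        coeffs = np.array([[l, 1.0]])
        theta, nll = _reml.reml_balanced_classes(
            np.array([ss_G]), np.array([g - 1.0]), coeffs,
            extra_ss=ss_within, extra_df=g * (l - 1.0), residual_index=1)
        sig = {}
        if lrt:
            _, nll0 = _reml.reml_balanced_classes(
                np.array([ss_G]), np.array([g - 1.0]), coeffs[:, 1:],
                extra_ss=ss_within, extra_df=g * (l - 1.0), residual_index=0)
            sig["var_G"] = _lrt_pvalue(nll, nll0)
        vG, ve = theta
    else:
        from .kernels import incidence_matrices
        inc = incidence_matrices(rec)
        y = rec["value"].to_numpy(dtype=float)
        theta, beta, nll = _reml.reml_dense(
            y, np.ones((len(y), 1)), [inc.Z_L @ inc.Z_L.T])
        vG, ve = theta
        mu = float(beta[0])
        sig = {}
        if lrt:
            _, _, nll0 = _reml.reml_dense(y, np.ones((len(y), 1)), [])
            sig["var_G"] = _lrt_pvalue(nll, nll0)
    return VarianceComponents(
        var_G=float(vG), var_e=float(ve), n_env=l, n_rep=float(l),
        grand_mean=mu, design="env-as-replicate", significance=sig,
    )


@dataclass
class CorrelationResult:
    corr: pd.DataFrame
    pvalues: pd.DataFrame
    n_shared: int


def trait_correlations(tables: dict) -> CorrelationResult:
    """Pairwise Pearson correlations of BLUEs over shared lines.

    ``tables`` maps a label (e.g. environment or trait name) to a BlueTable
    DataFrame with columns ``line`` and ``blue`` (a ``value`` column is also
    accepted). At least two tables sharing at least three lines are
    required.
    """
    if len(tables) < 2:
        raise InsufficientOverlapError("need >= 2 tables to correlate")
    series = {}
    for label, tab in tables.items():
        col = "blue" if "blue" in tab.columns else "value"
        s = tab.set_index("line")[col].astype(float)
        series[label] = s[~s.index.duplicated()]
    shared = None
    for s in series.values():
        shared = s.index if shared is None else shared.intersection(s.index)
    if shared is None or len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {0 if shared is None else len(shared)} shared lines (< 3)"
        )
    labels = list(series)
    k = len(labels)
    corr = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(series[labels[i]].loc[shared],
                                  series[labels[j]].loc[shared])
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    return CorrelationResult(
        corr=pd.DataFrame(corr, index=labels, columns=labels),
        pvalues=pd.DataFrame(pval, index=labels, columns=labels),
        n_shared=len(shared),
    )
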