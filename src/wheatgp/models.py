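"""Reaction-norm GBLUP models.

Seven nested random-effect models for multi-environment records
y_ij (line i, environment j), all containing an intercept, a random
environment main effect E and an iid line main effect L:

====== =======================
model  terms
====== =======================
1      E + L
2      E + L + G
3      E + L + G + GxE
4      E + L + A
5      E + L + A + AxE
6      E + L + G + A
7      E + L + G + A + GxE + AxE
====== =======================

Record-level covariance structures: E: Z_E Z_E' s2_E; L: Z_L Z_L' s2_L;
G: Z_L G Z_L' s2_g; A: Z_L A Z_L' s2_a; GxE: (Z_L G Z_L') o (Z_E Z_E')
s2_gE; AxE analogously; residual iid s2_e.

Estimation is a Gibbs sampler over one Gaussian block per term.  Each
record-level kernel K_t is eigendecomposed once, K_t = U_t D_t U_t', and
the effect is parameterized as u_t = U_t b_t with b_t ~ N(0, s2_t D_t);
because the U_t columns are orthonormal, the full conditional of b_t is
diagonal and a sweep costs one pair of matrix-vector products per term.
Variances carry scaled-inverse-chi-square priors; held-out responses are
imputed from the current posterior predictive each sweep (data
augmentation), which makes masked-record prediction a by-product of
fitting.

:func:`solve_gblup_fixed_variance` is a deterministic Henderson-style
mixed-model solver at fixed variance ratios, used as an independent oracle
for the sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .containers import IncidenceMaps, Kernel, validate_records
from .exceptions import (
    InvalidConfigError,
    NumericalError,
    PredictionError,
    ValidationError,
)
from .kernels import incidence_matrices

logger = logging.getLogger(__name__)

MODEL_TERMS = {
    1: ("E", "L"),
    2: ("E", "L", "G"),
    3: ("E", "L", "G", "GxE"),
    4: ("E", "L", "A"),
    5: ("E", "L", "A", "AxE"),
    6: ("E", "L", "G", "A"),
    7: ("E", "L", "G", "A", "GxE", "AxE"),
}
_TERMS_TO_MODEL = {terms: num for num, terms in MODEL_TERMS.items()}


@dataclass(frozen=True)
class ModelSpec:
    """Term set of one model; ``model_number`` and ``terms`` are a bijection."""

    model_number: int

    def __post_init__(self) -> None:
        if self.model_number not in MODEL_TERMS:
            raise InvalidConfigError(
                f"model_number must be 1..7, got {self.model_number}"
            )

    @property
    def terms(self) -> tuple:
        return MODEL_TERMS[self.model_number]

    @classmethod
    def from_terms(cls, terms) -> "ModelSpec":
        key = tuple(terms)
        if key not in _TERMS_TO_MODEL:
            raise InvalidConfigError(f"no model with terms {terms}")
        return cls(_TERMS_TO_MODEL[key])

    @property
    def needs_g(self) -> bool:
        return any(t in self.terms for t in ("G", "GxE"))

    @property
    def needs_a(self) -> bool:
        return any(t in self.terms for t in ("A", "AxE"))


@dataclass
class FitConfig:
    """Sampler settings: chain length, thinning, prior hyperparameters."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise InvalidConfigError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise InvalidConfigError("thin must be >= 1")
        if self.prior_df <= 0:
            raise InvalidConfigError("prior_df must be > 0")
        if not 0.0 < self.prior_r2 < 1.0:
            raise InvalidConfigError("prior_r2 must be in (0, 1)")


def build_model(spec: ModelSpec, records: pd.DataFrame,
                g: Kernel | None = None, a: Kernel | None = None,
                inc: IncidenceMaps | None = None) -> dict:
    """Assemble the ordered record-level covariance structures of a model.

    Returns a dict term -> (n x n) covariance structure (unit variance);
    the iid residual is implicit.
    """
    rec = validate_records(records)
    if spec.needs_g and g is None:
        raise InvalidConfigError(f"model {spec.model_number} requires a G kernel")
    if spec.needs_a and a is None:
        raise InvalidConfigError(f"model {spec.model_number} requires an A kernel")
    if inc is None:
        ref = g if g is not None else a
        inc = incidence_matrices(rec, line_ids=None if ref is None else ref.ids)
    structures = {}
    same_env = None
    for term in spec.terms:
        if term == "E":
            structures["E"] = inc.Z_E @ inc.Z_E.T
        elif term == "L":
            structures["L"] = inc.Z_L @ inc.Z_L.T
        elif term in ("G", "A"):
            k = g if term == "G" else a
            structures[term] = inc.Z_L @ k.align(inc.line_ids).values @ inc.Z_L.T
        elif term in ("GxE", "AxE"):
            k = g if term == "GxE" else a
            main = inc.Z_L @ k.align(inc.line_ids).values @ inc.Z_L.T
            if same_env is None:
                same_env = inc.Z_E @ inc.Z_E.T
            structures[term] = main * same_env
    return structures


# ---------------------------------------------------------------------------
# eigendecompositions of record-level kernels


def _onehot_eig(Z: np.ndarray):
    """Eigenpairs of Z Z' for one-hot Z: vectors z_j/sqrt(c_j), values c_j."""
    counts = Z.sum(axis=0)
    keep = counts > 0
    U = Z[:, keep] / np.sqrt(counts[keep])
    return U, counts[keep].astype(float)

def _line_kernel_eig(Z_L: np.ndarray, K: np.ndarray, tol: float = 1e-9):
    """Eigenpairs of Z_L K Z_L' when every line has the same record count."""
    counts = Z_L.sum(axis=0)
    c = counts[0]
    w, V = linalg.eigh((K + K.T) / 2.0)
    keep = w > tol * max(w.max(), 1e-300)
    U = (Z_L @ V[:, keep]) / np.sqrt(c)
    return U, c * w[keep]


def _generic_eig(Kr: np.ndarray, tol: float = 1e-9):
    w, V = linalg.eigh((Kr + Kr.T) / 2.0)
    keep = w > tol * max(w.max(), 1e-300)
    return V[:, keep], w[keep]


def precompute_term_eigs(spec: ModelSpec, records: pd.DataFrame,
                         g: Kernel | None = None, a: Kernel | None = None,
                         inc: IncidenceMaps | None = None) -> dict:
    """Eigendecompose each term's record-level kernel (reusable across fits).

    Fit results depend on the record set and kernels only through these
    pairs, so cross-validation refits with different masks can share one
    precomputation. Structured fast paths cover one-hot main effects,
    equal-record-count line kernels, and per-environment interaction
    blocks; anything else falls back to a dense eigendecomposition.
    """
    rec = validate_records(records)
    if inc is None:
        ref = g if g is not None else a
        inc = incidence_matrices(rec, line_ids=None if ref is None else ref.ids)
    eigs = {}
    env_codes = np.argmax(inc.Z_E, axis=1)
    for term in spec.terms:
        if term == "E":
            eigs[term] = _onehot_eig(inc.Z_E)
        elif term == "L":
            eigs[term] = _onehot_eig(inc.Z_L)
        elif term in ("G", "A"):
            K = (g if term == "G" else a).align(inc.line_ids).values
            counts = inc.Z_L.sum(axis=0)
            pos = counts > 0
            if np.all(counts[pos] == counts[pos][0]) and pos.all():
                eigs[term] = _line_kernel_eig(inc.Z_L, K)
            else:
                eigs[term] = _generic_eig(inc.Z_L @ K @ inc.Z_L.T)
        elif term in ("GxE", "AxE"):
            K = (g if term == "GxE" else a).align(inc.line_ids).values
            n = inc.Z_L.shape[0]
            Us, ds = [], []
            ok = True
            blocks = []
            for j in range(inc.Z_E.shape[1]):
                idx = np.flatnonzero(env_codes == j)
                if idx.size == 0:
                    continue
                lines_j = np.argmax(inc.Z_L[idx], axis=1)
                blocks.append((idx, lines_j))
                if len(set(lines_j)) != len(lines_j):
                    ok = False
            if ok:
                for idx, lines_j in blocks:
                    Ksub = K[np.ix_(lines_j, lines_j)]
                    w, V = linalg.eigh((Ksub + Ksub.T) / 2.0)
                    keep = w > 1e-9 * max(w.max(), 1e-300)
                    Uj = np.zeros((n, int(keep.sum())))
                    Uj[idx] = V[:, keep]
                    Us.append(Uj)
                    ds.append(w[keep])
                eigs[term] = (np.hstack(Us), np.concatenate(ds))
            else:
                main = inc.Z_L @ K @ inc.Z_L.T
                eigs[term] = _generic_eig(main * (inc.Z_E @ inc.Z_E.T))
    return eigs


# ---------------------------------------------------------------------------
# Gibbs sampler


class ReactionNormGBLUP(BaseEstimator):
    """Bayesian multi-kernel GBLUP with optional GxE interaction kernels.

    Parameters
    ----------
    model : int, 1..7
        Which term set to fit (see module docstring).
    n_iter, burn_in, thin : int
        Chain length, discarded sweeps, retention stride.
    seed : int
        Seed; identical seed + inputs give bitwise-identical summaries.
    prior_df : float
        Degrees of freedom of every scaled-inverse-chi-square variance prior.
    prior_r2 : float
        Proportion of var(y) split equally across terms to set prior modes;
        the residual prior mode is (1 - prior_r2) var(y).
    env_fixed : bool
        Treat environment effects as unshrunk (flat prior) instead of random.

    Attributes (after fit)
    ----------------------
    mu_ : float — posterior-mean intercept.
    var_components_ : dict term -> posterior-mean variance (incl. "residual").
    yhat_ : ndarray — posterior-mean signal (mu + all terms) per record,
        defined for masked records too.
    effects_ : dict term -> posterior-mean record-level effect.
    chains_ : DataFrame of retained variance and intercept samples.
    """

    def __init__(self, model: int = 2, n_iter: int = 12_000,
                 burn_in: int = 2_000, thin: int = 5, seed: int = 0,
                 prior_df: float = 5.0, prior_r2: float = 0.5,
                 env_fixed: bool = False):
        self.model = model
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_df = prior_df
        self.prior_r2 = prior_r2
        self.env_fixed = env_fixed

    # -- fitting -----------------------------------------------------------

    def fit(self, records: pd.DataFrame, g: Kernel | None = None,
            a: Kernel | None = None, mask: np.ndarray | None = None,
            term_eigs: dict | None = None,
            fixed_variances: dict | None = None) -> "ReactionNormGBLUP":
        """Run the sampler on long-format records.

        ``mask`` flags records whose responses are held out (predicted by
        data augmentation). ``fixed_variances`` (term -> s2, plus
        "residual") disables variance sampling — the oracle-comparison
        mode. ``term_eigs`` injects precomputed eigendecompositions.
        """
        cfg = FitConfig(n_iter=self.n_iter, burn_in=self.burn_in,
                        thin=self.thin, seed=self.seed,
                        prior_df=self.prior_df, prior_r2=self.prior_r2)
        spec = ModelSpec(self.model)
        rec = validate_records(records)
        y = rec["value"].to_numpy(dtype=float)
        n = len(y)
        if mask is None:
            mask = np.zeros(n, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.all():
            raise ValidationError("at least one observed response required")
        if not np.isfinite(y[~mask]).all():
            raise ValidationError("non-finite responses among observed records")
        ref = g if g is not None else a
        inc = incidence_matrices(rec, line_ids=None if ref is None else ref.ids)
        if term_eigs is None:
            term_eigs = precompute_term_eigs(spec, rec, g, a, inc)
        terms = list(spec.terms)

        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 17]))
        y_obs = y[~mask]
        vy = float(np.var(y_obs)) if len(y_obs) > 1 else 1.0
        vy = vy or 1.0
        nu = cfg.prior_df
        # prior mode nu*S/(nu+2) = share  =>  S = share (nu+2)/nu
        share = cfg.prior_r2 * vy / len(terms)
        S_term = {t: share * (nu + 2.0) / nu for t in terms}
        S_e = (1.0 - cfg.prior_r2) * vy * (nu + 2.0) / nu

        sig2 = {t: share for t in terms}
        sig2_e = (1.0 - cfg.prior_r2) * vy
        if fixed_variances is not None:
            for t in terms:
                if t not in fixed_variances:
                    raise InvalidConfigError(f"fixed variance for {t} missing")
                sig2[t] = float(fixed_variances[t])
            sig2_e = float(fixed_variances.get("residual", sig2_e))

        U = {t: term_eigs[t][0] for t in terms}
        d = {t: np.asarray(term_eigs[t][1], dtype=float) for t in terms}
        b = {t: np.zeros(U[t].shape[1]) for t in terms}
        fit_t = {t: np.zeros(n) for t in terms}
        mu = float(np.mean(y_obs))
        y_aug = y.copy()
        y_aug[mask] = mu

        keep = max((cfg.n_iter - cfg.burn_in) // cfg.thin, 1)
        sum_yhat = np.zeros(n)
        sum_fit = {t: np.zeros(n) for t in terms}
        sum_b = {t: np.zeros(U[t].shape[1]) for t in terms}
        sum_mu = 0.0
        chain_rows = []
        kept = 0

        total_fit = np.zeros(n)
        for sweep in range(cfg.n_iter):
            # intercept (flat prior)
            e = y_aug - total_fit
            mu = rng.normal(e.mean(), np.sqrt(sig2_e / n))
            # one Gaussian block per term
            for t in terms:
                e = y_aug - mu - total_fit + fit_t[t]
                r = U[t].T @ e
                if self.env_fixed and t == "E":
                    prec = np.full(len(r), 1.0 / sig2_e)
                else:
                    prec = 1.0 / sig2_e + 1.0 / (sig2[t] * d[t])
                mean = (r / sig2_e) / prec
                b[t] = mean + rng.standard_normal(len(r)) / np.sqrt(prec)
                new_fit = U[t] @ b[t]
                total_fit += new_fit - fit_t[t]
                fit_t[t] = new_fit
            # variances
            if fixed_variances is None:
                for t in terms:
                    if self.env_fixed and t == "E":
                        continue
                    sc = float(np.sum(b[t] ** 2 / d[t]))
                    df = nu + len(b[t])
                    sig2[t] = (sc + nu * S_term[t]) / rng.chisquare(df)
                resid = y_aug - mu - total_fit
                sig2_e = (float(resid @ resid) + nu * S_e) / rng.chisquare(nu + n)
            # data augmentation for held-out responses
            if mask.any():
                y_aug[mask] = (mu + total_fit[mask]
                               + rng.standard_normal(int(mask.sum()))
                               * np.sqrt(sig2_e))
            if sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0:
                kept += 1
                sum_mu += mu
                sum_yhat += mu + total_fit
                for t in terms:
                    sum_fit[t] += fit_t[t]
                    sum_b[t] += b[t]
                row = {"mu": mu, "residual": sig2_e}
                row.update({t: sig2[t] for t in terms})
                chain_rows.append(row)

        self.spec_ = spec
        self.inc_ = inc
        self.records_ = rec
        self.mask_ = mask
        self.mu_ = sum_mu / kept
        self.yhat_ = sum_yhat / kept
        self.effects_ = {t: sum_fit[t] / kept for t in terms}
        self.coef_b_ = {t: sum_b[t] / kept for t in terms}
        self.var_components_ = {t: float(np.mean([r[t] for r in chain_rows]))
                                for t in terms}
        self.var_components_["residual"] = float(
            np.mean([r["residual"] for r in chain_rows]))
        self.chains_ = pd.DataFrame(chain_rows)
        self._build_effect_tables()
        return self

    def _build_effect_tables(self) -> None:
        rec = self.records_
        env = rec["environment"].to_numpy()
        line = rec["line"].to_numpy()
        tabs = {}
        for t, vals in self.effects_.items():
            df = pd.DataFrame({"env": env, "line": line, "val": vals})
            if t == "E":
                tabs[t] = df.groupby("env")["val"].mean().to_dict()
            elif t in ("L", "G", "A"):
                tabs[t] = df.groupby("line")["val"].mean().to_dict()
            else:
                tabs[t] = df.groupby(["line", "env"])["val"].mean().to_dict()
        self.effect_tables_ = tabs

    # -- prediction --------------------------------------------------------

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Sum of posterior-mean effects for each record.

        Effects with no information (unseen environment's E, unseen line's
        L, unseen line-environment interaction cell) contribute zero.
        Lines absent from every kernel and from training are an error.
        """
        rec = validate_records(records)
        known_lines = set(self.inc_.line_ids)
        unknown = sorted(set(rec["line"]) - known_lines)
        if unknown:
            raise PredictionError(
                f"lines unknown to the fitted model: {unknown[:5]}"
            )
        out = np.full(len(rec), self.mu_, dtype=float)
        tabs = self.effect_tables_
        for i, (line, env) in enumerate(zip(rec["line"], rec["environment"])):
            for t in self.spec_.terms:
                tab = tabs[t]
                if t == "E":
                    out[i] += tab.get(env, 0.0)
                elif t in ("L", "G", "A"):
                    out[i] += tab.get(line, 0.0)
                else:
                    out[i] += tab.get((line, env), 0.0)
        return out


def fit_gibbs(spec: ModelSpec, records: pd.DataFrame, cfg: FitConfig,
              g: Kernel | None = None, a: Kernel | None = None,
              mask: np.ndarray | None = None,
              term_eigs: dict | None = None,
              fixed_variances: dict | None = None) -> ReactionNormGBLUP:
    """Functional wrapper over :class:`ReactionNormGBLUP`."""
    est = ReactionNormGBLUP(model=spec.model_number, n_iter=cfg.n_iter,
                            burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed,
                            prior_df=cfg.prior_df, prior_r2=cfg.prior_r2)
    return est.fit(records, g=g, a=a, mask=mask, term_eigs=term_eigs,
                   fixed_variances=fixed_variances)


def solve_gblup_fixed_variance(records: pd.DataFrame, structures: dict,
                               varcomps: dict,
                               mask: np.ndarray | None = None) -> dict:
    """Deterministic mixed-model solution at fixed variance components.

    GLS intercept and BLUP effects for the multi-kernel model
    y = mu + sum_t u_t + e with cov(u_t) = s2_t K_t, computed on the
    observed records and propagated to all records through the kernels:

        mu    = (1' V^-1 1)^-1 1' V^-1 y
        u_t   = s2_t K_t[:, obs] V^-1 (y_obs - mu)

    ``structures`` is the output of :func:`build_model`; ``varcomps`` maps
    each term plus "residual" to its (positive) variance.
    """
    rec = validate_records(records)
    y = rec["value"].to_numpy(dtype=float)
    n = len(y)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    obs = ~mask
    for t in list(structures) + ["residual"]:
        if varcomps.get(t, 0.0) <= 0:
            raise InvalidConfigError(f"variance for {t!r} must be > 0")
    V = varcomps["residual"] * np.eye(int(obs.sum()))
    for t, K in structures.items():
        V += varcomps[t] * K[np.ix_(obs, obs)]
    try:
        c = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError as e:
        raise NumericalError(
            f"singular system (cond={np.linalg.cond(V):.3g})"
        ) from e
    ones = np.ones(int(obs.sum()))
    Vinv_y = linalg.cho_solve(c, y[obs], check_finite=False)
    Vinv_1 = linalg.cho_solve(c, ones, check_finite=False)
    mu = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    w = linalg.cho_solve(c, y[obs] - mu, check_finite=False)
    effects = {t: varcomps[t] * (K[:, obs] @ w) for t, K in structures.items()}
    yhat = mu + sum(effects.values())
    return {"mu": mu, "effects": effects, "yhat": yhat}


def predict(fit: ReactionNormGBLUP, records: pd.DataFrame) -> np.ndarray:
    """Functional wrapper over :meth:`ReactionNormGBLUP.predict`."""
    return fit.predict(records)
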