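"""Mixed-linear-model association scan and linkage-disequilibrium decay.

The scan fits, for each marker m,

    y = W alpha + x_m b_m + u + e,   u ~ N(0, K s2_u),  e ~ N(0, s2_e I)

where W holds an intercept plus principal-component covariates (the Q of a
Q+K model) and K is a genomic kinship. Variance components are estimated by
REML on the *null* model (no marker) through the eigendecomposition of K,
then reused for every marker test — the P3D ("population parameters
previously determined") approximation; exact per-marker REML is available
behind ``use_p3d=False``. Each marker gets a generalized-least-squares Wald
test, an allele-substitution effect, the proportion of (decorrelated)
residual variance it explains, and its minor allele frequency.

Family-wise significance uses the Bonferroni cutoff
-log10(alpha / n_markers).

LD decay is the squared dose correlation of same-chromosome marker pairs
within a sliding window of adjacent markers, with a moving-average smooth
over genetic distance and the distance at which the smoothed r2 first drops
below a threshold (0.2 by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .containers import Kernel, MarkerMatrix, validate_map
from .exceptions import InvalidConfigError, ValidationError

logger = logging.getLogger(__name__)


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Genome-wide -log10(P) cutoff: -log10(alpha / n_markers)."""
    if not 0.0 < alpha < 1.0:
        raise InvalidConfigError("alpha must be in (0, 1)")
    if n_markers < 1:
        raise InvalidConfigError("n_markers must be >= 1")
    return float(-np.log10(alpha / n_markers))


def pca_covariates(m: MarkerMatrix, n_pcs: int = 3):
    """Principal-component scores of the centered dose matrix.

    Returns (scores DataFrame indexed by line, variance-explained
    fractions). Requires an imputed matrix.
    """
    if m.missing_mask.any():
        raise ValidationError("impute missing doses before PCA")
    if n_pcs > min(m.n_lines, m.n_markers):
        raise InvalidConfigError(
            f"n_pcs={n_pcs} exceeds min(lines, markers)="
            f"{min(m.n_lines, m.n_markers)}"
        )
    X = m.doses - m.doses.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = float((s ** 2).sum())
    scores = U[:, :n_pcs] * s[:n_pcs]
    frac = (s[:n_pcs] ** 2) / total if total > 0 else np.zeros(n_pcs)
    return (
        pd.DataFrame(scores, index=m.line_ids,
                     columns=[f"PC{i + 1}" for i in range(n_pcs)]),
        frac,
    )


def _null_reml_h2(yt: np.ndarray, Wt: np.ndarray, lam: np.ndarray) -> float:
    """Profiled REML for the rotated null model.

    Rotated observations are independent with variance
    v_i = s2_u lam_i + s2_e; parameterize h = s2_u/(s2_u+s2_e) and profile
    the total variance out analytically.
    """
    n, p = Wt.shape

    def nll(h):
        v = h * lam + (1.0 - h)
        w = 1.0 / v
        WtW = (Wt * w[:, None]).T @ Wt
        Wty = (Wt * w[:, None]).T @ yt
        try:
            beta = np.linalg.solve(WtW, Wty)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Wt @ beta
        rss = float(r * w @ r)
        sign, logdet = np.linalg.slogdet(WtW)
        if sign <= 0:
            return np.inf
        return ((n - p) * np.log(rss) + np.log(v).sum() + logdet)

    res = optimize.minimize_scalar(nll, bounds=(1e-6, 1.0 - 1e-6),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


@dataclass
class _Rotation:
    yt: np.ndarray
    Wt: np.ndarray
    v: np.ndarray          # per-observation variance (unit total scale)
    h2: float


class MixedLinearGWAS(BaseEstimator):
    """Q+K single-marker mixed-model scan (P3D by default).

    Parameters
    ----------
    n_pcs : int
        Principal-component covariates from the marker matrix (0 disables).
    alpha : float
        Family-wise error rate for the Bonferroni threshold.
    use_p3d : bool
        Estimate the variance ratio once under the null (True) or by exact
        REML for every marker (False; slow, for small panels).

    Attributes (after fit)
    ----------------------
    results_ : DataFrame of association records (one row per tested marker):
        marker, chromosome, cM, Mb, neg_log10_p, effect, r2_marker, maf,
        favorable_allele.
    threshold_ : float — Bonferroni -log10(P) cutoff for the tested panel.
    h2_null_ : float — null-model variance ratio s2_u/(s2_u + s2_e).
    pc_variance_ : ndarray — variance fractions of the PC covariates.
    """

    def __init__(self, n_pcs: int = 3, alpha: float = 0.05,
                 use_p3d: bool = True):
        self.n_pcs = n_pcs
        self.alpha = alpha
        self.use_p3d = use_p3d

    def fit(self, markers: MarkerMatrix, y, kinship: Kernel | None = None,
            gmap: pd.DataFrame | None = None) -> "MixedLinearGWAS":
        """Scan all markers against per-line phenotypes (e.g. BLUEs).

        ``y`` may be a Series indexed by line or an array aligned with
        ``markers.line_ids``. ``kinship`` defaults to the VanRaden-scaled
        genomic relationship built from the same panel. Monomorphic markers
        are skipped with a log entry.
        """
        from .kernels import genomic_relationship, impute_missing

        if isinstance(y, pd.Series):
            missing = [l for l in markers.line_ids if l not in y.index]
            if missing:
                raise ValidationError(f"phenotypes missing for lines {missing[:5]}")
            y = y.loc[list(markers.line_ids)].to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        if len(y) != markers.n_lines:
            raise ValidationError("y length does not match marker lines")
        if not np.isfinite(y).all():
            raise ValidationError("non-finite phenotypes")
        m = impute_missing(markers) if markers.missing_mask.any() else markers
        if kinship is None:
            kinship = genomic_relationship(m, scale="vanraden")
        K = kinship.align(m.line_ids).values
        n = len(y)
        if self.n_pcs > 0:
            scores, frac = pca_covariates(m, self.n_pcs)
            W = np.column_stack([np.ones(n), scores.to_numpy()])
            self.pc_variance_ = frac
        else:
            W = np.ones((n, 1))
            self.pc_variance_ = np.array([])
        lam, Q = np.linalg.eigh((K + K.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        yt = Q.T @ y
        Wt = Q.T @ W
        Xt = Q.T @ m.doses
        h2 = _null_reml_h2(yt, Wt, lam)
        self.h2_null_ = h2

        p_freq = m.allele_freq()
        maf = np.minimum(p_freq, 1.0 - p_freq)
        poly = maf > 0
        n_skip = int((~poly).sum())
        if n_skip:
            logger.info("skipping %d monomorphic markers", n_skip)

        if self.use_p3d:
            res = self._scan_p3d(yt, Wt, Xt, lam, h2, poly)
        else:
            res = self._scan_exact(yt, Wt, Xt, lam, poly)

        out = pd.DataFrame({
            "marker": m.marker_ids[poly],
            "neg_log10_p": res["neg_log10_p"],
            "effect": res["effect"],
            "r2_marker": res["r2"],
            "maf": maf[poly],
        })
        out["favorable_allele"] = np.where(out["effect"] >= 0, "counted",
                                           "alternate")
        if gmap is not None:
            gm = validate_map(gmap).set_index("marker")
            out.insert(1, "chromosome",
                       [gm["chromosome"].get(mk, "") for mk in out["marker"]])
            out.insert(2, "cM", [gm["cM"].get(mk, np.nan) for mk in out["marker"]])
            out.insert(3, "Mb", [gm["Mb"].get(mk, np.nan) for mk in out["marker"]])
        self.results_ = out
        self.threshold_ = bonferroni_threshold(int(poly.sum()), self.alpha)
        return self

    @staticmethod
    def _gls_marker_stats(yt, Wt, Xt, v):
        """Vectorized per-marker GLS under diagonal variances v."""
        w = 1.0 / v
        WtW = (Wt * w[:, None]).T @ Wt
        WtW_inv = np.linalg.inv(WtW)
        Wty = (Wt * w[:, None]).T @ yt
        beta0 = WtW_inv @ Wty
        r0 = yt - Wt @ beta0
        rss0 = float(r0 * w @ r0)
        # residualize each marker on W under the weights
        WtX = (Wt * w[:, None]).T @ Xt
        Xres = Xt - Wt @ (WtW_inv @ WtX)
        sxx = np.einsum("ij,ij->j", Xres * w[:, None], Xres)
        sxy = (Xres * w[:, None]).T @ r0
        ok = sxx > 1e-12
        b = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        rss1 = rss0 - b * sxy
        return b, sxx, rss0, rss1, ok

    def _scan_p3d(self, yt, Wt, Xt, lam, h2, poly):
        v = h2 * lam + (1.0 - h2)
        n, p = Wt.shape
        b, sxx, rss0, rss1, ok = self._gls_marker_stats(yt, Wt, Xt[:, poly], v)
        # per-marker residual scale at the P3D variance ratio
        sigma2 = rss1 / (n - p - 1)
        se = np.sqrt(sigma2 / np.where(sxx > 1e-12, sxx, np.nan))
        z = b / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        r2 = np.clip(1.0 - rss1 / rss0, 0.0, 1.0)
        return {
            "neg_log10_p": -np.log10(np.clip(pvals, 1e-300, None)),
            "effect": b,
            "r2": r2,
        }

    def _scan_exact(self, yt, Wt, Xt, lam, poly):
        idx = np.flatnonzero(poly)
        neg, eff, r2s = [], [], []
        for j in idx:
            Wj = np.column_stack([Wt, Xt[:, j]])
            h2 = _null_reml_h2(yt, Wj, lam)
            v = h2 * lam + (1.0 - h2)
            b, sxx, rss0, rss1, ok = self._gls_marker_stats(
                yt, Wt, Xt[:, [j]], v)
            n, p = Wj.shape
            w = 1.0 / v
            WtWj = (Wj * w[:, None]).T @ Wj
            betaj = np.linalg.solve(WtWj, (Wj * w[:, None]).T @ yt)
            rj = yt - Wj @ betaj
            sigma2 = float(rj * w @ rj) / (n - p)
            se = np.sqrt(sigma2 / sxx[0]) if sxx[0] > 1e-12 else np.nan
            z = b[0] / se if se and np.isfinite(se) else 0.0
            pv = 2.0 * stats.norm.sf(abs(z))
            neg.append(-np.log10(max(pv, 1e-300)))
            eff.append(b[0])
            r2s.append(max(0.0, 1.0 - rss1[0] / rss0))
        return {"neg_log10_p": np.array(neg), "effect": np.array(eff),
                "r2": np.array(r2s)}


def mlm_scan(y, m: MarkerMatrix, k: Kernel | None = None, n_pcs: int = 3,
             alpha: float = 0.05, use_p3d: bool = True,
             gmap: pd.DataFrame | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`MixedLinearGWAS`; returns results_."""
    est = MixedLinearGWAS(n_pcs=n_pcs, alpha=alpha, use_p3d=use_p3d)
    est.fit(m, y, kinship=k, gmap=gmap)
    return est.results_


def ld_decay(m: MarkerMatrix, gmap: pd.DataFrame, window: int = 100,
             smooth: int = 10, r2_threshold: float = 0.2):
    """Pairwise LD (r2) within a sliding window of adjacent mapped markers.

    Markers are ordered by chromosome then cM; r2 is the squared Pearson
    correlation of (mean-imputed) dose columns for all same-chromosome
    pairs at most ``window`` positions apart. The smoothed curve is a
    moving average of span ``smooth`` over distance-ordered r2 values.

    Returns (pairs DataFrame: marker_a, marker_b, distance_cM, r2;
    smoothed DataFrame: distance_cM, r2_smooth; ld_extent_cM — the distance
    where the smoothed curve first falls below ``r2_threshold``, NaN if it
    never does).
    """
    gm = validate_map(gmap)
    mapped = gm[gm["marker"].isin(set(m.marker_ids))]
    n_unmapped = m.n_markers - len(mapped)
    if n_unmapped:
        logger.info("excluding %d unmapped markers from LD", n_unmapped)
    order = mapped.sort_values(["chromosome", "cM"])
    sub = m.subset_markers(order["marker"].to_numpy(dtype=object))
    doses = sub.doses.copy()
    if np.isnan(doses).any():
        p = np.nanmean(doses, axis=0)
        idx = np.where(np.isnan(doses))
        doses[idx] = p[idx[1]]
    X = doses - doses.mean(axis=0)
    sd = X.std(axis=0)
    chrom = order["chromosome"].to_numpy()
    cm = order["cM"].to_numpy(dtype=float)
    n = X.shape[0]
    rows = []
    nm = X.shape[1]
    for lag in range(1, min(window, nm - 1) + 1):
        a = slice(0, nm - lag)
        b = slice(lag, nm)
        same = chrom[a] == chrom[b]
        denom = sd[a] * sd[b]
        valid = same & (denom > 0)
        if not valid.any():
            continue
        r = np.einsum("ij,ij->j", X[:, a], X[:, b]) / (n * denom + 1e-300)
        d = np.abs(cm[b] - cm[a])
        ia = np.flatnonzero(valid)
        for i in ia:
            rows.append((sub.marker_ids[i], sub.marker_ids[i + lag],
                         d[i], min(r[i] ** 2, 1.0)))
    pairs = pd.DataFrame(rows, columns=["marker_a", "marker_b",
                                        "distance_cM", "r2"])
    if pairs.empty:
        return pairs, pd.DataFrame(columns=["distance_cM", "r2_smooth"]), np.nan
    ordered = pairs.sort_values("distance_cM").reset_index(drop=True)
    span = max(1, min(smooth, len(ordered)))
    r2s = ordered["r2"].rolling(span, min_periods=1, center=True).mean()
    smoothed = pd.DataFrame({"distance_cM": ordered["distance_cM"],
                             "r2_smooth": r2s})
    below = smoothed[smoothed["r2_smooth"] < r2_threshold]
    extent = float(below["distance_cM"].iloc[0]) if not below.empty else np.nan
    return pairs, smoothed, extent
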