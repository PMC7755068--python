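"""Cross-validation schemes for multi-environment genomic prediction.

Three partitioning schemes over line x environment records:

* **CV1** — whole lines are assigned to folds; a test line has no record of
  any environment in training (prediction of never-phenotyped lines).
* **CV2** — individual records are assigned to folds; a test record's line
  typically keeps records from other environments in training (sparse
  testing / incomplete trials).
* **CV0** — leave-one-environment-out: every record of one environment is
  predicted from the other environments.

Accuracy is the plain Pearson correlation between predicted and observed
values computed *within* each test environment (so an unidentified
environment main effect in CV0 cannot bias it), averaged over partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Kernel, validate_records
from .exceptions import InvalidConfigError, StructureError
from .models import FitConfig, ModelSpec, fit_gibbs, precompute_term_eigs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVPartition:
    """One train/test split; record identifiers are positional indices."""

    scheme: str
    replicate: int
    fold: int
    test_records: np.ndarray
    train_records: np.ndarray


def _fold_sizes(n: int, k: int) -> np.ndarray:
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return sizes


def make_cv1_partitions(records: pd.DataFrame, k: int = 5, reps: int = 20,
                        seed: int = 0) -> list:
    """Assign lines to folds; a fold's test set is every record of its lines."""
    rec = validate_records(records)
    lines = np.array(sorted(rec["line"].unique()), dtype=object)
    if k > len(lines):
        raise InvalidConfigError(f"k={k} folds exceed {len(lines)} lines")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    line_of = rec["line"].to_numpy()
    all_idx = np.arange(len(rec))
    parts = []
    for rep in range(reps):
        perm = rng.permutation(len(lines))
        stops = np.cumsum(_fold_sizes(len(lines), k))
        start = 0
        for fold, stop in enumerate(stops):
            test_lines = set(lines[perm[start:stop]])
            start = stop
            test = all_idx[[l in test_lines for l in line_of]]
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            parts.append(CVPartition("CV1", rep, fold, test, train))
    return parts


def make_cv2_partitions(records: pd.DataFrame, k: int = 5, reps: int = 20,
                        seed: int = 0) -> list:
    """Assign individual records to folds (sparse-testing scheme)."""
    rec = validate_records(records)
    n = len(rec)
    if k > n:
        raise InvalidConfigError(f"k={k} folds exceed {n} records")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    all_idx = np.arange(n)
    parts = []
    for rep in range(reps):
        perm = rng.permutation(n)
        stops = np.cumsum(_fold_sizes(n, k))
        start = 0
        for fold, stop in enumerate(stops):
            test = np.sort(perm[start:stop])
            start = stop
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            parts.append(CVPartition("CV2", rep, fold, test, train))
    return parts


def make_cv0_partitions(records: pd.DataFrame) -> list:
    """One partition per environment: test = that environment's records."""
    rec = validate_records(records)
    envs = sorted(rec["environment"].unique())
    if len(envs) < 2:
        raise StructureError("CV0 requires >= 2 environments")
    env_of = rec["environment"].to_numpy()
    all_idx = np.arange(len(rec))
    parts = []
    for fold, env in enumerate(envs):
        test = all_idx[env_of == env]
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        parts.append(CVPartition("CV0", 0, fold, test, train))
    return parts


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def run_cv(model_specs, partitions, records: pd.DataFrame,
           g: Kernel | None = None, a: Kernel | None = None,
           cfg: FitConfig | None = None, fitter=None,
           min_test_records: int = 3) -> pd.DataFrame:
    """Fit each model on each partition and score within-environment accuracy.

    For every model x partition, test responses are masked, the model is
    refit, test records are predicted, and Pearson r between prediction and
    observation is computed separately within each environment present in
    the test set. Environments with fewer than ``min_test_records`` test
    records are skipped with a warning; constant predictions yield a
    missing (NaN) accuracy, never zero.

    ``fitter(spec, records, mask, part_seed) -> predictions for all
    records`` can replace the Gibbs sampler (testing hook). Per-partition
    sampler seeds derive as cfg.seed + partition index.

    Returns a tidy frame: scheme, model, replicate, fold, environment,
    accuracy, n_test.
    """
    rec = validate_records(records)
    if cfg is None:
        cfg = FitConfig()
    specs = [s if isinstance(s, ModelSpec) else ModelSpec(s) for s in model_specs]
    env_of = rec["environment"].to_numpy()
    y = rec["value"].to_numpy(dtype=float)
    rows = []
    for spec in specs:
        eigs = None
        if fitter is None:
            eigs = precompute_term_eigs(spec, rec, g, a)
        for p_idx, part in enumerate(partitions):
            mask = np.zeros(len(rec), dtype=bool)
            mask[part.test_records] = True
            part_seed = (int(cfg.seed) + p_idx) % (2 ** 31)
            if fitter is not None:
                preds = np.asarray(fitter(spec, rec, mask, part_seed))
            else:
                fit = fit_gibbs(spec, rec,
                                FitConfig(n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                                          thin=cfg.thin, seed=part_seed,
                                          prior_df=cfg.prior_df,
                                          prior_r2=cfg.prior_r2),
                                g=g, a=a, mask=mask, term_eigs=eigs)
                preds = fit.yhat_
            for env in np.unique(env_of[mask]):
                sel = mask & (env_of == env)
                if sel.sum() < min_test_records:
                    logger.warning(
                        "partition %s/%s: environment %s has %d test records "
                        "(< %d); skipped", part.scheme, p_idx, env,
                        int(sel.sum()), min_test_records)
                    continue
                rows.append({
                    "scheme": part.scheme,
                    "model": spec.model_number,
                    "replicate": part.replicate,
                    "fold": part.fold,
                    "environment": env,
                    "accuracy": _pearson(preds[sel], y[sel]),
                    "n_test": int(sel.sum()),
                })
    return pd.DataFrame(rows)


def summarize_cv(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-partition accuracies to mean and SD per
    (scheme, model, environment) — the published tables' layout."""
    out = (results.groupby(["scheme", "model", "environment"])["accuracy"]
           .agg(mean_accuracy="mean", sd_accuracy="std", n_partitions="count")
           .reset_index())
    return out
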