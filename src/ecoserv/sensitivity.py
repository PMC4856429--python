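"""Standardized-regression-coefficient (SRC) sensitivity analysis.

For each service map the spatially varying model inputs are sampled at
random pixels, both sides are z-scored, and an ordinary-least-squares fit
yields one standardized coefficient per predictor — a unitless measure of
how strongly that input drives the mapped output.  Standard errors and 95%
confidence intervals come from a nonparametric bootstrap (percentile
method) by default, or from the OLS analytic formula.

With a single predictor the SRC equals the Pearson correlation; with
correlated predictors SRCs can leave [-1, 1], in which case a warning is
logged but values are reported unclipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterGrid, joint_valid_mask

log = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 10_000
DEFAULT_N_BOOT = 1_000


@dataclass
class SRCResult:
    """SRC point estimates with bootstrap uncertainty, one row per predictor."""

    table: pd.DataFrame  # columns: predictor, src, se, ci_lo, ci_hi
    n_samples: int
    n_boot: int
    seed: int

    def src(self, predictor: str) -> float:
        return float(self.table.set_index("predictor").loc[predictor, "src"])


def sample_pixels(
    grids: dict[str, RasterGrid], n: int = DEFAULT_N_SAMPLES, seed: int = 0
) -> pd.DataFrame:
    """Uniform sample (without replacement) of cells valid in every grid.

    Returns one row per sampled cell with a column per named grid, plus the
    ``row``/``col`` indices.  Deterministic under ``seed``.
    """
    if not grids:
        raise ValueError("sample_pixels needs at least one grid")
    names = list(grids)
    mask = joint_valid_mask(*grids.values())
    valid_idx = np.flatnonzero(mask.ravel())
    if n > len(valid_idx):
        raise ValueError(f"requested {n} samples but only {len(valid_idx)} jointly valid cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(valid_idx, size=n, replace=False)
    nc = next(iter(grids.values())).n_cols
    out = {"row": chosen // nc, "col": chosen % nc}
    for name in names:
        out[name] = grids[name].values.ravel()[chosen].astype(float)
    return pd.DataFrame(out)


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def src_analysis(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    method: str = "bootstrap",
) -> SRCResult:
    """Standardized regression coefficients of ``response`` on ``predictors``.

    ``method`` is ``"bootstrap"`` (percentile CI from ``n_boot`` resamples)
    or ``"analytic"`` (OLS standard errors, normal CI).  Constant predictors
    are dropped with a warning; exact collinearity raises, naming the
    columns involved.
    """
    if len(data) < 2:
        raise ValueError("src_analysis needs at least two rows")
    keep = []
    for p in predictors:
        if np.std(data[p].to_numpy()) == 0:
            log.warning("predictor %r is constant in the sample; dropped", p)
        else:
            keep.append(p)
    if not keep:
        raise ValueError("all predictors are constant")
    y = _zscore(data[response].to_numpy(dtype=float))
    X = _zscore(data[keep].to_numpy(dtype=float))
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"collinear predictors among {keep} (rank {rank} < {p})")

    Xd = np.column_stack([X, np.ones(n)])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    src = coef[:p]
    if np.abs(src).max() > 1 + 1e-9:
        log.warning("SRC outside [-1, 1]: predictors are correlated; reported unclipped")

    rng = np.random.default_rng(seed)
    if method == "bootstrap":
        # re-standardize within each resample so the CI reflects the whole
        # estimator (including the z-scoring step)
        Xraw = data[keep].to_numpy(dtype=float)
        yraw = data[response].to_numpy(dtype=float)
        boot = np.empty((n_boot, p))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = _zscore(Xraw[idx])
            yb = _zscore(yraw[idx])
            Xb = np.column_stack([Xb, np.ones(n)])
            g = Xb.T @ Xb
            try:
                boot[b] = np.linalg.solve(g, Xb.T @ yb)[:p]
            except np.linalg.LinAlgError:
                boot[b] = np.nan
        se = np.nanstd(boot, axis=0, ddof=1)
        ci_lo = np.nanpercentile(boot, 2.5, axis=0)
        ci_hi = np.nanpercentile(boot, 97.5, axis=0)
    elif method == "analytic":
        resid = y - Xd @ coef
        sigma2 = resid @ resid / (n - p - 1)
        cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
        se = np.sqrt(np.diag(cov)[:p])
        ci_lo, ci_hi = src - 1.96 * se, src + 1.96 * se
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(
        {"predictor": keep, "src": src, "se": se, "ci_lo": ci_lo, "ci_hi": ci_hi}
    )
    return SRCResult(table, n_samples=n, n_boot=n_boot, seed=seed)


def build_predictor_sets(
    quality: RasterGrid,
    threat_impacts: dict[str, RasterGrid],
    beta: RasterGrid,
    carbon_stock: RasterGrid,
    carbon_pools: dict[str, RasterGrid],
    retention: RasterGrid,
    usle_grids: dict[str, RasterGrid],
) -> dict[str, tuple[RasterGrid, dict[str, RasterGrid]]]:
    """The three (response, predictors) specifications.

    * habitat quality ~ per-threat impacts + accessibility (``ACCESS``);
    * carbon stock ~ the four pool rasters (AGB, BGB, SOC, DOC);
    * sediment retention ~ R, K, LS, C, P and the filtration factor.
    """
    return {
        "habitat_quality": (quality, {**threat_impacts, "ACCESS": beta}),
        "carbon": (carbon_stock, dict(carbon_pools)),
        "sediment": (retention, dict(usle_grids)),
    }


def run_sensitivity(
    predictor_sets: dict[str, tuple[RasterGrid, dict[str, RasterGrid]]],
    n: int = DEFAULT_N_SAMPLES,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    method: str = "bootstrap",
) -> pd.DataFrame:
    """SRC analysis for every model; returns one tidy table."""
    frames = []
    for model, (response, predictors) in predictor_sets.items():
        grids = {"__response__": response, **predictors}
        n_use = min(n, int(joint_valid_mask(*grids.values()).sum()))
        data = sample_pixels(grids, n_use, seed)
        res = src_analysis(data, "__response__", list(predictors), n_boot, seed, method)
        tab = res.table.copy()
        tab.insert(0, "model", model)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
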