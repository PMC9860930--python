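"""Negative-binomial differential expression between two groups.

Median-of-ratios size factors, method-of-moments dispersion, an NB log-link
GLM per gene (intercept + group indicator, size factors as offsets) with a
Wald test on the group effect, and BH-FDR DEG calling at |log2FC| > 1 and
q < 0.05. A transparent NB core: no dispersion shrinkage, no independent
filtering and no fold-change shrinkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ConfigError, ExpressionSet

log = logging.getLogger("selconv.de")

ALPHA_FLOOR = 1e-8
EFFECT_CAP = np.log(2.0) * 15.0   # |log2FC| cap under complete separation


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization: factor_j = median over all-positive
    genes of count_gj / geometric mean_g; falls back to total-count ratios
    when no gene is positive in every sample."""
    counts = np.asarray(counts, dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.sum() == 0:
        log.warning("no gene positive in all samples; using total-count "
                    "size factors")
        totals = counts.sum(axis=0)
        pos = totals > 0
        if not pos.any():
            return np.ones(counts.shape[1])
        sf = np.ones(counts.shape[1])
        sf[pos] = totals[pos] / np.exp(np.mean(np.log(totals[pos])))
        return sf
    sub = counts[allpos]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    return np.median(sub / geo, axis=0)


def estimate_dispersion(counts: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion on the normalized scale:
    alpha = max((s^2 - mu) / mu^2, floor)."""
    norm = np.asarray(counts, dtype=float) / sf[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / mu ** 2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_FLOOR)
    return np.maximum(alpha, ALPHA_FLOOR)


def _nb_glm_fit(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
                alpha: float, max_iter: int = 100, tol: float = 1e-10
                ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fisher-scoring fit of an NB GLM with log link and fixed dispersion.

    Returns (beta, standard errors, converged). Design ``x`` is (n, 2):
    intercept and group indicator."""
    n = len(y)
    beta = np.zeros(2)
    mu0 = max(np.mean(y / np.exp(offset)), 1e-8)
    beta[0] = np.log(mu0)
    ok = False
    for _ in range(max_iter):
        eta = x @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)           # Fisher weights
        score = x.T @ ((y - mu) / (1.0 + alpha * mu))
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(2), score)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + np.clip(step, -5.0, 5.0)
        beta_new[1] = np.clip(beta_new[1], -EFFECT_CAP, EFFECT_CAP)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            ok = True
            break
        beta = beta_new
    eta = np.clip(x @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    info = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(info + 1e-12 * np.eye(2))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
        ok = False
    return beta, se, ok


def nb_wald_test(counts: ExpressionSet | pd.DataFrame, groups: pd.Series,
                 sf: np.ndarray | None = None,
                 dispersions: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test of group2 vs group1.

    ``groups`` maps sample name to one of exactly two group labels (sorted
    order defines group1/group2); each group needs >= 2 samples. Genes with
    all-zero counts are excluded from testing and from the BH denominator.
    Returns a DataFrame with base_mean, log2fc, se_log2fc, wald_z, p_value,
    q_value, separated and converged columns.
    """
    values = counts.values if isinstance(counts, ExpressionSet) else counts
    mat = values.to_numpy(dtype=float)
    samples = list(values.columns)
    glabels = sorted(groups.unique())
    if len(glabels) != 2:
        raise ConfigError(f"exactly two groups required, got {glabels}")
    ind = np.array([1.0 if groups[s] == glabels[1] else 0.0
                    for s in samples])
    if ind.sum() < 2 or (len(ind) - ind.sum()) < 2:
        raise ConfigError("each group needs at least 2 samples")
    if sf is None:
        sf = size_factors(mat)
    if dispersions is None:
        dispersions = estimate_dispersion(mat, sf)
    offset = np.log(sf)
    x = np.column_stack([np.ones(len(ind)), ind])
    nonzero = mat.sum(axis=1) > 0
    rows = []
    ln2 = np.log(2.0)
    for gi in np.nonzero(nonzero)[0]:
        y = mat[gi]
        separated = (y[ind == 1].sum() == 0) or (y[ind == 0].sum() == 0)
        beta, se, ok = _nb_glm_fit(y, x, offset, float(dispersions[gi]))
        lfc = beta[1] / ln2
        se_lfc = se[1] / ln2
        if separated:
            lfc = float(np.clip(lfc, -EFFECT_CAP / ln2, EFFECT_CAP / ln2))
        z = beta[1] / se[1] if se[1] > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append((values.index[gi], float((y / sf).mean()), float(lfc),
                     float(se_lfc), float(z), float(p), separated, ok))
    df = pd.DataFrame(rows, columns=["gene", "base_mean", "log2fc",
                                     "se_log2fc", "wald_z", "p_value",
                                     "separated", "converged"])
    df = df.set_index("gene")
    df["q_value"] = np.nan
    testable = df["converged"] & df["p_value"].notna()
    if testable.any():
        df.loc[testable, "q_value"] = multipletests(
            df.loc[testable, "p_value"], method="fdr_bh")[1]
    df["group1"], df["group2"] = glabels[0], glabels[1]
    return df


def call_degs(results: pd.DataFrame, lfc_threshold: float = 1.0,
              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """DEGs at |log2FC| strictly above and q strictly below the thresholds;
    the direction flag marks up/down regulation in group2."""
    hit = (results["log2fc"].abs() > lfc_threshold) \
        & (results["q_value"] < fdr_threshold)
    out = results[hit].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    n_up = int((out["direction"] == "up").sum())
    log.info("%d DEGs (%d up, %d down in group2)", len(out), n_up,
             len(out) - n_up)
    return out
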