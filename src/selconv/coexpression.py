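"""Weighted coexpression network core: soft-threshold selection, topological
overlap, module detection and merging, eigengenes, module--trait correlation
and GS/MM hub screening.

The network is unsigned (adjacency |cor|^beta) by default and the dendrogram
cut is a deterministic static-height cut of the average-linkage dissTOM tree
(branches with at least ``min_module_size`` leaves become modules). Both
choices are configuration switches; see the methods note for the rationale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import ConfigError, ExpressionSet

log = logging.getLogger("selconv.coexpr")


# ---------------------------------------------------------------------------
# Gene and sample filtering
# ---------------------------------------------------------------------------

def filter_by_sd(expr: ExpressionSet, sd_min: float = 0.5) -> ExpressionSet:
    """Drop genes whose sample standard deviation is below ``sd_min``
    (>= keeps the boundary)."""
    sd = expr.values.std(axis=1, ddof=1)
    keep = sd >= sd_min
    log.info("SD filter kept %d / %d genes", int(keep.sum()), len(keep))
    return ExpressionSet(values=expr.values.loc[keep], samples=expr.samples)


def detect_sample_outliers(expr: ExpressionSet,
                           cut_height: float | None = None
                           ) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering of samples on Euclidean distance.

    With ``cut_height=None`` (default) the dendrogram is report-only and all
    samples are retained; otherwise samples falling in clusters of size < 2
    after cutting at that height are dropped.
    Returns (retained sample names, linkage matrix)."""
    x = expr.values.to_numpy().T
    if x.shape[0] < 3:
        raise ConfigError("need at least 3 samples to cluster")
    link = hierarchy.linkage(x, method="average", metric="euclidean")
    names = expr.sample_names
    if cut_height is None:
        return list(names), link
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    keep = [n for n, lab in zip(names, labels) if sizes[lab] >= 2]
    dropped = sorted(set(names) - set(keep))
    if dropped:
        log.info("sample outliers dropped: %s", dropped)
    return keep, link


# ---------------------------------------------------------------------------
# Soft threshold and adjacency
# ---------------------------------------------------------------------------

def adjacency_matrix(expr_values: np.ndarray, beta: int,
                     signed: bool = False) -> np.ndarray:
    """Gene-gene adjacency |cor|^beta (unsigned) or ((1+cor)/2)^beta
    (signed); unit diagonal."""
    cor = np.corrcoef(expr_values)
    cor = np.nan_to_num(cor, nan=0.0)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free fit index: bin connectivity k into ``n_bins``, regress
    log10(freq) on log10(mean k), and report -sign(slope) * R^2 so that the
    negative slope a power-law produces scores positive (the WGCNA
    convention)."""
    k = adjacency.sum(axis=0) - np.diag(adjacency)
    k = k[k > 0]
    if len(k) < 3:
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_threshold(expr: ExpressionSet, powers=range(1, 21),
                        target_r2: float = 0.85, signed: bool = False
                        ) -> tuple[int, pd.DataFrame]:
    """Smallest power whose signed scale-free fit index reaches ``target_r2``;
    falls back (with a warning) to the argmax power when none reaches it."""
    x = expr.values.to_numpy()
    rows = []
    for beta in powers:
        a = adjacency_matrix(x, beta, signed=signed)
        r2 = scale_free_fit(a)
        rows.append((beta, r2))
        if np.isfinite(r2) and r2 >= target_r2:
            log.info("soft threshold beta=%d (signed R^2=%.3f)", beta, r2)
            return beta, pd.DataFrame(rows, columns=["power", "signed_r2"])
    df = pd.DataFrame(rows, columns=["power", "signed_r2"])
    finite = df.dropna()
    if finite.empty:
        raise ConfigError("scale-free fit undefined at every power")
    best = int(finite.loc[finite["signed_r2"].idxmax(), "power"])
    log.warning("no power reached R^2 >= %.2f; using argmax beta=%d",
                target_r2, best)
    return best, df


# ---------------------------------------------------------------------------
# Topological overlap and module detection
# ---------------------------------------------------------------------------

def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, 1 on it, where k excludes the diagonal."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def cut_modules(diss_tom: np.ndarray, min_module_size: int = 30,
                cut_fraction: float = 0.99) -> np.ndarray:
    """Static-height tree cut of the average-linkage dissTOM dendrogram at
    ``cut_fraction`` x the maximum merge height; branches with at least
    ``min_module_size`` leaves become modules labelled 1..k by decreasing
    size, everything else is label 0."""
    n = diss_tom.shape[0]
    d = diss_tom.copy()
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    height = cut_fraction * link[:, 2].max() if link[:, 2].max() > 0 else 0.0
    raw = hierarchy.fcluster(link, t=height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].sort_values(ascending=False)
    for new, (old, _) in enumerate(big.items(), start=1):
        labels[raw == old] = new
    return labels


def module_eigengene(expr: ExpressionSet, labels: np.ndarray) -> pd.DataFrame:
    """Module eigengenes: first principal component across samples of each
    module's per-gene z-scored submatrix, sign-aligned to the module's mean
    expression profile and scaled to unit variance. Rows are samples,
    columns ME<label>."""
    x = expr.values.to_numpy()
    mes = {}
    for m in sorted(set(labels) - {0}):
        sub = x[labels == m]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        z = (sub - mu) / np.where(sd > 0, sd, 1.0)
        if z.shape[0] == 1:
            me = z[0]
        else:
            # first right singular vector = first PC scores over samples
            # (rows are already centred by the per-gene z-scoring)
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
        mean_profile = z.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        sd_me = me.std(ddof=1)
        mes[f"ME{m}"] = me / sd_me if sd_me > 0 else me
    return pd.DataFrame(mes, index=expr.sample_names)


def merge_modules(expr: ExpressionSet, labels: np.ndarray,
                  me_diss_threshold: float = 0.25,
                  max_rounds: int = 10) -> tuple[np.ndarray, pd.DataFrame]:
    """Merge modules whose eigengene dissimilarity 1 - cor(ME_i, ME_j) falls
    below the threshold (average-linkage clusters of the ME dissimilarity),
    recomputing eigengenes until stable."""
    labels = labels.copy()
    for _ in range(max_rounds):
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        mes = module_eigengene(expr, labels)
        diss = 1.0 - np.corrcoef(mes.to_numpy().T)
        np.fill_diagonal(diss, 0.0)
        link = hierarchy.linkage(squareform(diss, checks=False),
                                 method="average")
        groups = hierarchy.fcluster(link, t=me_diss_threshold,
                                    criterion="distance")
        if len(set(groups)) == len(mods):
            break
        mapping = {}
        for g in sorted(set(groups)):
            members = [mods[i] for i in range(len(mods)) if groups[i] == g]
            for m in members:
                mapping[m] = members[0]
        labels = np.array([mapping.get(l, 0) for l in labels])
        # relabel by decreasing size
        sizes = pd.Series(labels[labels > 0]).value_counts()
        relab = {old: new for new, (old, _) in
                 enumerate(sizes.sort_values(ascending=False).items(), 1)}
        labels = np.array([relab.get(l, 0) for l in labels])
    return labels, module_eigengene(expr, labels)


# ---------------------------------------------------------------------------
# Module--trait correlation and hub genes
# ---------------------------------------------------------------------------

def _cor_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


STAGE_ORDER = ("anagen", "catagen", "telogen", "late-telogen")


def stage_indicators(traits: pd.DataFrame, stage_col: str = "stage"
                     ) -> pd.DataFrame:
    """Binary indicator columns for the four hair-follicle cycle stages."""
    out = pd.DataFrame(index=traits.index)
    for s in STAGE_ORDER:
        out[s] = (traits[stage_col] == s).astype(float)
    return out


@dataclass
class ModuleTraitResult:
    module_trait_r: pd.DataFrame
    module_trait_p: pd.DataFrame
    gene_significance: pd.DataFrame      # genes x traits (GS)
    module_membership: pd.DataFrame      # genes x MEs (MM)
    hub_genes: dict[str, list[str]]


def module_trait_and_hubs(expr: ExpressionSet, mes: pd.DataFrame,
                          labels: np.ndarray, traits: pd.DataFrame,
                          key_modules: list[str] | None = None,
                          gs_cut: float = 0.2, mm_cut: float = 0.8
                          ) -> ModuleTraitResult:
    """Pearson module--trait, gene--trait (GS) and gene--eigengene (MM)
    correlations; hub genes are members of the key modules with
    |GS| > gs_cut against any trait and |MM| > mm_cut for their own module."""
    x = expr.values.to_numpy()
    genes = expr.genes
    for col in traits.columns:
        if traits[col].std() == 0:
            log.warning("trait column %r has zero variance; correlations "
                        "undefined", col)
    r_mt = pd.DataFrame(index=mes.columns, columns=traits.columns, dtype=float)
    p_mt = r_mt.copy()
    for me in mes.columns:
        for tr in traits.columns:
            r, p = _cor_with_p(mes[me].to_numpy(),
                               traits[tr].to_numpy(dtype=float))
            r_mt.loc[me, tr] = r
            p_mt.loc[me, tr] = p
    gs = pd.DataFrame(index=genes, columns=traits.columns, dtype=float)
    for tr in traits.columns:
        tv = traits[tr].to_numpy(dtype=float)
        for gi, g in enumerate(genes):
            gs.loc[g, tr] = _cor_with_p(x[gi], tv)[0]
    mm = pd.DataFrame(index=genes, columns=mes.columns, dtype=float)
    for me in mes.columns:
        mv = mes[me].to_numpy()
        for gi, g in enumerate(genes):
            mm.loc[g, me] = _cor_with_p(x[gi], mv)[0]
    if key_modules is None:
        key_modules = list(mes.columns)
    hubs: dict[str, list[str]] = {}
    for me in key_modules:
        m = int(me.replace("ME", ""))
        members = [g for g, lab in zip(genes, labels) if lab == m]
        hubs[me] = [g for g in members
                    if (gs.loc[g].abs() > gs_cut).any()
                    and abs(mm.loc[g, me]) > mm_cut]
    return ModuleTraitResult(module_trait_r=r_mt, module_trait_p=p_mt,
                             gene_significance=gs, module_membership=mm,
                             hub_genes=hubs)


# ---------------------------------------------------------------------------
# One-call driver
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionResult:
    beta: int
    labels: np.ndarray
    genes: list[str]
    eigengenes: pd.DataFrame
    trait_result: ModuleTraitResult


def run_coexpression(expr: ExpressionSet, traits: pd.DataFrame,
                     sd_min: float = 0.5, target_r2: float = 0.85,
                     min_module_size: int = 30,
                     me_diss_threshold: float = 0.25, gs_cut: float = 0.2,
                     mm_cut: float = 0.8, signed: bool = False
                     ) -> CoexpressionResult:
    """SD filter -> soft threshold -> TOM -> static tree cut -> ME merge ->
    module--trait correlation and hub screening."""
    expr = filter_by_sd(expr, sd_min)
    beta, _ = pick_soft_threshold(expr, target_r2=target_r2, signed=signed)
    a = adjacency_matrix(expr.values.to_numpy(), beta, signed=signed)
    tom = tom_matrix(a)
    labels = cut_modules(1.0 - tom, min_module_size)
    labels, mes = merge_modules(expr, labels, me_diss_threshold)
    trait_res = module_trait_and_hubs(expr, mes, labels, traits,
                                      gs_cut=gs_cut, mm_cut=mm_cut)
    return CoexpressionResult(beta=beta, labels=labels, genes=expr.genes,
                              eigengenes=mes, trait_result=trait_res)
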