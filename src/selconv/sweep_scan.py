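"""Sliding-window selective-sweep scan: Weir–Cockerham Fst and nucleotide
diversity (pi) in 50 kb / 20 kb windows, pi-ratio, top-quantile window
calling, overlap of the two methods and gene annotation of candidates.

Site filtering mirrors the vcftools invocation the protocol describes:
biallelic sites with overall MAF >= 0.05 and at most 10% missing genotypes.
Window Fst is the ratio of summed variance components (weighted Fst), which
is what the vcftools windowed Weir–Cockerham estimator reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ConfigError, RunConfig, VariantPanel

log = logging.getLogger("selconv.sweep")


# ---------------------------------------------------------------------------
# Site filtering and per-site counts
# ---------------------------------------------------------------------------

@dataclass
class SiteCounts:
    """Per-site allele bookkeeping for the two populations after filtering.

    Arrays are parallel over retained sites: ``n`` holds called allele
    counts, ``alt`` alt-allele counts and ``het`` heterozygote individual
    counts per population, in the order (pop1, pop2).
    """

    chrom: np.ndarray
    pos: np.ndarray
    n: tuple[np.ndarray, np.ndarray]
    alt: tuple[np.ndarray, np.ndarray]
    het: tuple[np.ndarray, np.ndarray]
    pop_names: tuple[str, str]


def filter_sites(panel: VariantPanel, maf_min: float = 0.05,
                 max_missing: float = 0.10,
                 pops: tuple[str, str] | None = None) -> SiteCounts:
    """Keep biallelic sites with overall minor-allele frequency >= maf_min
    and missing-genotype fraction <= max_missing, computed over the union of
    both populations. Missing genotypes are never imputed; they reduce the
    called-allele denominators."""
    if pops is None:
        if len(panel.pops) != 2:
            raise ConfigError("two populations required for the sweep scan")
        # panel declaration order; the second population is treated as the
        # selected one unless window_scan is told otherwise
        pops = tuple(panel.pops)
    idx = np.concatenate([panel.pops[pops[0]], panel.pops[pops[1]]])
    sub = panel.gt[:, idx]
    n_called = (sub >= 0).sum(axis=1)
    call_rate = n_called / sub.shape[1] if sub.shape[1] else np.zeros(len(sub))
    alt_total = np.where(sub >= 0, sub, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_called > 0, alt_total / (2.0 * n_called), 0.0)
    maf = np.minimum(af, 1.0 - af)
    keep = (panel.biallelic & (call_rate >= 1.0 - max_missing)
            & (maf >= maf_min) & (n_called > 0))
    ns, alts, hets = [], [], []
    for p in pops:
        called, alt, het = panel.pop_counts(p)
        ns.append(called[keep])
        alts.append(alt[keep])
        hets.append(het[keep])
    log.info("site filter kept %d / %d sites", int(keep.sum()), panel.n_sites)
    return SiteCounts(chrom=panel.chrom[keep], pos=panel.pos[keep],
                      n=(ns[0], ns[1]), alt=(alts[0], alts[1]),
                      het=(hets[0], hets[1]), pop_names=pops)


# ---------------------------------------------------------------------------
# Weir–Cockerham (1984) variance components, diploid, two populations
# ---------------------------------------------------------------------------

def wc_fst_components(n_alleles: tuple, alt: tuple, het: tuple
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised a (among-population), b (among-individual within
    population) and c (within-individual) components per site.

    Inputs are per-population arrays of called allele counts, alt-allele
    counts and heterozygote individual counts. Sites where either
    population has no called diploid yield NaN components (skipped
    downstream)."""
    r = 2.0
    n_i = [np.asarray(n, dtype=float) / 2.0 for n in n_alleles]  # diploids
    p_i = [np.divide(a, n, out=np.zeros_like(np.asarray(a, float)),
                     where=np.asarray(n) > 0)
           for a, n in zip(alt, n_alleles)]
    h_i = [np.divide(h, ni, out=np.zeros_like(np.asarray(h, float)),
                     where=ni > 0)
           for h, ni in zip(het, n_i)]
    n_total = n_i[0] + n_i[1]
    nbar = n_total / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (n_total - (n_i[0] ** 2 + n_i[1] ** 2) / n_total) / (r - 1.0)
        pbar = (n_i[0] * p_i[0] + n_i[1] * p_i[1]) / (r * nbar)
        s2 = (n_i[0] * (p_i[0] - pbar) ** 2
              + n_i[1] * (p_i[1] - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n_i[0] * h_i[0] + n_i[1] * h_i[1]) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                     - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2.0
    bad = (n_i[0] < 1) | (n_i[1] < 1) | (nbar <= 1.0) | ~np.isfinite(nc) \
        | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass
class WindowTable:
    """Per-window statistics as a DataFrame with columns chrom, start, end,
    n_sites, fst, pi_<pop1>, pi_<pop2>, pi_ratio plus flag columns added by
    :func:`top_windows`."""

    df: pd.DataFrame
    pop_names: tuple[str, str]


def _window_starts(chrom_len: int, size: int, step: int) -> np.ndarray:
    if chrom_len <= size:
        return np.array([0])
    last = ((chrom_len - size) // step) * step
    return np.arange(0, last + 1, step)


def window_scan(sites: SiteCounts, chrom_lengths: dict[str, int],
                config: RunConfig, pi_ratio_cap: float = 1e6,
                selected_pop: str | None = None) -> WindowTable:
    """Windowed weighted Fst, per-population pi per bp and the pi-ratio.

    ``selected_pop`` names the population under putative selection (the
    cashmere population); the ratio is pi_reference / pi_selected so sweeps
    in the selected population land in the upper tail. Windows with no
    usable sites carry NaN statistics.
    """
    if selected_pop is None:
        selected_pop = sites.pop_names[1]
    if selected_pop not in sites.pop_names:
        raise ConfigError(f"unknown selected population {selected_pop!r}")
    ref_pop = sites.pop_names[0] if selected_pop == sites.pop_names[1] \
        else sites.pop_names[1]
    a, b, c = wc_fst_components(sites.n, sites.alt, sites.het)
    abc = a + b + c
    pi_site = []
    for k in range(2):
        n = sites.n[k].astype(float)
        alt = sites.alt[k].astype(float)
        ref = n - alt
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(n >= 2, 2.0 * ref * alt / (n * (n - 1.0)), np.nan)
        pi_site.append(pi)
    rows = []
    size, step = config.window_size_bp, config.window_step_bp
    for chrom, clen in chrom_lengths.items():
        on = sites.chrom == chrom
        pos = sites.pos[on]
        for start in _window_starts(clen, size, step):
            end = start + size
            inw = (pos >= start) & (pos < end)
            sel = np.nonzero(on)[0][inw]
            n_sites = len(sel)
            num = np.nansum(a[sel]) if n_sites else 0.0
            den = np.nansum(abc[sel]) if n_sites else 0.0
            fst = num / den if (n_sites and den != 0) else np.nan
            pis = []
            for k in range(2):
                vals = pi_site[k][sel]
                vals = vals[np.isfinite(vals)]
                pis.append(vals.sum() / size if n_sites else np.nan)
            rows.append((chrom, start, end, n_sites, fst, pis[0], pis[1]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                     "fst", f"pi_{sites.pop_names[0]}",
                                     f"pi_{sites.pop_names[1]}"])
    df["pi_ratio"] = pi_ratio(df[f"pi_{ref_pop}"].to_numpy(),
                              df[f"pi_{selected_pop}"].to_numpy(),
                              cap=pi_ratio_cap)
    df["fst_clamped"] = df["fst"].clip(lower=0.0)
    return WindowTable(df=df, pop_names=sites.pop_names)


def pi_ratio(pi_reference: np.ndarray, pi_selected: np.ndarray,
             cap: float = 1e6) -> np.ndarray:
    """pi_reference / pi_selected; NaN when both are zero or either is
    missing, capped when only the denominator is zero."""
    pi_reference = np.asarray(pi_reference, dtype=float)
    pi_selected = np.asarray(pi_selected, dtype=float)
    out = np.full(pi_reference.shape, np.nan)
    ok = np.isfinite(pi_reference) & np.isfinite(pi_selected)
    both_zero = ok & (pi_reference == 0) & (pi_selected == 0)
    den_zero = ok & (pi_selected == 0) & (pi_reference > 0)
    normal = ok & (pi_selected > 0)
    out[normal] = pi_reference[normal] / pi_selected[normal]
    out[den_zero] = cap
    out[both_zero] = np.nan
    return np.minimum(out, cap, where=np.isfinite(out), out=out)


# ---------------------------------------------------------------------------
# Top-quantile calling, overlap and annotation
# ---------------------------------------------------------------------------

def top_windows(values: np.ndarray, top_fraction: float
                ) -> tuple[float, np.ndarray]:
    """Empirical upper-tail call: threshold is the k-th largest value with
    k = ceil(top_fraction * n) over non-missing values; windows >= threshold
    are flagged (ties kept, so the flag count can exceed k)."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n == 0:
        return float("nan"), np.zeros(len(values), dtype=bool)
    k = max(1, math.ceil(top_fraction * n))
    threshold = float(np.sort(values[finite])[::-1][k - 1])
    flags = finite & (values >= threshold)
    if int(flags.sum()) > k:
        log.warning("ties at the top-%g%% threshold: %d windows flagged "
                    "(capacity %d)", 100 * top_fraction, int(flags.sum()), k)
    return threshold, flags


def _merge_intervals(iv: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of possibly overlapping/bookended half-open intervals."""
    out: list[list] = []
    for chrom, s, e in sorted(iv):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([chrom, s, e])
    return [tuple(x) for x in out]


def _intersect_intervals(a: list[tuple[str, int, int]],
                         b: list[tuple[str, int, int]]
                         ) -> list[tuple[str, int, int]]:
    out = []
    for chrom, s1, e1 in a:
        for c2, s2, e2 in b:
            if c2 != chrom:
                continue
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((chrom, s, e))
    return _merge_intervals(out)


@dataclass
class SweepCandidates:
    fst_threshold: float
    pi_ratio_threshold: float
    common_regions: list[tuple[str, int, int]]
    n_common_window_pairs: int
    genes_fst: list[str]
    genes_pi: list[str]
    genes_intersection: list[str]
    windows: pd.DataFrame


def overlap_and_annotate(table: WindowTable, gene_intervals: pd.DataFrame,
                         top_fraction: float = 0.01) -> SweepCandidates:
    """Flag the top-fraction windows of each statistic, intersect the two
    flagged window sets into common candidate regions, annotate genes by
    >= 1 bp overlap with each method's flagged windows, and intersect the two
    gene lists."""
    df = table.df.copy()
    fst_thr, fst_flags = top_windows(df["fst"].to_numpy(), top_fraction)
    pi_thr, pi_flags = top_windows(df["pi_ratio"].to_numpy(), top_fraction)
    df["top_fst"] = fst_flags
    df["top_pi_ratio"] = pi_flags
    df["overlap"] = fst_flags & pi_flags

    def intervals(mask) -> list[tuple[str, int, int]]:
        sub = df[mask]
        return _merge_intervals(
            list(zip(sub["chrom"], sub["start"], sub["end"])))

    fst_iv, pi_iv = intervals(fst_flags), intervals(pi_flags)
    common = _intersect_intervals(fst_iv, pi_iv)
    n_pairs = int((fst_flags & pi_flags).sum())

    def genes_for(iv: list[tuple[str, int, int]]) -> list[str]:
        hits = []
        for chrom, s, e in iv:
            sel = gene_intervals[(gene_intervals["chrom"] == chrom)
                                 & (gene_intervals["start"] < e)
                                 & (gene_intervals["end"] > s)]
            hits.extend(sel["gene"].tolist())
        return sorted(set(hits))

    genes_fst, genes_pi = genes_for(fst_iv), genes_for(pi_iv)
    inter = sorted(set(genes_fst) & set(genes_pi))
    log.info("sweep scan: Fst > %.4f, pi-ratio > %.4f, %d common regions, "
             "%d / %d / %d genes (fst / pi / intersection)",
             fst_thr, pi_thr, len(common), len(genes_fst), len(genes_pi),
             len(inter))
    return SweepCandidates(fst_threshold=fst_thr, pi_ratio_threshold=pi_thr,
                           common_regions=common,
                           n_common_window_pairs=n_pairs,
                           genes_fst=genes_fst, genes_pi=genes_pi,
                           genes_intersection=inter, windows=df)


def run_sweep_scan(panel: VariantPanel, gene_intervals: pd.DataFrame,
                   chrom_lengths: dict[str, int], config: RunConfig,
                   selected_pop: str | None = None) -> SweepCandidates:
    """Filter sites, scan windows and call candidate sweep regions."""
    sites = filter_sites(panel, config.maf_min, config.max_missing)
    table = window_scan(sites, chrom_lengths, config,
                        selected_pop=selected_pop)
    return overlap_and_annotate(table, gene_intervals, config.top_fraction)
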