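"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates (i) codon alignments evolved on a fixed tree under the same GY94
process the inference module fits, with optional foreground omega shifts and
planted convergent amino-acid substitutions on two focal branches; (ii)
two-population genotype panels with neutral background windows and planted
low-diversity/high-differentiation sweep windows; (iii) negative-binomial
count matrices with planted fold changes plus normalized matrices with
planted stage-linked coexpression modules; and (iv) gene annotations and
pathway tables consistent with the planted signals.

Population sites are simulated independently (Beta-distributed shared
frequencies with per-population jitter), not via a coalescent: windows are
exchangeable, truth is analytic, and no downstream statistic uses linkage.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (Alignment, AMINO_ACIDS, ConfigError, ExpressionSet,
                         Tree, VariantPanel)
from .phylo_selection import (CODONS, CODON_AA, CODON_INDEX, IS_NONSYN,
                              SINGLE_STEP, f1x4_frequencies, gy94_mean_rate,
                              gy94_rate_matrix)

log = logging.getLogger("selconv.simulate")

_CODON_FOR_AA = {}
for _i, _aa in enumerate(CODON_AA):
    _CODON_FOR_AA.setdefault(_aa, CODONS[_i])


# ---------------------------------------------------------------------------
# Codon alignments with planted selection and convergence
# ---------------------------------------------------------------------------

@dataclass
class Substitution:
    gene: str
    site: int            # 0-based codon index
    branch: int          # child node id
    from_codon: int
    to_codon: int


@dataclass
class PhyloTruth:
    """Complete record of the simulated codon histories."""

    tree: Tree
    kappa: float
    codon_freqs: np.ndarray
    omega_by_branch: dict[int, float]
    foreground_branches: tuple[int, ...]
    node_states: dict[str, np.ndarray]      # gene -> (n_nodes, n_codons)
    history: dict[str, list[Substitution]]
    convergent_sites: list[tuple] = field(default_factory=list)
    # (gene, 1-based site, derived residue, focal_pair, conservative)

    @property
    def selected_genes(self) -> set[str]:
        """Genes simulated with a genuine foreground omega shift."""
        if not self.foreground_branches:
            return set()
        fg = self.omega_by_branch[self.foreground_branches[0]]
        bg = next(v for k, v in self.omega_by_branch.items()
                  if k not in self.foreground_branches)
        return set(self.node_states) if fg != bg else set()


def _sampler_tables(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exit rates and cumulative jump distributions for Gillespie draws."""
    rates = -np.diag(q)
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        jump = jump / np.where(rates[:, None] > 0, rates[:, None], 1.0)
    return rates, np.cumsum(jump, axis=1)


def simulate_codon_data(tree: Tree, n_genes: int, n_codons: int,
                        kappa: float = 2.0, base_omega: float = 0.2,
                        foreground_branches: tuple = (),
                        foreground_omega: float | None = None,
                        nuc_freqs=(0.25, 0.25, 0.25, 0.25),
                        rate_reference_omega: float | None = None,
                        seed: int = 0) -> tuple[dict[str, Alignment], PhyloTruth]:
    """Evolve codon sequences root-to-tips under GY94 (same rate-matrix code
    path as the inference module), recording every substitution.

    ``foreground_branches`` are child node ids (or resolvable specs) that
    evolve under ``foreground_omega`` instead of ``base_omega``.

    By default each branch's generator is normalized to one expected
    substitution per codon per branch-length unit under its own omega. With
    ``rate_reference_omega`` set, every generator is instead normalized by
    the mean rate at that reference omega, so a branch with elevated omega
    accumulates proportionally more substitutions -- the convention the
    branch-site mixture model uses across its site classes.
    """
    if base_omega <= 0 or (foreground_omega is not None
                           and foreground_omega <= 0):
        raise ConfigError("omega values must be positive")
    rng = np.random.default_rng(seed)
    fg = tuple(b if isinstance(b, (int, np.integer)) else tree.branch_for(b)
               for b in foreground_branches)
    bad = [b for b in fg if not 0 <= b < tree.n_nodes - 1]
    if bad:
        raise ConfigError(f"foreground branches {bad} not edges of the tree")
    if foreground_omega is None:
        foreground_omega = base_omega
    pi = f1x4_frequencies(nuc_freqs)
    omega_by_branch = {v: (foreground_omega if v in fg else base_omega)
                       for v in range(tree.n_nodes - 1)}
    tables = {}
    for om in set(omega_by_branch.values()):
        q = gy94_rate_matrix(pi, kappa, om, scale=rate_reference_omega is None)
        if rate_reference_omega is not None:
            q = q / gy94_mean_rate(pi, kappa, rate_reference_omega)
        tables[om] = _sampler_tables(q)
    alignments: dict[str, Alignment] = {}
    node_states: dict[str, np.ndarray] = {}
    history: dict[str, list[Substitution]] = {}
    leaf_name = {v: tree.names[v] for v in tree.leaves}
    for g in range(n_genes):
        gene = f"gene{g + 1:04d}"
        states = np.full((tree.n_nodes, n_codons), -1, dtype=int)
        states[tree.root] = rng.choice(len(CODONS), size=n_codons, p=pi)
        events: list[Substitution] = []
        for v in tree.preorder():
            if v == tree.root:
                continue
            t = tree.blen[v]
            rates, cum = tables[omega_by_branch[v]]
            seq = states[tree.parent[v]].copy()
            if t > 0:
                for k in range(n_codons):
                    s, elapsed = seq[k], 0.0
                    while True:
                        if rates[s] <= 0:
                            break
                        elapsed += rng.exponential(1.0 / rates[s])
                        if elapsed > t:
                            break
                        j = int(np.searchsorted(cum[s], rng.random()))
                        events.append(Substitution(gene, k, v, int(s), j))
                        s = j
                    seq[k] = s
            states[v] = seq
        node_states[gene] = states
        history[gene] = events
        ids = [leaf_name[v] for v in tree.leaves]
        seqs = ["".join(CODONS[c] for c in states[v]) for v in tree.leaves]
        alignments[gene] = Alignment(ids=ids, seqs=seqs, kind="codon")
    truth = PhyloTruth(tree=tree, kappa=kappa, codon_freqs=pi,
                       omega_by_branch=omega_by_branch,
                       foreground_branches=fg, node_states=node_states,
                       history=history)
    return alignments, truth


def realized_dnds(truth: PhyloTruth, gene: str | None = None) -> float:
    """Counting oracle: nonsynonymous/synonymous substitution counts from
    the recorded history, normalized by the neutral (omega = 1) flux ratio
    of the same rate matrix, giving the realized dN/dS."""
    genes = [gene] if gene else list(truth.history)
    n_obs = s_obs = 0
    for g in genes:
        for ev in truth.history[g]:
            if CODON_AA[ev.from_codon] != CODON_AA[ev.to_codon]:
                n_obs += 1
            else:
                s_obs += 1
    q1 = gy94_rate_matrix(truth.codon_freqs, truth.kappa, 1.0)
    flux = truth.codon_freqs[:, None] * np.where(SINGLE_STEP, q1, 0.0)
    n_flux = flux[IS_NONSYN].sum()
    s_flux = flux[SINGLE_STEP & ~IS_NONSYN].sum()
    if s_obs == 0:
        return float("nan")
    return (n_obs / s_obs) / (n_flux / s_flux)


def plant_convergent_sites(alignments: dict[str, Alignment],
                           truth: PhyloTruth, focal_pair: tuple,
                           n_sites: int, conservative: bool = True,
                           seed: int = 0,
                           genes: list[str] | None = None
                           ) -> tuple[dict[str, Alignment], PhyloTruth]:
    """Overwrite ``n_sites`` alignment columns so both focal lineages carry
    an identical derived residue that differs from their parents' states.

    With ``conservative=True`` every non-focal leaf is forced to one shared
    background residue (so the site passes the CCS filter); otherwise only
    the focal leaves are rewritten. Sites already hit by a substitution on a
    focal branch are resampled (logged). ``genes`` restricts (round-robin)
    which genes receive planted sites.
    """
    tree = truth.tree
    fp = tuple(b if isinstance(b, (int, np.integer)) else tree.branch_for(b)
               for b in focal_pair)
    rng = np.random.default_rng(seed)
    gene_list = genes or list(alignments)
    n_codons = alignments[gene_list[0]].n_codons
    if n_sites > n_codons * len(gene_list):
        raise ConfigError("more planted sites requested than codon columns")
    focal_leaves = set()
    for b in fp:
        focal_leaves |= set(tree.subtree_leaves(b)) & set(tree.leaves)
    out = {g: Alignment(ids=list(a.ids), seqs=list(a.seqs), kind="codon")
           for g, a in alignments.items()}
    used: set[tuple[str, int]] = set()
    aa_list = list(AMINO_ACIDS)
    for i in range(n_sites):
        gene = gene_list[i % len(gene_list)]
        for _attempt in range(200):
            site = int(rng.integers(n_codons))
            if (gene, site) in used:
                continue
            touched = any(ev.site == site and ev.branch in fp
                          for ev in truth.history[gene])
            if touched:
                log.debug("site %s:%d variable on a focal branch; resampled",
                          gene, site)
                continue
            break
        else:
            raise ConfigError("could not place planted site")
        used.add((gene, site))
        aln = out[gene]
        # background residue: consensus of current non-focal leaf states
        col_aa = []
        for v in tree.leaves:
            if v in focal_leaves:
                continue
            cod = aln.row(tree.names[v])[3 * site:3 * site + 3]
            j = CODON_INDEX.get(cod)
            if j is not None:
                col_aa.append(CODON_AA[j])
        bg = max(set(col_aa), key=col_aa.count) if col_aa else "A"
        derived = aa_list[int(rng.integers(len(aa_list)))]
        while derived == bg:
            derived = aa_list[int(rng.integers(len(aa_list)))]
        d_codon = _CODON_FOR_AA[derived]
        b_codon = _CODON_FOR_AA[bg]
        for r, name in enumerate(aln.ids):
            v = tree.leaf_index(name)
            s = aln.seqs[r]
            if v in focal_leaves:
                aln.seqs[r] = s[:3 * site] + d_codon + s[3 * site + 3:]
            elif conservative:
                aln.seqs[r] = s[:3 * site] + b_codon + s[3 * site + 3:]
        truth.convergent_sites.append((gene, site + 1, derived, fp,
                                       conservative))
    return out, truth


# ---------------------------------------------------------------------------
# Two-population variant panels with planted sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepTruth:
    sweep_windows: list[tuple[str, int, int]]
    background_pi: dict[str, float]          # per-bp, measured on output
    reduction: float
    divergence: float
    pop_names: tuple[str, str]


def simulate_variant_panel(n_per_pop: int = 30,
                           chrom_length_bp: int = 6_000_000,
                           snp_density: float = 0.002,
                           sweep_windows: list[tuple[str, int, int]] | None = None,
                           reduction: float = 0.1, divergence: float = 0.9,
                           missing_rate: float = 0.02, seed: int = 0,
                           chrom: str = "chr1",
                           pop_names: tuple[str, str] = ("non_cashmere",
                                                         "cashmere")
                           ) -> tuple[VariantPanel, SweepTruth]:
    """Site-wise two-population panel.

    Background sites draw a shared frequency from a symmetric Beta and
    jitter it per population; inside sweep windows the second (selected)
    population's frequency is pulled toward a fixation target with weight
    ``1 - reduction``, the target being chosen against population 1 with
    probability ``divergence``. ``reduction = 1`` with ``divergence = 0``
    reproduces the background process exactly.
    """
    if not 0 < reduction <= 1:
        raise ConfigError("reduction must lie in (0, 1]")
    if sweep_windows is None:
        sweep_windows = [(chrom, 1_000_000, 1_050_000),
                         (chrom, 3_000_000, 3_050_000),
                         (chrom, 5_000_000, 5_050_000)]
    for c, s, e in sweep_windows:
        if s < 0 or e > chrom_length_bp or e <= s:
            raise ConfigError(f"sweep window ({c},{s},{e}) outside chromosome")
    ivs = sorted((s, e) for _, s, e in sweep_windows)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ConfigError("sweep windows must be disjoint")
    rng = np.random.default_rng(seed)
    n_sites = int(round(chrom_length_bp * snp_density))
    pos = np.sort(rng.choice(chrom_length_bp, size=n_sites, replace=False))
    shared = rng.beta(0.6, 0.6, size=n_sites)
    p1 = np.clip(shared + rng.normal(0, 0.02, n_sites), 0.01, 0.99)
    p2 = np.clip(shared + rng.normal(0, 0.02, n_sites), 0.01, 0.99)
    in_sweep = np.zeros(n_sites, dtype=bool)
    for _, s, e in sweep_windows:
        in_sweep |= (pos >= s) & (pos < e)
    # sweep sites: pop-2 moves to within reduction * (distance to nearest
    # fixation) of a target allele; the target is pop-1's minor allele with
    # probability `divergence` (raising differentiation), otherwise pop-2's
    # own major allele (pure diversity loss). reduction=1, divergence=0
    # reproduces the background frequencies exactly.
    against = rng.random(n_sites) < divergence
    target = np.where(against, 1.0 - np.round(p1), np.round(p2))
    m = np.minimum(p2, 1.0 - p2)
    p2_sweep = np.where(target > 0.5, 1.0 - reduction * m, reduction * m)
    p2 = np.clip(np.where(in_sweep, p2_sweep, p2), 0.0, 1.0)
    gt1 = rng.binomial(2, p1[:, None], size=(n_sites, n_per_pop))
    gt2 = rng.binomial(2, p2[:, None], size=(n_sites, n_per_pop))
    gt = np.concatenate([gt1, gt2], axis=1).astype(np.int8)
    if missing_rate > 0:
        gt[rng.random(gt.shape) < missing_rate] = -1
    samples = [f"{pop_names[0]}_{i + 1:03d}" for i in range(n_per_pop)] + \
              [f"{pop_names[1]}_{i + 1:03d}" for i in range(n_per_pop)]
    panel = VariantPanel(
        chrom=np.array([chrom] * n_sites, dtype=object), pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object), gt=gt,
        biallelic=np.ones(n_sites, dtype=bool), samples=samples,
        pops={pop_names[0]: np.arange(n_per_pop),
              pop_names[1]: np.arange(n_per_pop, 2 * n_per_pop)})
    bg = ~in_sweep
    background_pi = {
        pop_names[0]: float((2 * p1[bg] * (1 - p1[bg])).sum()
                            / chrom_length_bp),
        pop_names[1]: float((2 * p2[bg] * (1 - p2[bg])).sum()
                            / chrom_length_bp)}
    truth = SweepTruth(sweep_windows=list(sweep_windows),
                       background_pi=background_pi, reduction=reduction,
                       divergence=divergence, pop_names=pop_names)
    return panel, truth


def pop_table_for(panel: VariantPanel) -> dict[str, str]:
    out = {}
    for p, ix in panel.pops.items():
        for i in ix:
            out[panel.samples[i]] = p
    return out


# ---------------------------------------------------------------------------
# Expression matrices with planted modules and fold changes
# ---------------------------------------------------------------------------

STAGE_MONTHS = {"anagen": ["Apr", "May", "Jun", "Jul", "Aug", "Sep"],
                "catagen": ["Oct", "Nov", "Dec"],
                "telogen": ["Jan", "Feb"],
                "late-telogen": ["Mar"]}


@dataclass
class ExprTruth:
    de_genes: dict[str, float]               # gene -> planted log2FC
    module_assignment: dict[str, int]        # gene -> module id (0 background)
    module_latent: pd.DataFrame              # modules x samples
    trait_table: pd.DataFrame                # sample -> month, stage, breed
    nb_dispersion: dict[str, float]


def simulate_expression(n_genes: int = 1000, samples_per_stage: int = 15,
                        n_modules: int = 4, module_size: int = 60,
                        module_cor: float = 0.8, n_de: int = 100,
                        lfc: float = 2.0, dispersion: float = 0.2,
                        base_mean: float = 100.0, seed: int = 0
                        ) -> tuple[ExpressionSet, ExpressionSet, ExprTruth]:
    """Stage-linked coexpression modules in a normalized matrix plus an
    independent NB count matrix with planted breed fold changes.

    Module genes follow sqrt(rho) x latent + sqrt(1-rho) x noise so the
    planted within-module correlation is ``module_cor``; each module's
    latent factor tracks one follicle-cycle stage. DE genes are drawn from
    the non-module background with alternating-sign planted log2FC between
    the two breeds.
    """
    if not 0 < module_cor < 1:
        raise ConfigError("module_cor must lie in (0, 1)")
    if dispersion <= 0:
        raise ConfigError("dispersion must be positive")
    if n_modules * module_size > n_genes:
        raise ConfigError("module genes exceed n_genes")
    if n_de > n_genes - n_modules * module_size:
        raise ConfigError("n_de exceeds available background genes")
    rng = np.random.default_rng(seed)
    stages = [s for s in STAGE_MONTHS for _ in range(samples_per_stage)]
    n_samples = len(stages)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    months = [STAGE_MONTHS[s][i % len(STAGE_MONTHS[s])]
              for i, s in enumerate(stages)]
    breeds = ["chuannan_black" if i % 2 == 0 else "shanbei_cashmere"
              for i in range(n_samples)]
    traits = pd.DataFrame({"month": months, "stage": stages, "breed": breeds},
                          index=samples)
    genes = [f"EXP{i + 1:05d}" for i in range(n_genes)]

    stage_names = list(STAGE_MONTHS)
    stage_idx = np.array([stage_names.index(s) for s in stages])
    latents = np.empty((n_modules, n_samples))
    norm = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    assignment = {g: 0 for g in genes}
    for m in range(n_modules):
        f = (stage_idx == m % 4).astype(float) * 2.0 \
            + rng.normal(0, 0.7, n_samples)
        f = (f - f.mean()) / f.std()
        latents[m] = f
        lo, hi = m * module_size, (m + 1) * module_size
        eps = rng.normal(0.0, 1.0, size=(module_size, n_samples))
        # heterogeneous loadings centred on sqrt(module_cor): mean pairwise
        # within-module correlation stays ~module_cor while the connectivity
        # spread gives the network its hub structure
        load = np.clip(rng.normal(np.sqrt(module_cor), 0.08, module_size),
                       0.3, 0.98)
        norm[lo:hi] = load[:, None] * f[None, :] \
            + np.sqrt(1.0 - load[:, None] ** 2) * eps
        for g in genes[lo:hi]:
            assignment[g] = m + 1
    normalized = ExpressionSet(
        values=pd.DataFrame(norm, index=genes, columns=samples),
        samples=traits)

    mu = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    group2 = np.array([b == "shanbei_cashmere" for b in breeds])
    de_genes: dict[str, float] = {}
    de_pool = genes[n_modules * module_size:]
    lfc_vec = np.zeros(n_genes)
    if lfc != 0.0:
        for j in range(n_de):
            g = de_pool[j]
            signed = lfc if j % 2 == 0 else -lfc
            de_genes[g] = signed
            lfc_vec[genes.index(g)] = signed
    mean_mat = mu[:, None] * np.power(2.0, lfc_vec[:, None]
                                      * group2[None, :].astype(float))
    if dispersion < 1e-6:
        counts = rng.poisson(mean_mat)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mean_mat))
    counts_es = ExpressionSet(
        values=pd.DataFrame(counts.astype(int), index=genes, columns=samples),
        samples=traits)
    truth = ExprTruth(
        de_genes=de_genes, module_assignment=assignment,
        module_latent=pd.DataFrame(latents,
                                   index=[f"M{m + 1}" for m in range(n_modules)],
                                   columns=samples),
        trait_table=traits,
        nb_dispersion={g: dispersion for g in genes})
    return counts_es, normalized, truth


# ---------------------------------------------------------------------------
# Annotation and pathway tables tied to the planted sweeps
# ---------------------------------------------------------------------------

def simulate_annotation_and_pathways(chrom_length_bp: int, n_genes: int,
                                     sweep_truth: SweepTruth | None = None,
                                     n_pathways: int = 10,
                                     enriched_pathway_genes: list[str] | None = None,
                                     genes_per_sweep: int = 2,
                                     gene_length_bp: int = 20_000,
                                     pathway_size: int = 15,
                                     seed: int = 0, chrom: str = "chr1"
                                     ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Disjoint gene intervals tiling the chromosome, with designated genes
    placed strictly inside each planted sweep window (1 kb margins so no
    gene straddles a sweep boundary), plus a pathway table in which one
    pathway is enriched for a designated gene set.
    """
    rng = np.random.default_rng(seed)
    sweeps = sweep_truth.sweep_windows if sweep_truth else []
    rows = []
    gid = 0

    def next_name() -> str:
        nonlocal gid
        gid += 1
        return f"G{gid:04d}"

    sweep_genes = []
    for _, s, e in sweeps:
        inner_len = (e - s) - 2000
        span = inner_len // genes_per_sweep
        glen = min(gene_length_bp, span - 100)
        for j in range(genes_per_sweep):
            gs = s + 1000 + j * span
            name = next_name()
            rows.append((chrom, gs, gs + glen, name))
            sweep_genes.append(name)
    n_background = n_genes - len(sweep_genes)
    if n_background < 0:
        raise ConfigError("n_genes smaller than the sweep gene count")
    # allowed territory: outside sweeps plus 1 kb margins
    blocked = sorted((max(0, s - 1000), min(chrom_length_bp, e + 1000))
                     for _, s, e in sweeps)
    gaps, cursor = [], 0
    for s, e in blocked:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < chrom_length_bp:
        gaps.append((cursor, chrom_length_bp))
    placed = 0
    min_pitch = gene_length_bp + 1000
    capacities = [max(0, (e - s - 200) // min_pitch) for s, e in gaps]
    if sum(capacities) < n_background:
        raise ConfigError("genes do not fit on the chromosome without overlap")
    total_cap = sum(capacities)
    for (s, e), cap in zip(gaps, capacities):
        want = min(cap, n_background - placed,
                   max(1, round(n_background * cap / total_cap)) if cap else 0)
        if want <= 0:
            continue
        pitch = (e - s) // want
        for j in range(want):
            gs = s + j * pitch + 100
            rows.append((chrom, gs, gs + gene_length_bp, next_name()))
            placed += 1
    # top up any rounding shortfall in the gaps with spare capacity
    if placed < n_background:
        for (s, e), cap in zip(gaps, capacities):
            while placed < n_background:
                gs = e - 100 - (gene_length_bp + 1000)
                taken = [r for r in rows if r[1] >= s and r[2] <= e]
                last_end = max((r[2] for r in taken), default=s)
                gs = last_end + 1000
                if gs + gene_length_bp > e - 100:
                    break
                rows.append((chrom, gs, gs + gene_length_bp, next_name()))
                placed += 1
            if placed >= n_background:
                break
    if placed < n_background:
        raise ConfigError("genes do not fit on the chromosome without overlap")
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    intervals["in_sweep"] = intervals["gene"].isin(sweep_genes)
    intervals = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)

    all_genes = intervals["gene"].tolist()
    if enriched_pathway_genes is None:
        enriched_pathway_genes = sweep_genes or all_genes[:pathway_size]
    pathways: dict[str, list[str]] = {"PW01": list(enriched_pathway_genes)}
    others = [g for g in all_genes if g not in set(enriched_pathway_genes)]
    for p in range(2, n_pathways + 1):
        members = rng.choice(others, size=min(pathway_size, len(others)),
                             replace=False)
        pathways[f"PW{p:02d}"] = sorted(members.tolist())
    return intervals, pathways
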