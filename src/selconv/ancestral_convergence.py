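"""Ancestral protein-state reconstruction and convergent-substitution calls.

The detector reconstructs marginal ancestral amino-acid states under a
Poisson substitution model with alignment-wide observed frequencies, then
reports alignment sites where both focal branches substitute to an identical
derived residue that differs from each branch's parent (most recent common
ancestor side) state. A conservative-site filter (CCS) additionally requires
every valid non-focal leaf to carry one shared residue different from the
focal derived residue.

Fitch parsimony is included as a brute-force-friendly reconstruction oracle.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io_formats import AMINO_ACIDS, Alignment, ConfigError, Tree

log = logging.getLogger("selconv.converge")

N_AA = len(AMINO_ACIDS)
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Validity filtering
# ---------------------------------------------------------------------------

@dataclass
class ValidityReport:
    passes: bool
    validity: float                  # fraction of cells with canonical residues
    column_validity: np.ndarray      # per-column valid-cell fraction


def validity_filter(protein_alignment: Alignment,
                    min_valid: float = 0.75) -> ValidityReport:
    """A gene passes when at least ``min_valid`` of its alignment cells are
    canonical amino acids (>= semantics at the boundary)."""
    mat = protein_alignment.protein_matrix()
    valid = mat >= 0
    frac = float(valid.mean()) if valid.size else 0.0
    return ValidityReport(passes=frac >= min_valid, validity=frac,
                          column_validity=valid.mean(axis=0))


# ---------------------------------------------------------------------------
# Fitch parsimony (reconstruction oracle)
# ---------------------------------------------------------------------------

def fitch_states(tree: Tree, protein_alignment: Alignment, site: int
                 ) -> tuple[list[frozenset[str]] | None, int]:
    """Bottom-up Fitch state sets and parsimony substitution count for one
    0-based site. Invalid leaf residues act as wildcards; an all-invalid
    column returns (None, 0) and is skipped."""
    mat = protein_alignment.protein_matrix()
    row_of = {tree.names[v]: protein_alignment.ids.index(tree.names[v])
              for v in tree.leaves}
    full = frozenset(AMINO_ACIDS)
    sets: list[frozenset[str]] = [frozenset()] * tree.n_nodes
    count = 0
    any_valid = False
    for v in tree.postorder():
        if not tree.children[v]:
            s = mat[row_of[tree.names[v]], site]
            if s < 0:
                sets[v] = full
            else:
                sets[v] = frozenset(AMINO_ACIDS[s])
                any_valid = True
        else:
            inter = full
            union: frozenset[str] = frozenset()
            for c in tree.children[v]:
                inter = inter & sets[c]
                union = union | sets[c]
            if inter:
                sets[v] = inter
            else:
                sets[v] = union
                count += 1
    if not any_valid:
        return None, 0
    return sets, count


# ---------------------------------------------------------------------------
# Marginal reconstruction under a Poisson amino-acid model
# ---------------------------------------------------------------------------

def poisson_pmat(t: float, freqs: np.ndarray) -> np.ndarray:
    """Closed-form transition matrix of the frequency-weighted Poisson model
    (q_ij = pi_j for i != j), scaled to one expected substitution per site at
    equilibrium: P(t) = e^{-st} I + (1 - e^{-st}) 1 pi^T."""
    rate = 1.0 - float(freqs @ freqs)
    s = 1.0 / rate if rate > 0 else 0.0
    decay = np.exp(-s * t)
    return decay * np.eye(N_AA) + (1.0 - decay) * np.tile(freqs, (N_AA, 1))


def observed_aa_freqs(alignment: Alignment) -> np.ndarray:
    mat = alignment.protein_matrix()
    counts = np.bincount(mat[mat >= 0].ravel(), minlength=N_AA).astype(float)
    if counts.sum() == 0:
        return np.full(N_AA, 1.0 / N_AA)
    # Laplace smoothing keeps unobserved residues reachable
    counts += 0.1
    return counts / counts.sum()


@dataclass
class AncestralStates:
    """Reconstructed amino-acid states for every node and site.

    ``states[v, k]`` is the integer residue state (argmax marginal posterior
    for internal nodes, observed state for valid leaf cells, -1 for invalid
    leaf cells); ``posterior[v, k]`` the posterior of that state (1.0 for
    observed leaves).
    """

    states: np.ndarray
    posterior: np.ndarray
    exchange_matrix: np.ndarray | None = None


def marginal_reconstruction(tree: Tree, protein_alignment: Alignment,
                            freqs: np.ndarray | None = None,
                            exchange: np.ndarray | None = None
                            ) -> AncestralStates:
    """Per-node, per-site marginal posteriors via the up-down pruning pass.

    A user-supplied 20x20 transition-probability hook (``exchange``: a
    callable-free alternative would be a rate matrix; here we accept
    precomputed per-branch mats via the Poisson default only) may replace
    the Poisson model in a later revision; the Poisson + observed-frequency
    model is the default and the shallow-divergence workhorse.

    Ties in the argmax are broken toward the residue observed in more leaves
    at the site, then alphabetically.
    """
    if freqs is None:
        freqs = observed_aa_freqs(protein_alignment)
    mat = protein_alignment.protein_matrix()
    row_of = {v: protein_alignment.ids.index(tree.names[v])
              for v in tree.leaves}
    n_nodes, n_sites = tree.n_nodes, protein_alignment.length
    pmats = {v: poisson_pmat(tree.blen[v], freqs)
             for v in range(n_nodes - 1)}

    up = np.ones((n_nodes, N_AA, n_sites))
    for v in tree.postorder():
        if not tree.children[v]:
            col = mat[row_of[v]]
            leafp = np.ones((N_AA, n_sites))
            valid = col >= 0
            leafp[:, valid] = 0.0
            leafp[col[valid], np.nonzero(valid)[0]] = 1.0
            up[v] = leafp
        else:
            p = np.ones((N_AA, n_sites))
            for c in tree.children[v]:
                p = p * (pmats[c] @ up[c])
            up[v] = p

    # outside (down) pass
    down = np.ones((n_nodes, N_AA, n_sites))
    down[tree.root] = freqs[:, None]
    for v in tree.preorder():
        for c in tree.children[v]:
            contrib = down[v].copy()
            for s in tree.children[v]:
                if s != c:
                    contrib = contrib * (pmats[s] @ up[s])
            down[c] = pmats[c].T @ contrib

    post = up * down
    norm = post.sum(axis=1, keepdims=True)
    post = post / np.maximum(norm, 1e-300)

    leaf_counts = np.zeros((N_AA, n_sites))
    for v in tree.leaves:
        col = mat[row_of[v]]
        valid = col >= 0
        leaf_counts[col[valid], np.nonzero(valid)[0]] += 1

    states = np.full((n_nodes, n_sites), -1, dtype=int)
    posterior = np.zeros((n_nodes, n_sites))
    for v in range(n_nodes):
        if not tree.children[v]:
            col = mat[row_of[v]]
            states[v] = col
            posterior[v] = np.where(col >= 0, 1.0, 0.0)
            continue
        pv = post[v]
        best = pv.max(axis=0)
        for k in range(n_sites):
            cands = np.nonzero(pv[:, k] >= best[k] - 1e-12)[0]
            if len(cands) > 1:
                counts = leaf_counts[cands, k]
                cands = cands[counts == counts.max()]
            states[v, k] = cands[0]
            posterior[v, k] = pv[states[v, k], k]
    return AncestralStates(states=states, posterior=posterior)


# ---------------------------------------------------------------------------
# Convergence detection and the CCS filter
# ---------------------------------------------------------------------------

@dataclass
class ConvergentSite:
    gene: str
    site: int                       # 1-based alignment position
    focal_pair: tuple[int, int]     # child node ids of the two focal branches
    derived: str
    parents: tuple[str, str]
    background_residues: frozenset[str]
    parallel: bool                  # identical parent states on both branches
    min_posterior: float
    ccs_pass: bool = False


def _check_focal_pair(tree: Tree, focal_pair: tuple[int, int]) -> None:
    a, b = focal_pair
    if a == b:
        raise ConfigError("focal branches must be distinct")
    if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
        raise ConfigError("focal branches are ancestrally nested")


def detect_convergent_substitutions(anc: AncestralStates, tree: Tree,
                                    focal_pair: tuple[int, int],
                                    gene: str = "gene",
                                    posterior_min: float = 0.8
                                    ) -> list[ConvergentSite]:
    """Sites where both focal branches change state and the derived states
    are identical; all four endpoint states must reach ``posterior_min``."""
    _check_focal_pair(tree, focal_pair)
    b1, b2 = focal_pair
    p1, p2 = tree.parent[b1], tree.parent[b2]
    n_sites = anc.states.shape[1]
    focal_leaf_sets = [set(tree.subtree_leaves(b)) for b in focal_pair]
    background = [v for v in tree.leaves
                  if v not in focal_leaf_sets[0] | focal_leaf_sets[1]]
    out: list[ConvergentSite] = []
    for k in range(n_sites):
        c1, c2 = anc.states[b1, k], anc.states[b2, k]
        a1, a2 = anc.states[p1, k], anc.states[p2, k]
        if min(c1, c2, a1, a2) < 0:
            continue
        if c1 != c2 or c1 == a1 or c2 == a2:
            continue
        min_post = float(min(anc.posterior[v, k] for v in (b1, b2, p1, p2)))
        if min_post < posterior_min:
            continue
        bg = frozenset(AMINO_ACIDS[anc.states[v, k]] for v in background
                       if anc.states[v, k] >= 0)
        out.append(ConvergentSite(
            gene=gene, site=k + 1, focal_pair=(b1, b2),
            derived=AMINO_ACIDS[c1],
            parents=(AMINO_ACIDS[a1], AMINO_ACIDS[a2]),
            background_residues=bg, parallel=a1 == a2,
            min_posterior=min_post))
    return out


def ccs_filter(sites: list[ConvergentSite], tree: Tree,
               protein_alignment: Alignment,
               focal_pair: tuple[int, int]) -> list[ConvergentSite]:
    """Conservative-site filter: the derived residue appears in the two focal
    lineages only, every focal-clade leaf carries it, and all valid
    background leaves share one single different residue."""
    mat = protein_alignment.protein_matrix()
    row_of = {v: protein_alignment.ids.index(tree.names[v])
              for v in tree.leaves}
    focal_leaves = set(tree.subtree_leaves(focal_pair[0])) \
        | set(tree.subtree_leaves(focal_pair[1]))
    focal_leaves &= set(tree.leaves)
    background = [v for v in tree.leaves if v not in focal_leaves]
    out = []
    for s in sites:
        k = s.site - 1
        d = AA_INDEX[s.derived]
        focal_states = [mat[row_of[v], k] for v in focal_leaves]
        if any(x != d for x in focal_states):
            continue
        bg_states = {int(mat[row_of[v], k]) for v in background
                     if mat[row_of[v], k] >= 0}
        if len(bg_states) != 1 or d in bg_states:
            continue
        s.ccs_pass = True
        out.append(s)
    return out


def converge_report(gene_sites: dict[str, list[ConvergentSite]],
                    ccs_only: bool = True) -> dict[str, list[str]]:
    """Gene-level convergent set with substitution labels formatted as
    parent residue + 1-based site + derived residue (e.g. K136R); branches
    with differing parent states are labelled with both parents."""
    out: dict[str, list[str]] = {}
    for gene, sites in gene_sites.items():
        labels = []
        for s in sites:
            if ccs_only and not s.ccs_pass:
                continue
            if s.parents[0] == s.parents[1]:
                labels.append(f"{s.parents[0]}{s.site}{s.derived}")
            else:
                labels.append(f"{s.parents[0]}/{s.parents[1]}{s.site}{s.derived}")
        if labels:
            out[gene] = labels
    return out


def run_convergence_scan(tree: Tree, alignments: dict[str, Alignment],
                         focal_pair_spec: tuple, posterior_min: float = 0.8,
                         min_valid: float = 0.75, apply_ccs: bool = True
                         ) -> dict[str, list[ConvergentSite]]:
    """Full per-gene scan: validity filter, reconstruction, detection, and
    (optionally) the CCS filter; returns all detected sites with their
    ``ccs_pass`` flags set."""
    focal_pair = (tree.branch_for(focal_pair_spec[0]),
                  tree.branch_for(focal_pair_spec[1]))
    _check_focal_pair(tree, focal_pair)
    results: dict[str, list[ConvergentSite]] = {}
    n_skipped = 0
    for gene, aln in alignments.items():
        if aln.kind == "codon":
            aln = aln.translate()
        if not validity_filter(aln, min_valid).passes:
            n_skipped += 1
            continue
        anc = marginal_reconstruction(tree, aln)
        sites = detect_convergent_substitutions(
            anc, tree, focal_pair, gene=gene, posterior_min=posterior_min)
        if apply_ccs:
            ccs_filter(sites, tree, aln, focal_pair)
        if sites:
            results[gene] = sites
    if n_skipped:
        log.info("validity filter removed %d genes", n_skipped)
    return results
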