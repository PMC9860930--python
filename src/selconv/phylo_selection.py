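"""Codon-model selection tests on a fixed species tree.

Implements a Goldman–Yang-style (GY94) codon substitution process over the 61
sense codons of the universal code, Felsenstein pruning likelihoods, bounded
quasi-Newton model fitting, and the two likelihood-ratio tests used to call
rapidly evolving genes (branch model, REG) and positively selected genes
(branch-site model, PSG) on a designated foreground branch. Branch lengths
are taken from the input tree (expected substitutions per codon) and held
fixed; only rate parameters are optimised.

A counting-based per-branch dN/dS (Nei–Gojobori-style over reconstructed or
true ancestral codons) is provided as a fast cross-check of the likelihood
machinery.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from Bio.Data import CodonTable

from .io_formats import Alignment, ConfigError, Tree

log = logging.getLogger("selconv.phylo")

# ---------------------------------------------------------------------------
# Codon alphabet: 61 sense codons of the universal code
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "TCAG"
CODONS: list[str] = [a + b + c
                     for a in _BASES for b in _BASES for c in _BASES
                     if a + b + c not in _TABLE.stop_codons]
N_CODONS = len(CODONS)              # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = [_TABLE.forward_table[c] for c in CODONS]

_PURINES = {"A", "G"}


def _pair_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = ({a, b} <= _PURINES) or ({a, b} <= {"C", "T"})
            nonsyn[i, j] = CODON_AA[i] != CODON_AA[j]
    return single, transition, nonsyn


SINGLE_STEP, IS_TRANSITION, IS_NONSYN = _pair_masks()


def f1x4_frequencies(nuc_freqs) -> np.ndarray:
    """F1x4 equilibrium codon frequencies from nucleotide frequencies given
    in A, C, G, T order."""
    f = dict(zip("ACGT", np.asarray(nuc_freqs, dtype=float)))
    pi = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in CODONS])
    return pi / pi.sum()


def observed_nuc_freqs(alignment: Alignment) -> np.ndarray:
    counts = np.zeros(4)
    for s in alignment.seqs:
        for i, b in enumerate("ACGT"):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def gy94_rate_matrix(codon_freqs: np.ndarray, kappa: float, omega: float,
                     scale: bool = True) -> np.ndarray:
    """GY94 generator: q_ij = pi_j * kappa^[transition] * omega^[nonsyn] for
    single-nucleotide neighbours, 0 otherwise; rows sum to zero; scaled so
    the expected rate at equilibrium is one substitution per codon."""
    rate = np.where(IS_TRANSITION, kappa, 1.0) * np.where(IS_NONSYN, omega, 1.0)
    q = np.where(SINGLE_STEP, rate * codon_freqs[None, :], 0.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        mean_rate = -(codon_freqs * np.diag(q)).sum()
        if mean_rate > 0:
            q = q / mean_rate
    return q


def gy94_mean_rate(codon_freqs: np.ndarray, kappa: float,
                   omega: float) -> float:
    """Equilibrium mean rate of the *unscaled* GY94 generator; the relative
    speed of site classes in mixture models."""
    q = gy94_rate_matrix(codon_freqs, kappa, omega, scale=False)
    return float(-(codon_freqs * np.diag(q)).sum())


class CodonModel:
    """Transition-probability factory with cached spectral decompositions.

    GY94 is time-reversible, so ``D^{1/2} Q D^{-1/2}`` is symmetric and a
    single `eigh` per (kappa, omega) serves every branch length.
    """

    def __init__(self, codon_freqs: np.ndarray):
        self.pi = np.asarray(codon_freqs, dtype=float)
        self._sqrt = np.sqrt(self.pi)
        self._cache: dict[tuple[float, float], tuple] = {}

    def _decompose(self, kappa: float, omega: float):
        key = (round(kappa, 12), round(omega, 12))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        q = gy94_rate_matrix(self.pi, kappa, omega, scale=False)
        rho = float(-(self.pi * np.diag(q)).sum())
        b = (self._sqrt[:, None] * q) / self._sqrt[None, :]
        w, u = np.linalg.eigh(0.5 * (b + b.T))
        left = u.T * self._sqrt[None, :]          # U^T D^{1/2}
        right = (u.T / self._sqrt[None, :]).T     # D^{-1/2} U
        self._cache[key] = (w, right, left, rho)
        if len(self._cache) > 256:
            self._cache.pop(next(iter(self._cache)))
        return self._cache[key]

    def mean_rate(self, kappa: float, omega: float) -> float:
        return self._decompose(kappa, omega)[3]

    def pmat(self, t: float, kappa: float, omega: float,
             rate: float | None = None) -> np.ndarray:
        """P(t); by default the generator is normalized to one expected
        substitution per codon per unit t. ``rate`` overrides the factor
        multiplying t (used by mixture models that share one scale across
        site classes)."""
        w, right, left, rho = self._decompose(kappa, omega)
        factor = (1.0 / rho if rho > 0 else 0.0) if rate is None else rate
        p = (right * np.exp(w * t * factor)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        return p


# ---------------------------------------------------------------------------
# Alignment preparation & pruning likelihood
# ---------------------------------------------------------------------------

def encode_codon_alignment(aln: Alignment) -> np.ndarray:
    """(n_seqs, n_codons) integer codon states; -1 for gap/ambiguous/stop."""
    n = aln.n_codons
    out = np.full((aln.n_seqs, n), -1, dtype=int)
    for r, s in enumerate(aln.seqs):
        for k in range(n):
            out[r, k] = CODON_INDEX.get(s[3 * k:3 * k + 3], -1)
    return out


def prepare_patterns(tree: Tree, aln: Alignment
                     ) -> tuple[list[int], np.ndarray, np.ndarray, int]:
    """Map alignment rows to tree leaves, drop columns containing any
    invalid codon (complete-case sites) and compress to site patterns.

    Returns (leaf node ids, patterns (n_leaves, n_patterns), weights,
    n_dropped_columns).
    """
    leaves = tree.leaves
    missing = set(n for n in tree.leaf_names) - set(aln.ids)
    if missing:
        raise ConfigError(f"alignment lacks taxa {sorted(missing)}")
    mat = encode_codon_alignment(aln)
    rows = np.array([aln.ids.index(tree.names[v]) for v in leaves])
    mat = mat[rows]
    keep = (mat >= 0).all(axis=0)
    dropped = int((~keep).sum())
    if dropped:
        log.debug("dropped %d incomplete codon columns", dropped)
    mat = mat[:, keep]
    if mat.shape[1] == 0:
        raise ConfigError("no complete codon columns left after filtering")
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return leaves, patterns, weights.astype(float), dropped


def _site_likelihoods(tree: Tree, leaves: list[int], patterns: np.ndarray,
                      pmats: dict[int, np.ndarray], pi: np.ndarray
                      ) -> np.ndarray:
    """Felsenstein pruning: per-pattern likelihoods at the root."""
    n_pat = patterns.shape[1]
    partial: dict[int, np.ndarray] = {}
    leaf_row = {v: r for r, v in enumerate(leaves)}
    for v in tree.postorder():
        if not tree.children[v]:
            p = np.zeros((N_CODONS, n_pat))
            p[patterns[leaf_row[v]], np.arange(n_pat)] = 1.0
            partial[v] = p
        else:
            p = np.ones((N_CODONS, n_pat))
            for c in tree.children[v]:
                p *= pmats[c] @ partial.pop(c)
            partial[v] = p
    return pi @ partial[tree.root]


def log_likelihood(tree: Tree, alignment: Alignment, kappa: float,
                   omega, codon_freqs: np.ndarray | None = None) -> float:
    """Pruning log-likelihood of a codon alignment under GY94.

    ``omega`` is a scalar (shared across branches) or a mapping from branch
    (child node id) to omega.
    """
    if codon_freqs is None:
        codon_freqs = f1x4_frequencies(observed_nuc_freqs(alignment))
    model = CodonModel(codon_freqs)
    leaves, patterns, weights, _ = prepare_patterns(tree, alignment)
    if np.isscalar(omega):
        omega_of = {v: float(omega) for v in range(tree.n_nodes - 1)}
    else:
        omega_of = {v: float(omega[v]) for v in range(tree.n_nodes - 1)}
    pmats = {v: model.pmat(tree.blen[v], kappa, omega_of[v])
             for v in range(tree.n_nodes - 1)}
    site_l = _site_likelihoods(tree, leaves, patterns, pmats, model.pi)
    return float(weights @ np.log(np.maximum(site_l, 1e-300)))


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

MODELS = ("one_ratio", "free_ratio", "two_ratio",
          "branch_site_null", "branch_site_alt")

# multi-start grid: branch-site likelihood surfaces are multimodal
_STARTS = [(1.0, 0.1), (2.0, 0.5), (4.0, 1.5)]


@dataclass
class FitResult:
    model: str
    lnL: float
    kappa: float
    params: dict
    converged: bool
    n_dropped_sites: int = 0


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


class _GeneData:
    """Per-gene precomputation shared by all model fits."""

    def __init__(self, tree: Tree, alignment: Alignment,
                 codon_freqs: np.ndarray | None = None):
        self.tree = tree
        if codon_freqs is None:
            codon_freqs = f1x4_frequencies(observed_nuc_freqs(alignment))
        self.model = CodonModel(codon_freqs)
        (self.leaves, self.patterns, self.weights,
         self.n_dropped) = prepare_patterns(tree, alignment)

    def lnl_branch(self, kappa: float, omega_of: dict[int, float]) -> float:
        pmats = {v: self.model.pmat(self.tree.blen[v], kappa, omega_of[v])
                 for v in range(self.tree.n_nodes - 1)}
        sl = _site_likelihoods(self.tree, self.leaves, self.patterns, pmats,
                               self.model.pi)
        return float(self.weights @ np.log(np.maximum(sl, 1e-300)))

    def site_l_for(self, kappa: float, omega_of: dict[int, float]) -> np.ndarray:
        pmats = {v: self.model.pmat(self.tree.blen[v], kappa, omega_of[v])
                 for v in range(self.tree.n_nodes - 1)}
        return _site_likelihoods(self.tree, self.leaves, self.patterns, pmats,
                                 self.model.pi)

    def lnl_branch_site(self, kappa: float, p0: float, p1: float,
                        omega0: float, omega2: float, foreground: int) -> float:
        """Branch-site model A mixture: classes 0 (w0 everywhere),
        1 (neutral), 2a (w0 background, w2 foreground), 2b (1 background,
        w2 foreground); p2a/p2b split p2 proportionally to p0:p1.

        All classes share one rate normalization -- the proportion-weighted
        mean rate of the background process -- so branch lengths are
        calibrated on the background mixture and an elevated omega2 raises
        the foreground substitution rate, as in codeml."""
        edges = range(self.tree.n_nodes - 1)
        p2 = max(1.0 - p0 - p1, 0.0)
        denom = p0 + p1 if p0 + p1 > 0 else 1.0
        p2a, p2b = p2 * p0 / denom, p2 * p1 / denom
        rho0 = self.model.mean_rate(kappa, omega0)
        rho1 = self.model.mean_rate(kappa, 1.0)
        rho_bar = (p0 + p2a) * rho0 + (p1 + p2b) * rho1
        rate = 1.0 / rho_bar if rho_bar > 0 else 0.0

        def site_l(bg: float, fg: float) -> np.ndarray:
            pmats = {v: self.model.pmat(
                self.tree.blen[v], kappa,
                fg if v == foreground else bg, rate=rate)
                for v in edges}
            return _site_likelihoods(self.tree, self.leaves, self.patterns,
                                     pmats, self.model.pi)

        l0 = site_l(omega0, omega0)
        l1 = site_l(1.0, 1.0)
        l2a = site_l(omega0, omega2)
        l2b = site_l(1.0, omega2)
        mix = p0 * l0 + p1 * l1 + p2a * l2a + p2b * l2b
        return float(self.weights @ np.log(np.maximum(mix, 1e-300)))


def fit_model(tree: Tree, alignment: Alignment, model: str,
              foreground: int | None = None, init: dict | None = None,
              tol: float = 1e-6, codon_freqs: np.ndarray | None = None,
              max_restarts: int = 3) -> FitResult:
    """Maximise the pruning log-likelihood of one gene under the requested
    model by bounded quasi-Newton (L-BFGS-B) from multiple starts.

    ``foreground`` is the child node id of the foreground branch (required
    for two_ratio and the branch-site models).
    """
    if model not in MODELS:
        raise ConfigError(f"unknown model {model!r}")
    if model in ("two_ratio", "branch_site_null", "branch_site_alt") \
            and foreground is None:
        raise ConfigError(f"model {model} requires a foreground branch")
    data = _GeneData(tree, alignment, codon_freqs)
    edges = list(range(tree.n_nodes - 1))

    if model == "one_ratio":
        def unpack(x):
            return {"kappa": math.exp(x[0]), "omega": math.exp(x[1])}
        def nll(x):
            p = unpack(x)
            return -data.lnl_branch(p["kappa"],
                                    {v: p["omega"] for v in edges})
        starts = [[math.log(k), math.log(w)] for k, w in _STARTS]
        bounds = [(-5, 5), (-9, 4)]
    elif model == "two_ratio":
        def unpack(x):
            return {"kappa": math.exp(x[0]), "omega_background": math.exp(x[1]),
                    "omega_foreground": math.exp(x[2])}
        def nll(x):
            p = unpack(x)
            om = {v: (p["omega_foreground"] if v == foreground
                      else p["omega_background"]) for v in edges}
            return -data.lnl_branch(p["kappa"], om)
        starts = [[math.log(k), math.log(w), math.log(w)] for k, w in _STARTS]
        bounds = [(-5, 5), (-9, 4), (-9, 4)]
    elif model == "free_ratio":
        def unpack(x):
            return {"kappa": math.exp(x[0]),
                    "omega_by_branch": {v: math.exp(x[1 + i])
                                        for i, v in enumerate(edges)}}
        def nll(x):
            p = unpack(x)
            return -data.lnl_branch(p["kappa"], p["omega_by_branch"])
        starts = [[math.log(k)] + [math.log(w)] * len(edges)
                  for k, w in _STARTS]
        bounds = [(-5, 5)] + [(-9, 4)] * len(edges)
    else:  # branch-site null / alt
        alt = model == "branch_site_alt"
        def unpack(x):
            s = _sigmoid(x[2])           # p0 + p1
            r = _sigmoid(x[3])           # p0 / (p0 + p1)
            p = {"kappa": math.exp(x[0]), "omega0": _sigmoid(x[1]),
                 "p0": s * r, "p1": s * (1 - r)}
            p["omega2"] = 1.0 + math.exp(x[4]) if alt else 1.0
            return p
        def nll(x):
            p = unpack(x)
            return -data.lnl_branch_site(p["kappa"], p["p0"], p["p1"],
                                         p["omega0"], p["omega2"], foreground)
        starts = []
        for k, w in _STARTS:
            base = [math.log(k), _logit(min(w, 0.9)), _logit(0.8), _logit(0.6)]
            if alt:
                base.append(math.log(max(w * 2, 1.0)))
            starts.append(base)
        bounds = [(-5, 5), (-14, 14), (-14, 14), (-14, 14)]
        if alt:
            bounds.append((-10, 5))

    if init is not None:
        starts = [_pack_init(model, init, edges)] + starts

    best = None
    n_ok = 0
    for x0 in starts:
        try:
            # ftol is relative in L-BFGS-B; divide by the lnL magnitude so
            # `tol` acts as an absolute log-likelihood tolerance
            scale = max(abs(nll(np.asarray(x0, dtype=float))), 1.0)
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": tol / scale,
                                             "gtol": 1e-7, "maxiter": 1000})
        except Exception as exc:  # pragma: no cover - numerical edge cases
            log.warning("optimizer failure from start %s: %s", x0, exc)
            continue
        n_ok += int(bool(res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    params = unpack(best.x)
    kappa = params.pop("kappa")
    converged = n_ok > 0 and np.isfinite(best.fun)
    if not converged:
        log.warning("fit of %s did not converge (%d/%d starts ok)",
                    model, n_ok, len(starts))
    return FitResult(model=model, lnL=-float(best.fun), kappa=kappa,
                     params=params, converged=converged,
                     n_dropped_sites=data.n_dropped)


def _pack_init(model: str, init: dict, edges: list[int]) -> list[float]:
    if model == "one_ratio":
        return [math.log(init["kappa"]), math.log(init["omega"])]
    if model == "two_ratio":
        return [math.log(init["kappa"]), math.log(init["omega_background"]),
                math.log(init["omega_foreground"])]
    if model == "free_ratio":
        return [math.log(init["kappa"])] + \
            [math.log(init["omega_by_branch"][v]) for v in edges]
    s = init["p0"] + init["p1"]
    x = [math.log(init["kappa"]), _logit(init["omega0"]), _logit(s),
         _logit(init["p0"] / s if s > 0 else 0.5)]
    if model == "branch_site_alt":
        x.append(math.log(max(init.get("omega2", 2.0) - 1.0, 1e-6)))
    return x


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    gene: str
    test: str
    lnL_null: float
    lnL_alt: float
    statistic: float
    df: int
    p_value: float
    foreground_omega_hat: float
    background_omega_hat: float | None
    verdict: bool
    elevated: bool
    converged: bool
    q_value: float = float("nan")


def _lrt(lnl_null: float, lnl_alt: float, df: int,
         boundary_mixture: bool = False) -> tuple[float, float]:
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p = float(stats.chi2.sf(stat, df))
    if boundary_mixture:
        # 50:50 mixture of chi2_0 and chi2_1 at the omega2 = 1 boundary
        p = 0.5 * p if stat > 0 else 1.0
    return stat, p


def branch_model_test(gene: str, tree: Tree, alignment: Alignment,
                      foreground: int, alpha: float = 0.05,
                      tol: float = 1e-6) -> LRTResult:
    """REG detector: one-ratio vs two-ratio branch model, df = 1.

    The candidate verdict requires both p < alpha and an elevated foreground
    omega; the direction flag is reported separately so a directionless rule
    can be applied downstream.
    """
    null = fit_model(tree, alignment, "one_ratio", tol=tol)
    alt = fit_model(tree, alignment, "two_ratio", foreground=foreground,
                    tol=tol)
    stat, p = _lrt(null.lnL, alt.lnL, 1)
    fg = alt.params["omega_foreground"]
    bg = alt.params["omega_background"]
    elevated = fg > bg
    conv = null.converged and alt.converged
    return LRTResult(gene=gene, test="branch", lnL_null=null.lnL,
                     lnL_alt=alt.lnL, statistic=stat, df=1, p_value=p,
                     foreground_omega_hat=fg, background_omega_hat=bg,
                     verdict=bool(conv and p < alpha and elevated),
                     elevated=elevated, converged=conv)


def branch_site_test(gene: str, tree: Tree, alignment: Alignment,
                     foreground: int, alpha: float = 0.05, tol: float = 1e-6,
                     boundary_mixture: bool = False) -> LRTResult:
    """PSG detector: branch-site model A alternative (omega2 >= 1) vs null
    (omega2 = 1), df = 1, plain chi-square reference by default."""
    null = fit_model(tree, alignment, "branch_site_null",
                     foreground=foreground, tol=tol)
    alt = fit_model(tree, alignment, "branch_site_alt",
                    foreground=foreground, tol=tol,
                    init={**null.params, "kappa": null.kappa, "omega2": 2.0})
    stat, p = _lrt(null.lnL, alt.lnL, 1, boundary_mixture=boundary_mixture)
    conv = null.converged and alt.converged
    return LRTResult(gene=gene, test="branch_site", lnL_null=null.lnL,
                     lnL_alt=alt.lnL, statistic=stat, df=1, p_value=p,
                     foreground_omega_hat=alt.params["omega2"],
                     background_omega_hat=alt.params["omega0"],
                     verdict=bool(conv and p < alpha),
                     elevated=alt.params["omega2"] > 1.0, converged=conv)


def attach_q_values(results: list[LRTResult]) -> list[LRTResult]:
    """BH-adjusted q-values across a batch of tests (reported alongside the
    raw p < alpha rule, which is what drives the verdict)."""
    from statsmodels.stats.multitest import multipletests

    tested = [r for r in results if r.converged]
    if tested:
        q = multipletests([r.p_value for r in tested], method="fdr_bh")[1]
        for r, qi in zip(tested, q):
            r.q_value = float(qi)
    return results


# ---------------------------------------------------------------------------
# Counting-based per-branch dN/dS (NG86-style on ancestral codons)
# ---------------------------------------------------------------------------

def _ng86_site_counts(codon_idx: int) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon; mutations to
    stop codons are excluded from both."""
    cod = CODONS[codon_idx]
    syn = nonsyn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == cod[pos]:
                continue
            alt = cod[:pos] + b + cod[pos + 1:]
            j = CODON_INDEX.get(alt)
            if j is None:
                continue  # stop codon
            if CODON_AA[j] == CODON_AA[codon_idx]:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


def _path_changes(i: int, j: int) -> tuple[float, float]:
    """Average (syn, nonsyn) substitution counts over all single-step paths
    from codon i to codon j that avoid stop codons."""
    ci, cj = CODONS[i], CODONS[j]
    diff = [k for k in range(3) if ci[k] != cj[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, ok = i, 0.0, 0.0, True
        for pos in order:
            nxt_str = CODONS[cur][:pos] + cj[pos] + CODONS[cur][pos + 1:]
            nxt = CODON_INDEX.get(nxt_str)
            if nxt is None:
                ok = False
                break
            if CODON_AA[nxt] == CODON_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:  # every route passes a stop; count all steps nonsynonymous
        return 0.0, float(len(diff))
    syn = sum(p[0] for p in paths) / len(paths)
    nonsyn = sum(p[1] for p in paths) / len(paths)
    return syn, nonsyn


def counting_omega_per_branch(tree: Tree, codon_alignment: Alignment,
                              ancestral_codons: np.ndarray
                              ) -> dict[int, dict]:
    """Per-branch dN, dS and their ratio by counting differences between the
    endpoint codon sequences of each branch.

    ``ancestral_codons`` is an (n_nodes, n_sites) integer codon-state matrix
    covering at least the internal nodes (leaf rows may be filled from the
    alignment); -1 marks unavailable states, and such sites are skipped for
    the branch. omega is NaN with ``undefined=True`` whenever dS = 0.
    """
    mat = encode_codon_alignment(codon_alignment)
    states = np.array(ancestral_codons, dtype=int, copy=True)
    for v in tree.leaves:
        r = codon_alignment.ids.index(tree.names[v])
        states[v] = mat[r]
    out: dict[int, dict] = {}
    for v in range(tree.n_nodes - 1):
        par = tree.parent[v]
        ok = (states[v] >= 0) & (states[par] >= 0)
        nd = sd = n_sites = s_sites = 0.0
        for k in np.nonzero(ok)[0]:
            i, j = int(states[par, k]), int(states[v, k])
            s_cnt, n_cnt = _ng86_site_counts(i)
            s_sites += s_cnt
            n_sites += n_cnt
            if i != j:
                s_obs, n_obs = _path_changes(i, j)
                sd += s_obs
                nd += n_obs
        dn = nd / n_sites if n_sites > 0 else float("nan")
        ds = sd / s_sites if s_sites > 0 else float("nan")
        undefined = not (sd > 0)
        omega = dn / ds if not undefined else float("nan")
        out[v] = {"dN": dn, "dS": ds, "omega": omega, "undefined": undefined,
                  "n_nonsyn_subs": nd, "n_syn_subs": sd}
    return out
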