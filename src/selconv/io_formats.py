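"""Readers and writers for the external formats the pipeline touches.

Covers newick trees, FASTA alignments (codon and protein), VCF v4.2 variant
panels with population assignments, BED/GFF3 gene annotations, TSV expression
matrices and TSV pathway-membership tables, plus the run configuration and
logging setup shared by every stage.

Internal genomic coordinates are 0-based half-open everywhere; conversion to
and from 1-based conventions (VCF, GFF3) happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("selconv")


class FormatError(ValueError):
    """A file violates its declared format."""


class ConfigError(ValueError):
    """Inconsistent configuration or mismatched inputs."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide thresholds and window parameters.

    Defaults follow the published analysis protocol: 50 kb windows with a
    20 kb step, top 1% window overlap, MAF >= 0.05, at most 10% missing
    genotypes, LRT alpha 0.05, |log2FC| > 1 with FDR < 0.05, SD >= 0.5 gene
    filter, scale-free fit target R^2 = 0.85, minimum module size 30,
    eigengene-dissimilarity merge threshold 0.25 and |GS| > 0.2, |MM| > 0.8
    hub criteria.
    """

    window_size_bp: int = 50_000
    window_step_bp: int = 20_000
    top_fraction: float = 0.01
    maf_min: float = 0.05
    max_missing: float = 0.10          # maximum fraction of missing genotypes
    lrt_alpha: float = 0.05
    lfc_threshold: float = 1.0         # log2 units
    fdr_threshold: float = 0.05
    sd_min: float = 0.5
    soft_power_target_r2: float = 0.85
    min_module_size: int = 30
    me_diss_threshold: float = 0.25
    gs_cut: float = 0.2
    mm_cut: float = 0.8
    rng_seed: int = 0

    _PROPORTIONS = (
        "top_fraction", "maf_min", "max_missing", "lrt_alpha", "fdr_threshold",
        "soft_power_target_r2", "me_diss_threshold", "gs_cut", "mm_cut",
    )

    def __post_init__(self) -> None:
        for name in self._PROPORTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.window_step_bp > self.window_size_bp:
            raise ConfigError(
                f"window_step_bp={self.window_step_bp} exceeds "
                f"window_size_bp={self.window_size_bp}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def log_resolved(self) -> None:
        log.info("resolved config: %s", self.as_dict())


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tree:
    """Rooted tree with indexed nodes in postorder.

    ``parent[i]`` is the parent index of node ``i`` (-1 for the root, which is
    the last index); ``children[i]`` lists child indices; ``blen[i]`` is the
    length of the branch above node ``i`` (0 for the root); ``names[i]`` is
    the leaf label or ``None`` for internal nodes. A branch is identified by
    its child node index throughout the package.
    """

    parent: np.ndarray
    children: tuple
    blen: np.ndarray
    names: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> range:
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def leaf_index(self, name: str) -> int:
        for i in self.leaves:
            if self.names[i] == name:
                return i
        raise ConfigError(f"leaf {name!r} not in tree")

    def subtree_leaves(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.append(v)
        return out

    def mrca(self, names: Iterable[str]) -> int:
        targets = {self.leaf_index(n) for n in names}
        # smallest postorder node whose subtree covers all targets
        for v in self.postorder():
            if targets <= set(self.subtree_leaves(v)):
                return v
        return self.root

    def branch_for(self, spec: str | Sequence[str]) -> int:
        """Resolve a foreground-branch spec (leaf name or leaf set) to the
        child node of the branch."""
        if isinstance(spec, str):
            return self.leaf_index(spec)
        node = self.mrca(spec)
        if node == self.root:
            raise ConfigError("foreground spec resolves to the root branch")
        return node

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if a is a (strict) ancestor of b."""
        v = self.parent[b]
        while v != -1:
            if v == a:
                return True
            v = self.parent[v]
        return False

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                body = self.names[v]
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v == self.root:
                return body + ";"
            return f"{body}:{self.blen[v]:.10g}"
        return fmt(self.root)


def _tree_from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    children: list[tuple] = [()] * n
    names: list = [None] * n
    for i, nd in enumerate(nodes):
        kids = nd.child_nodes()
        children[i] = tuple(index[id(c)] for c in kids)
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
        if not kids:
            if nd.taxon is None or not nd.taxon.label:
                raise FormatError("leaf without a label")
            names[i] = nd.taxon.label.replace(" ", "_")
        if nd.edge.length is not None:
            if nd.edge.length < 0:
                raise FormatError(
                    f"negative branch length {nd.edge.length} above "
                    f"{names[i] or 'internal node'}"
                )
            blen[i] = float(nd.edge.length)
    return Tree(parent=parent, children=tuple(children), blen=blen,
                names=tuple(names))


def read_tree(path: str | Path) -> Tree:
    """Parse a rooted newick tree; leaves must be uniquely labelled and
    branch lengths non-negative."""
    try:
        dtree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparsable newick in {path}: {exc}") from exc
    tree = _tree_from_dendropy(dtree)
    labels = tree.leaf_names
    if len(labels) < 2:
        raise FormatError(f"tree in {path} has fewer than 2 leaves")
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def parse_tree(newick: str) -> Tree:
    """Like :func:`read_tree` but from a newick string."""
    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise FormatError(f"unparsable newick: {exc}") from exc
    tree = _tree_from_dendropy(dtree)
    if len(tree.leaf_names) < 2:
        raise FormatError("tree has fewer than 2 leaves")
    labels = tree.leaf_names
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_tree(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


@dataclass
class Alignment:
    """An aligned set of sequences keyed by id.

    ``kind`` is ``"codon"`` (nucleotide, length divisible by 3) or
    ``"protein"``. Gaps and ambiguity codes are preserved in the raw
    sequences and flagged invalid in the matrix views.
    """

    ids: list[str]
    seqs: list[str]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("codon", "protein"):
            raise ConfigError(f"unknown alignment kind {self.kind!r}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.kind == "codon" and self.length % 3 != 0:
            raise FormatError(
                f"codon alignment length {self.length} not divisible by 3")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_codons(self) -> int:
        if self.kind != "codon":
            raise ConfigError("n_codons only defined for codon alignments")
        return self.length // 3

    def row(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def protein_matrix(self) -> np.ndarray:
        """Integer matrix of amino-acid states; -1 for any non-canonical
        residue (gap, X, ...)."""
        if self.kind != "protein":
            raise ConfigError("protein_matrix requires a protein alignment")
        lut = np.full(256, -1, dtype=np.int8)
        for i, aa in enumerate(AMINO_ACIDS):
            lut[ord(aa)] = i
        arr = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8)
        return lut[arr].reshape(self.n_seqs, self.length)

    def translate(self) -> "Alignment":
        """Codon alignment -> protein alignment; untranslatable codons
        (gaps, ambiguity) become 'X'."""
        if self.kind != "codon":
            raise ConfigError("translate requires a codon alignment")
        out = []
        for s in self.seqs:
            aas = []
            for k in range(0, len(s), 3):
                cod = s[k:k + 3]
                if set(cod) <= set(NUCLEOTIDES):
                    aas.append(str(Seq(cod).translate()))
                else:
                    aas.append("X")
            out.append("".join(aas).replace("*", "X"))
        return Alignment(ids=list(self.ids), seqs=out, kind="protein")


def read_alignment(path: str | Path, kind: str) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(ids=[r.id for r in records],
                     seqs=[str(r.seq) for r in records], kind=kind)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(aln.ids, aln.seqs)]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Variant panels (VCF)
# ---------------------------------------------------------------------------

@dataclass
class VariantPanel:
    """Biallelic-oriented SNP panel with per-sample alt-allele dosages.

    ``gt`` holds 0/1/2 alt-allele counts per diploid sample and -1 for
    missing genotypes. Multiallelic records are retained with
    ``biallelic=False`` and fully missing dosages. Positions are 0-based
    internally.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    biallelic: np.ndarray
    samples: list[str]
    pops: dict[str, np.ndarray]  # population -> sample index array

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pop_counts(self, pop: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-site (called alleles, alt alleles, het individuals) for one
        population. Missing genotypes reduce the called-allele denominator."""
        sub = self.gt[:, self.pops[pop]]
        called = (sub >= 0).sum(axis=1) * 2
        alt = np.where(sub >= 0, sub, 0).sum(axis=1)
        het = (sub == 1).sum(axis=1)
        return called, alt, het


def read_pop_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV sample -> population (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     dtype=str)
    return dict(zip(df["sample"], df["pop"]))


def read_vcf(path: str | Path, pop_table: Mapping[str, str] | str | Path
             ) -> VariantPanel:
    """Load a VCF v4.2 with GT fields into a :class:`VariantPanel`."""
    from cyvcf2 import VCF

    if not isinstance(pop_table, Mapping):
        pop_table = read_pop_table(pop_table)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing = set(pop_table) - set(samples)
    if missing:
        raise ConfigError(
            f"samples in population table absent from VCF: {sorted(missing)}")
    chrom, pos, ref, alt, gts, bial = [], [], [], [], [], []
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS - 1)  # to 0-based
        ref.append(v.REF)
        is_bi = len(v.ALT) == 1
        bial.append(is_bi)
        alt.append(v.ALT[0] if v.ALT else ".")
        if is_bi:
            g = v.gt_types.astype(np.int8)  # 0 hom-ref,1 het,2 hom-alt,3 miss
            g[g == 3] = -1
        else:
            g = np.full(len(samples), -1, dtype=np.int8)
        gts.append(g)
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        if s in pop_table:
            pops.setdefault(pop_table[s], []).append(i)
    return VariantPanel(
        chrom=np.array(chrom, dtype=object), pos=np.array(pos, dtype=int),
        ref=np.array(ref, dtype=object), alt=np.array(alt, dtype=object),
        gt=np.array(gts, dtype=np.int8) if gts else
        np.zeros((0, len(samples)), dtype=np.int8),
        biallelic=np.array(bial, dtype=bool), samples=samples,
        pops={p: np.array(ix, dtype=int) for p, ix in pops.items()})


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: VariantPanel, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples))
    for i in range(panel.n_sites):
        gt = "\t".join(_GT_STR[int(g)] for g in panel.gt[i])
        lines.append(f"{panel.chrom[i]}\t{panel.pos[i] + 1}\t.\t{panel.ref[i]}"
                     f"\t{panel.alt[i]}\t.\tPASS\t.\tGT\t{gt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pop_table(pop_of: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{p}\n" for s, p in pop_of.items()))


# ---------------------------------------------------------------------------
# Gene annotations (BED / GFF3)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene intervals as a DataFrame (chrom, start, end, gene); 0-based
    half-open internally. BED vs GFF3 is auto-detected from the extension."""
    path = Path(path)
    ext = path.suffix.lower()
    rows = []
    if ext == ".bed":
        for ln in path.read_text().splitlines():
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            gene = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, gene))
    elif ext in (".gff", ".gff3"):
        for ln in path.read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gene = attrs.get("Name") or attrs.get("ID") or f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, gene))
    else:
        raise FormatError(f"cannot auto-detect annotation format of {path}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    bad = df[df["end"] <= df["start"]]
    if len(bad):
        raise FormatError(
            f"interval end <= start after normalization: {bad.iloc[0].tolist()}")
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Expression matrices & trait tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSet:
    """Gene x sample matrix plus optional per-sample metadata."""

    values: pd.DataFrame             # genes in rows, samples in columns
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.issubdtype(np.asarray(self.values.values).dtype, np.number):
            raise FormatError("non-numeric cell in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)


def read_matrix(path: str | Path) -> ExpressionSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric matrix cell in {path}: {exc}") from exc
    return ExpressionSet(values=df)


def write_matrix(es: ExpressionSet, path: str | Path) -> None:
    es.values.to_csv(path, sep="\t")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Pathway tables
# ---------------------------------------------------------------------------

def read_pathways(path: str | Path) -> dict[str, list[str]]:
    """Long-format TSV with header columns ``pathway`` and ``gene`` ->
    ordered, deduplicated membership map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway", "gene"} <= set(df.columns):
        raise FormatError(f"pathway table {path} needs 'pathway' and 'gene' columns")
    out: dict[str, list[str]] = {}
    for pw, g in zip(df["pathway"], df["gene"]):
        bucket = out.setdefault(pw, [])
        if g not in bucket:
            bucket.append(g)
    return out


def write_pathways(pathways: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tgene\n")
        for pw, genes in pathways.items():
            for g in genes:
                fh.write(f"{pw}\t{g}\n")
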