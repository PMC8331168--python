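"""Phosphosite conservation analysis.

Consumes a precomputed protein multiple sequence alignment and provides:
Jukes-Cantor distances generalized to the 20-state amino-acid alphabet, UPGMA
ultrametric trees with deterministic tie-breaking, nonparametric bootstrap
support by column resampling, mapping of a reference residue (e.g. Arabidopsis
ACO3 Ser91) through the alignment with per-species Ser calls, per-column
BLOSUM62 window-similarity categories, and a degenerate-motif scanner (e.g. the
basophilic R-x-x-S kinase motif).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .errors import MotifError, SaturationError
from .rng import named_rng

GAP = "-"
_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_B62[a, b])


@dataclass
class MultipleAlignment:
    """Ordered aligned records over the 20 amino acids plus '-' gaps."""

    ids: list[str]
    rows: np.ndarray  # (n_taxa, n_columns) array of single characters

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype="U1")
        if len(self.ids) != self.rows.shape[0]:
            raise ValueError("ids and rows disagree in length")
        if len(self.ids) < 2:
            raise ValueError("alignment needs at least two rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate record ids")

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "MultipleAlignment":
        lengths = {len(s) for _, s in pairs}
        if len(lengths) != 1:
            raise ValueError("aligned rows must have equal length")
        ids = [i for i, _ in pairs]
        rows = np.array([list(s.upper()) for _, s in pairs], dtype="U1")
        return cls(ids=ids, rows=rows)

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls.from_pairs(pairs)

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    def index_of(self, ref_id: str) -> int:
        try:
            return self.ids.index(ref_id)
        except ValueError:
            raise KeyError(f"record {ref_id!r} not in alignment") from None


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")


def p_distance(msa: MultipleAlignment, i: int, j: int) -> float:
    """Observed proportion of differing sites, with pairwise gap deletion."""
    if i == j:
        raise ValueError("p-distance requires two distinct rows")
    a, b = msa.rows[i], msa.rows[j]
    comparable = (a != GAP) & (b != GAP)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError(f"rows {i} and {j} share no comparable sites")
    return float((a[comparable] != b[comparable]).sum() / n)


def jc_distance(p: float, k: int = 20) -> float:
    """Jukes-Cantor correction generalized to a k-state alphabet.

    d = -((k-1)/k) * ln(1 - (k/(k-1)) * p); for proteins k = 20.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    b = (k - 1) / k
    if p >= b:
        raise SaturationError(f"p = {p} is at or beyond saturation (>= {b})")
    return -b * math.log(1.0 - p / b)


def distance_matrix(msa: MultipleAlignment, k: int = 20) -> DistanceMatrix:
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(p_distance(msa, i, j), k=k)
    return DistanceMatrix(labels=list(msa.ids), values=d)


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; leaves sit at height 0."""

    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaf_labels() for c in self.children))

    def clades(self) -> dict[frozenset[str], "TreeNode"]:
        """Internal nodes keyed by their leaf set (the tree's rooted bipartitions)."""
        out = {}
        for child in self.children:
            if not child.is_leaf:
                out.update(child.clades())
        if not self.is_leaf:
            out[self.leaf_labels()] = self
        return out

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{length:.6f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            sup = ""
            if with_support and node.support is not None:
                sup = f"{node.support:g}"
            return f"({inner}){sup}:{length:.6f}"

        inner = ",".join(fmt(c, self.height) for c in self.children)
        sup = f"{self.support:g}" if (with_support and self.support is not None) else ""
        return f"({inner}){sup};"

    def cophenetic(self) -> dict[tuple[str, str], float]:
        """Tree-induced distances between leaves (2x the join height)."""
        out = {}
        for i, ci in enumerate(self.children):
            for cj in self.children[i + 1:]:
                for a in ci.leaf_labels():
                    for b in cj.leaf_labels():
                        out[tuple(sorted((a, b)))] = 2.0 * self.height
        for c in self.children:
            if not c.is_leaf:
                out.update(c.cophenetic())
        return out


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA with size-weighted cluster averaging.

    The closest pair merges at height d/2; merged-cluster distances are the
    size-weighted mean of member distances (UPGMA proper).  Equal-distance ties
    break on the smallest lexicographic pair of cluster representative labels,
    a representative being the cluster's lexicographically smallest leaf.
    """
    d = np.asarray(dm.values, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if len(dm.labels) < 2:
        raise ValueError("need at least two taxa")
    nodes = {i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(dm.labels)}
    reps = {i: lab for i, lab in enumerate(dm.labels)}
    sizes = {i: 1 for i in nodes}
    dist = {
        (i, j): d[i, j]
        for i in range(len(dm.labels))
        for j in range(i + 1, len(dm.labels))
    }
    next_id = len(dm.labels)
    while len(nodes) > 1:
        best = min(
            dist,
            key=lambda ij: (dist[ij], tuple(sorted((reps[ij[0]], reps[ij[1]])))),
        )
        i, j = best
        h = dist[best] / 2.0
        merged = TreeNode(height=h, children=[nodes[i], nodes[j]])
        m = next_id
        next_id += 1
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dist[(k, m)] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        del nodes[i], nodes[j]
        sizes[m] = sizes.pop(i) + sizes.pop(j)
        reps[m] = min(reps.pop(i), reps.pop(j))
        nodes[m] = merged
    return next(iter(nodes.values()))


def bootstrap_support(
    msa: MultipleAlignment, n_reps: int = 1000, seed: int = 0, k: int = 20
) -> TreeNode:
    """UPGMA tree of the full alignment annotated with bootstrap support.

    Columns are resampled with replacement ``n_reps`` times; support on each
    internal node is the percentage of replicate trees containing the same
    leaf set.  Deterministic given the seed; taxon input order does not affect
    the resampled columns.
    """
    if msa.n_columns < 1:
        raise ValueError("alignment has no columns")
    tree = upgma(distance_matrix(msa, k=k))
    clades = tree.clades()
    counts = {key: 0 for key in clades}
    rng = named_rng(seed, "bootstrap")
    for _ in range(n_reps):
        cols = rng.integers(0, msa.n_columns, size=msa.n_columns)
        rep = MultipleAlignment(ids=list(msa.ids), rows=msa.rows[:, cols])
        rep_clades = upgma(distance_matrix(rep, k=k)).clades().keys()
        for key in counts:
            if key in rep_clades:
                counts[key] += 1
    for key, node in clades.items():
        node.support = 100.0 * counts[key] / n_reps
    return tree


@dataclass
class SiteReport:
    column: int  # 1-based alignment column of the reference residue
    residues: dict[str, str]
    ser_present: dict[str, bool]


def map_reference_position(
    msa: MultipleAlignment, ref_id: str, ref_position: int
) -> SiteReport:
    """Map a 1-based residue index of the reference row to an alignment column.

    Residues are read down that column; a species is flagged Ser-present when
    it shows 'S' there (gaps read as '-', flag False).
    """
    row = msa.rows[msa.index_of(ref_id)]
    non_gap = np.flatnonzero(row != GAP)
    if ref_position < 1 or ref_position > non_gap.size:
        raise ValueError(
            f"reference position {ref_position} beyond {ref_id} ({non_gap.size} residues)"
        )
    col = int(non_gap[ref_position - 1])
    residues = {sp: str(msa.rows[i, col]) for i, sp in enumerate(msa.ids)}
    return SiteReport(
        column=col + 1,
        residues=residues,
        ser_present={sp: res == "S" for sp, res in residues.items()},
    )


#: Similarity categories as half-open bands; exactly 100% is black.
CATEGORY_BANDS = [(100.0, "black"), (80.0, "dark-grey"), (60.0, "light-grey")]


def _category(percent: float | None) -> str:
    if percent is None:
        return "uncolored"
    if percent >= 100.0:
        return "black"
    if percent >= 80.0:
        return "dark-grey"
    if percent >= 60.0:
        return "light-grey"
    return "uncolored"


@dataclass
class ColumnSimilarity:
    column: int  # 1-based
    consensus: str | None
    percent: float | None
    category: str


def window_similarity(
    msa: MultipleAlignment,
    columns: range | list[int],
    threshold: float = 1.0,
) -> list[ColumnSimilarity]:
    """BLOSUM62 similarity share per column against the modal-residue consensus.

    The consensus is the most frequent non-gap residue (ties: higher BLOSUM62
    self-score, then alphabetical).  The similarity percent is the share of
    non-gap residues scoring >= threshold against the consensus; categories use
    the 100 / [80,100) / [60,80) / <60 bands.  All-gap columns are uncolored
    with an undefined percent.
    """
    out = []
    for col in columns:
        if not 1 <= col <= msa.n_columns:
            raise ValueError(f"column {col} outside alignment (1..{msa.n_columns})")
        residues = [r for r in msa.rows[:, col - 1] if r != GAP]
        if not residues:
            out.append(ColumnSimilarity(col, None, None, "uncolored"))
            continue
        uniq, counts = np.unique(residues, return_counts=True)
        consensus = min(
            zip(uniq, counts),
            key=lambda rc: (-rc[1], -blosum62(rc[0], rc[0]), rc[0]),
        )[0]
        similar = sum(1 for r in residues if blosum62(r, consensus) >= threshold)
        percent = 100.0 * similar / len(residues)
        out.append(ColumnSimilarity(col, str(consensus), percent, _category(percent)))
    return out


_MOTIF_TOKEN = re.compile(
    r"([ACDEFGHIKLMNPQRSTVWY])|(x)|\[([ACDEFGHIKLMNPQRSTVWY]+)\]", re.IGNORECASE
)


def motif_scan(sequence: str, pattern: str) -> list[int]:
    """1-based start positions of (possibly overlapping) degenerate-motif matches.

    Patterns use residue letters, 'x' wildcards and bracketed alternatives,
    optionally dash-separated: "R-x-x-S", "RxxS" and "R-x-x-[ST]" are all
    valid.  Matching is case-insensitive.
    """
    compact = pattern.replace("-", "")
    pos = 0
    parts = []
    while pos < len(compact):
        m = _MOTIF_TOKEN.match(compact, pos)
        if m is None:
            raise MotifError(f"malformed motif pattern {pattern!r} near {compact[pos:]!r}")
        if m.group(1):
            parts.append(m.group(1).upper())
        elif m.group(2):
            parts.append(".")
        else:
            parts.append(f"[{m.group(3).upper()}]")
        pos = m.end()
    if not parts:
        raise MotifError("empty motif pattern")
    rx = re.compile("(?=" + "".join(parts) + ")", re.IGNORECASE)
    return [m.start() + 1 for m in rx.finditer(sequence)]
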