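"""Distance phylogeny of NBS domains: progressive alignment, p-distances,
neighbor joining, bootstrap support, monophyly tests.

The survey's phylogenetic claims are clade-membership statements (each class
forms a monophyletic group with strong bootstrap support), so a
neighbor-joining tree on amino-acid p-distances is used here: deterministic,
dependency-light, and exact on additive distances.  Likelihood inference is
deliberately out of scope.

Alignment is classical progressive alignment: a UPGMA guide tree on 3-mer
distances, then profile-profile dynamic programming with BLOSUM62 and affine
gaps (open 10, extend 1).  A codon back-translation utility maps a protein
alignment onto the coding sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import InputError, ValidationError
from .profiles import AMINO_ACIDS

__all__ = [
    "Msa",
    "progressive_align",
    "codon_backtranslate",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "is_monophyletic",
    "clade_support",
    "filter_alignment",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_GAP_OPEN = 10.0
_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment; records are (id, aligned sequence)."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValidationError("an alignment needs at least two records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1 or 0 in lengths:
            raise ValidationError("alignment rows must share one positive length")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def to_fasta(self, path) -> None:
        with open(path, "w") as out:
            for rid, seq in self.records:
                out.write(f">{rid}\n{seq}\n")


def _blosum_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = blosum[a][b]
    return m


_BLOSUM = _blosum_matrix()


def _profile(rows: list[str]) -> np.ndarray:
    """Column residue frequencies (gaps contribute nothing), (L, 20)."""
    length = len(rows[0])
    prof = np.zeros((length, len(AMINO_ACIDS)))
    for row in rows:
        for j, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                prof[j, idx] += 1.0
    return prof / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str]
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (Gotoh affine gaps)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    score = (pa @ _BLOSUM) @ pb.T  # (la, lb) column-pair scores
    neg = -np.inf
    m = np.full((la + 1, lb + 1), neg)  # match state
    x = np.full((la + 1, lb + 1), neg)  # gap in B (consume A)
    y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B)
    m[0, 0] = 0.0
    for i in range(1, la + 1):
        x[i, 0] = -_GAP_OPEN - _GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        y[0, j] = -_GAP_OPEN - _GAP_EXTEND * (j - 1)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        mi_prev, xi_prev, yi_prev = m[i - 1], x[i - 1], y[i - 1]
        # X state: gap in B, moving down a row (vectorized over j)
        cand = np.stack(
            [mi_prev - _GAP_OPEN, xi_prev - _GAP_EXTEND, yi_prev - _GAP_OPEN]
        )
        ptr_x[i] = cand.argmax(axis=0)
        x[i] = np.maximum(x[i], cand.max(axis=0))
        ptr_x[i, 0] = 1
        row_m = m[i]
        row_y = y[i]
        s = score[i - 1]
        for j in range(1, lb + 1):
            best = max(mi_prev[j - 1], xi_prev[j - 1], yi_prev[j - 1])
            if best == mi_prev[j - 1]:
                ptr_m[i, j] = 0
            elif best == xi_prev[j - 1]:
                ptr_m[i, j] = 1
            else:
                ptr_m[i, j] = 2
            row_m[j] = best + s[j - 1]
            cand_y = (
                row_m[j - 1] - _GAP_OPEN,
                x[i, j - 1] - _GAP_OPEN,
                row_y[j - 1] - _GAP_EXTEND,
            )
            k = int(np.argmax(cand_y))
            ptr_y[i, j] = k
            row_y[j] = cand_y[k]
    # traceback from the best terminal state
    states = (m[la, lb], x[la, lb], y[la, lb])
    state = int(np.argmax(states))
    i, j = la, lb
    out_a: list[str] = []
    out_b: list[str] = []
    gaps_a = "-" * len(rows_a)
    gaps_b = "-" * len(rows_b)
    cols_a = ["".join(r[k] for r in rows_a) for k in range(la)]
    cols_b = ["".join(r[k] for r in rows_b) for k in range(lb)]
    while i > 0 or j > 0:
        if state == 0:
            nxt = ptr_m[i, j]
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i, j = i - 1, j - 1
            state = int(nxt)
        elif state == 1:
            nxt = ptr_x[i, j]
            out_a.append(cols_a[i - 1])
            out_b.append(gaps_b)
            i -= 1
            state = int(nxt)
        else:
            nxt = ptr_y[i, j]
            out_a.append(gaps_a)
            out_b.append(cols_b[j - 1])
            j -= 1
            state = int(nxt)
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[k] for col in out_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in out_b) for k in range(len(rows_b))]
    return new_a, new_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


def progressive_align(seqs: list[tuple[str, str]] | dict[str, str]) -> Msa:
    """Progressive MSA: UPGMA guide tree on 3-mer distance, profile merges.

    Deterministic for a fixed input order.  Accepts (id, sequence) pairs or
    a mapping.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 2:
        raise InputError("need at least two sequences")
    for rid, seq in items:
        if not seq:
            raise InputError(f"{rid}: empty sequence")
    if len(items) == 2:
        (ia, sa), (ib, sb) = items
        rows_a, rows_b = _align_profiles([sa], [sb])
        return Msa(((ia, rows_a[0]), (ib, rows_b[0])))
    n = len(items)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(items[i][1], items[j][1])
    tree = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([items[i][0]], [items[i][1]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(tree):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _align_profiles(rows_a, rows_b)
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)
    ids, rows = clusters.popitem()[1]
    order = {rid: k for k, (rid, _) in enumerate(items)}
    merged = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return Msa(tuple(merged))


def codon_backtranslate(msa: Msa, cds: dict[str, str]) -> Msa:
    """Expand a protein alignment to codons; gaps become ``---``.

    Each CDS must be three times the ungapped protein length, optionally plus
    a terminal stop codon.
    """
    rows = []
    for rid, aligned in msa.records:
        try:
            nt = cds[rid].upper()
        except KeyError:
            raise ValidationError(f"no CDS for record {rid!r}") from None
        n_res = sum(1 for ch in aligned if ch != "-")
        if len(nt) not in (3 * n_res, 3 * n_res + 3):
            raise ValidationError(
                f"{rid}: CDS length {len(nt)} does not match {n_res} residues"
            )
        out = []
        pos = 0
        for ch in aligned:
            if ch == "-":
                out.append("---")
            else:
                out.append(nt[pos : pos + 3])
                pos += 3
        rows.append((rid, "".join(out)))
    return Msa(tuple(rows))


def _gap_mask(msa: Msa) -> np.ndarray:
    return np.array(
        [[ch == "-" for ch in seq] for _, seq in msa.records], dtype=bool
    )


def _char_matrix(msa: Msa) -> np.ndarray:
    return np.array([list(seq) for _, seq in msa.records])


def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Pairwise p-distances with pairwise gap deletion."""
    chars = _char_matrix(msa)
    gaps = chars == "-"
    n = chars.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            total = int(ok.sum())
            if total == 0:
                raise ValidationError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            diff = int((chars[i, ok] != chars[j, ok]).sum())
            dist[i, j] = dist[j, i] = diff / total
    return DistanceMatrix(dist, ids=list(msa.ids))


def nj_tree(d: DistanceMatrix | np.ndarray, ids: list[str] | None = None) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if not isinstance(d, DistanceMatrix):
        arr = np.asarray(d, dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValidationError("distance matrix must be symmetric")
        d = DistanceMatrix(arr, ids=ids or [str(i) for i in range(arr.shape[0])])
    if d.shape[0] < 3:
        raise InputError("neighbor joining needs at least three taxa")
    return nj(d, neg_as_zero=True)


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each normalized to its smaller side."""
    leaves = frozenset(leaf.name for leaf in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        parts.add(_normalize_side(side, leaves))
    return parts


def _normalize_side(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    other = leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: sorted(s))


def bootstrap_support(
    msa: Msa, replicates: int = 100, seed: int = 0
) -> TreeNode:
    """NJ tree with internal-node bootstrap supports (percent).

    Columns are resampled with replacement per replicate; support for each
    internal edge of the point-estimate tree is the percentage of replicate
    trees containing the same bipartition.
    """
    if replicates < 1:
        raise InputError("need at least one replicate")
    tree = nj_tree(p_distance_matrix(msa))
    leaves = frozenset(msa.ids)
    rng = np.random.default_rng(seed)
    chars = _char_matrix(msa)
    counts: dict[frozenset[str], int] = {}
    n_cols = chars.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = Msa(
            tuple(
                (rid, "".join(chars[i, cols]))
                for i, rid in enumerate(msa.ids)
            )
        )
        rep_tree = nj_tree(p_distance_matrix(resampled))
        for part in _bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        part = _normalize_side(side, leaves)
        node.support = 100.0 * counts.get(part, 0) / replicates
        node.name = f"{node.support:.0f}"
    return tree


def clade_support(tree: TreeNode, taxa: set[str]) -> float | None:
    """Bootstrap support of the edge separating ``taxa``, or None if absent.

    Matches by normalized bipartition, so the clade is found regardless of
    which side of the root it ended up on.
    """
    leaves = frozenset(leaf.name for leaf in tree.tips())
    target = _normalize_side(frozenset(taxa), leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if _normalize_side(side, leaves) == target:
            return getattr(node, "support", None)
    return None


def is_monophyletic(tree: TreeNode, taxa: set[str]) -> bool:
    """True iff some edge separates exactly ``taxa`` from the rest.

    The full leaf set and singletons are trivially monophyletic.
    """
    leaves = frozenset(leaf.name for leaf in tree.tips())
    taxa = frozenset(taxa)
    unknown = taxa - leaves
    if unknown:
        raise InputError(f"unknown taxa: {sorted(unknown)[:5]}")
    if len(taxa) in (1, len(leaves)):
        return True
    target = _normalize_side(taxa, leaves)
    return target in _bipartitions(tree)


def filter_alignment(
    msa: Msa, min_coverage: float = 0.5, max_mean_distance: float = 0.8
) -> Msa:
    """Drop rows too short or too divergent for a fine alignment.

    Removes records covering fewer than ``min_coverage`` of the columns or
    with mean p-distance above ``max_mean_distance``.
    """
    dist = p_distance_matrix(msa)
    keep = []
    n = len(msa.records)
    for i, (rid, seq) in enumerate(msa.records):
        coverage = sum(ch != "-" for ch in seq) / len(seq)
        mean_d = float(dist.data[i].sum() / (n - 1))
        if coverage >= min_coverage and mean_d <= max_mean_distance:
            keep.append((rid, seq))
    if len(keep) < 2:
        raise ValidationError("fewer than two records survive filtering")
    return Msa(tuple(keep))
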