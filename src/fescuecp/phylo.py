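"""Tree building: binary encoding, Dice and TN93 distances, UPGMA, bootstrap.

Variant calls are converted to a 0/1 marker matrix (one column per
non-reference state), from which genetic similarity is computed with the
Nei-Li/Dice coefficient 2a/(2a+b+c) -- shared presences only, shared
absences carry no signal. Sequence-level distances use the Tamura-Nei (TN93)
model with empirical base frequencies and pairwise deletion of gap/N
columns. Trees are built with UPGMA (size-weighted average linkage, node
height = half the merge distance, hence ultrametric); merge ties are broken
by the lexicographically smallest merged leaf-label set so results are
platform independent. Bootstrap support resamples columns with replacement
and reports, for each internal node of the original tree, the percentage of
replicate trees containing its bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import GAP, AlignedSequenceSet
from .errors import InputError, SaturationError
from .variants import VariantLocus


@dataclass
class Clade:
    """Node of a rooted ultrametric tree.

    ``height`` is the node's distance above the leaves; a leaf has height 0
    and a name. ``support`` is a bootstrap percentage in [0, 100] attached to
    internal nodes.
    """

    name: str | None = None
    height: float = 0.0
    children: list["Clade"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        return frozenset().union(*(c.leaves() for c in self.children))

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


# ---------------------------------------------------------------------------
# Binary encoding


def encode_binary(
    loci: list[VariantLocus],
    aln: AlignedSequenceSet,
    reference_taxon: str,
) -> pd.DataFrame:
    """Convert classified loci to a 0/1 marker matrix (taxa x markers).

    Each biallelic locus yields one column (1 = non-reference state); a
    multiallelic SNP yields one column per non-reference allele; an indel
    locus yields one column (1 = state opposite the reference convention).
    Missing states (N, or gap at a SNP column) score 0. Constant columns are
    dropped.
    """
    if reference_taxon not in aln.taxa:
        raise InputError(f"reference taxon {reference_taxon!r} not in alignment")
    columns: dict[str, list[int]] = {}
    for locus in loci:
        states = sorted({
            a for a in locus.alleles.values() if a not in ("N", GAP)
        })
        ref_state = locus.alleles[reference_taxon]
        if ref_state in ("N", GAP):
            # fall back to the majority state as reference
            counts = {s: 0 for s in states}
            for a in locus.alleles.values():
                if a in counts:
                    counts[a] += 1
            ref_state = max(sorted(counts), key=lambda s: counts[s])
        for state in states:
            if state == ref_state:
                continue
            label = f"{locus.start}_{locus.var_class}_{state}"
            columns[label] = [
                int(locus.alleles[t] == state) for t in aln.taxa
            ]
    matrix = pd.DataFrame(columns, index=aln.taxa, dtype=int)
    keep = [c for c in matrix.columns if matrix[c].nunique() > 1]
    return matrix[keep]


# ---------------------------------------------------------------------------
# Distances


def dice_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Nei-Li/Dice distance 1 - 2a/(2a+b+c) between rows of a 0/1 matrix.

    Rows with no presences at all (a = b = c = 0) are defined as identical
    (similarity 1).
    """
    if len(matrix) < 2:
        raise InputError("need at least two taxa")
    x = matrix.to_numpy(dtype=int)
    a = x @ x.T
    row = x.sum(axis=1)
    denom = row[:, None] + row[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * a / denom, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_sequences(m: np.ndarray) -> np.ndarray:
    """Character matrix -> int8 codes (A=0, C=1, G=2, T=3, gap/N=4)."""
    codes = np.full(m.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[m == base] = code
    return codes


def _tn93_pair(x: np.ndarray, y: np.ndarray, pair: tuple[str, str]) -> float:
    ok = (x < 4) & (y < 4)
    x, y = x[ok], y[ok]
    n = x.size
    if n == 0:
        raise SaturationError(f"no shared ungapped columns for pair {pair}")
    joint = np.bincount(
        (x.astype(np.int32) * 4 + y), minlength=16
    ).reshape(4, 4)
    freqs = (joint.sum(axis=0) + joint.sum(axis=1)) / (2.0 * n)
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    P1 = (joint[0, 2] + joint[2, 0]) / n
    P2 = (joint[1, 3] + joint[3, 1]) / n
    Q = (n - np.trace(joint)) / n - P1 - P2
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    if min(gA * gG, gT * gC, gR * gY) == 0:
        raise SaturationError(
            f"degenerate base composition for pair {pair}: {freqs}"
        )
    w1 = 1.0 - gR * P1 / (2.0 * gA * gG) - Q / (2.0 * gR)
    w2 = 1.0 - gY * P2 / (2.0 * gT * gC) - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise SaturationError(f"TN93 saturation for pair {pair}")
    k3 = gR * gY - gA * gG * gY / gR - gT * gC * gR / gY
    return float(
        -2.0 * gA * gG / gR * math.log(w1)
        - 2.0 * gT * gC / gY * math.log(w2)
        - 2.0 * k3 * math.log(w3)
    )


def tamura_nei_distance(aln: AlignedSequenceSet) -> pd.DataFrame:
    """Pairwise TN93 distances with pairwise deletion of gap/N columns.

    Base frequencies are estimated empirically from each pair's shared
    columns. A non-positive logarithm argument (saturation) raises an error
    naming the pair.
    """
    if len(aln.taxa) < 2:
        raise InputError("need at least two sequences")
    return _tn93_from_codes(_encode_sequences(aln.matrix()), list(aln.taxa))


def _tn93_from_codes(codes: np.ndarray, taxa: list[str]) -> pd.DataFrame:
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _tn93_pair(
                codes[i], codes[j], (taxa[i], taxa[j])
            )
    return pd.DataFrame(d, index=taxa, columns=taxa)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(d: pd.DataFrame) -> Clade:
    """Size-weighted average-linkage clustering of a distance matrix.

    Ties between equally close pairs are broken by the lexicographically
    smallest sorted label set of the would-be merged cluster, making the
    topology deterministic across platforms.
    """
    labels = list(d.index)
    if list(d.columns) != labels:
        raise InputError("distance matrix rows and columns must match")
    dist = {
        (i, j): float(d.iat[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    clusters: dict[int, tuple[Clade, int, tuple[str, ...]]] = {
        i: (Clade(name=lab), 1, (lab,)) for i, lab in enumerate(labels)
    }
    next_id = len(labels)
    tol = 1e-12

    def pair_dist(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(clusters) > 1:
        ids = sorted(clusters)
        best = min(
            pair_dist(i, j) for k, i in enumerate(ids) for j in ids[k + 1 :]
        )
        candidates = [
            (i, j)
            for k, i in enumerate(ids)
            for j in ids[k + 1 :]
            if pair_dist(i, j) <= best * (1 + tol) + tol
        ]
        i, j = min(
            candidates,
            key=lambda p: tuple(
                sorted(clusters[p[0]][2] + clusters[p[1]][2])
            ),
        )
        merge_dist = pair_dist(i, j)
        ci, ni, li = clusters.pop(i)
        cj, nj, lj = clusters.pop(j)
        merged = Clade(
            height=merge_dist / 2.0,
            children=sorted([ci, cj], key=lambda c: tuple(sorted(c.leaves()))),
        )
        for k in clusters:
            dk = (ni * pair_dist(i, k) + nj * pair_dist(j, k)) / (ni + nj)
            dist[(min(k, next_id), max(k, next_id))] = dk
        clusters[next_id] = (merged, ni + nj, tuple(sorted(li + lj)))
        next_id += 1
    (root, _, _) = next(iter(clusters.values()))
    return root


def branch_length(parent: Clade, child: Clade) -> float:
    return parent.height - child.height


# ---------------------------------------------------------------------------
# Newick


def to_newick(tree: Clade, with_support: bool = True) -> str:
    """Newick string with branch lengths and integer support labels."""

    def render(node: Clade, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(render(c, node.height) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = str(int(round(node.support)))
            body = f"({inner}){label}"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:.6g}"

    return render(tree, None) + ";"


# ---------------------------------------------------------------------------
# Bootstrap


def _build_tree(data, builder: str) -> Clade:
    if builder == "dice":
        return upgma(dice_distance(data))
    if builder == "tn93":
        if isinstance(data, tuple):  # (codes, taxa) bootstrap fast path
            return upgma(_tn93_from_codes(*data))
        return upgma(tamura_nei_distance(data))
    raise InputError(f"unknown distance builder {builder!r}")


def _resample(data, idx: np.ndarray):
    if isinstance(data, pd.DataFrame):
        out = data.iloc[:, idx]
        out.columns = [f"c{k}" for k in range(len(idx))]
        return out
    codes, taxa = data
    return (codes[:, idx], taxa)


def bootstrap_support(
    data,
    builder: str = "dice",
    n_replicates: int = 1000,
    seed: int = 0,
) -> Clade:
    """UPGMA tree with column-resampling bootstrap supports.

    ``data`` is a 0/1 marker matrix (builder ``"dice"``) or an
    AlignedSequenceSet (builder ``"tn93"``). Supports are mapped onto the
    original tree's internal nodes: the percentage of replicate trees that
    contain the node's bipartition (the leaf set or its complement).
    Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    if isinstance(data, AlignedSequenceSet):
        data = (_encode_sequences(data.matrix()), list(data.taxa))
    tree = _build_tree(data, builder)
    all_taxa = tree.leaves()
    internal = [n for n in tree.walk() if not n.is_leaf]
    counts = {id(n): 0 for n in internal}
    n_cols = data.shape[1] if isinstance(data, pd.DataFrame) else data[0].shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_tree = _build_tree(_resample(data, idx), builder)
        rep_clades = {n.leaves() for n in rep_tree.walk() if not n.is_leaf}
        rep_bips = rep_clades | {all_taxa - c for c in rep_clades}
        for node in internal:
            if node.leaves() in rep_bips:
                counts[id(node)] += 1
    for node in internal:
        node.support = 100.0 * counts[id(node)] / n_replicates
    return tree
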