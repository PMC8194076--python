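"""Distance trees, codon-position partitioning and the resolution-retention
diagnostic.

The diagnostic rests on a molecular-evolution asymmetry: in a functional
protein-coding fragment most substitutions are synonymous and fall on third
codon positions, so restricting the alignment to first codon positions
collapses the resolution of genuine intraspecific haplogroups.  Pseudogene
(NUMT) lineages evolve free of purifying selection, spread their
substitutions uniformly over codon positions, and therefore keep long,
strongly supported stem branches on first positions alone.  A candidate
group "retains resolution" when its first-position bootstrap support stays
above a threshold and its first-position stem branch keeps at least a set
fraction of its all-positions length.

Trees are neighbor-joining over p/JC/K2P distances with column-resampling
bootstrap; group support is the percentage of replicates containing the
bipartition separating the group from everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "subset_codon_positions",
    "p_distance_matrix",
    "distance_matrix",
    "DiagTree",
    "build_tree",
    "group_support",
    "group_stem_length",
    "RetentionRow",
    "resolution_retention",
]

POSITION_SETS = {
    "all": (0, 1, 2),
    "pos1": (0,),
    "pos2": (1,),
    "pos3": (2,),
    "pos12": (0, 1),
}


def subset_codon_positions(
    seqs: Sequence[str], frame_offset: int, positions: str
) -> list[str]:
    """Keep the requested codon positions of an in-frame window.

    ``pos1`` of an L-bp frame-0 window keeps ceil(L/3) columns.  Columns
    before ``frame_offset`` (a partial leading codon) are discarded.
    """
    if positions not in POSITION_SETS:
        raise ValueError(f"positions must be one of {sorted(POSITION_SETS)}")
    if frame_offset not in (0, 1, 2):
        raise ValueError("invalid frame")
    L = len(seqs[0])
    if L - frame_offset < 3:
        raise ValueError("window shorter than one codon")
    wanted = POSITION_SETS[positions]
    cols = [c for c in range(frame_offset, L) if (c - frame_offset) % 3 in wanted]
    return ["".join(s[c] for c in cols) for s in seqs]


_ACGT = frozenset(b"ACGT")


def _encode(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    return arr, valid


def p_distance_matrix(seqs: Sequence[str], cols: np.ndarray | None = None) -> np.ndarray:
    """Pairwise p-distances over positions where both rows are unambiguous."""
    arr, valid = _encode(seqs)
    if cols is not None:
        arr, valid = arr[:, cols], valid[:, cols]
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & both
        total = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(total > 0, diff.sum(axis=1) / np.maximum(total, 1), 0.0)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


_PURINES = (b"A", b"G")


def _transition_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    px = np.isin(x, _PURINES)
    py = np.isin(y, _PURINES)
    return (x != y) & (px == py)


def distance_matrix(
    seqs: Sequence[str],
    model: str = "p",
    cols: np.ndarray | None = None,
) -> np.ndarray:
    """p, Jukes-Cantor or Kimura-2-parameter distances.

    Saturated pairs (undefined under JC/K2P) fall back to the p-distance
    with a warning.
    """
    p = p_distance_matrix(seqs, cols)
    if model == "p":
        return p
    if model == "JC":
        arg = 1.0 - 4.0 * p / 3.0
        sat = arg <= 0
        if sat.any():
            warnings.warn("JC saturation; falling back to p-distance for saturated pairs")
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(sat, p, -0.75 * np.log(np.where(sat, 1.0, arg)))
        np.fill_diagonal(d, 0.0)
        return d
    if model == "K2P":
        arr, valid = _encode(seqs)
        if cols is not None:
            arr, valid = arr[:, cols], valid[:, cols]
        n = arr.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                total = both.sum()
                if total == 0:
                    continue
                ts = (_transition_mask(arr[i], arr[j]) & both).sum() / total
                tv = ((arr[i] != arr[j]) & both).sum() / total - ts
                a1, a2 = 1 - 2 * ts - tv, 1 - 2 * tv
                if a1 <= 0 or a2 <= 0:
                    warnings.warn("K2P saturation; falling back to p-distance")
                    d[i, j] = d[j, i] = p[i, j]
                else:
                    d[i, j] = d[j, i] = -0.5 * np.log(a1) - 0.25 * np.log(a2)
        return d
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# trees and bipartitions
# ---------------------------------------------------------------------------


def _canonical(side: frozenset, taxa: frozenset, anchor: str) -> frozenset:
    """Represent a bipartition by the side NOT containing the anchor taxon."""
    return frozenset(taxa - side) if anchor in side else side


def _bipartitions(tree: TreeNode, taxa: frozenset, anchor: str) -> dict[frozenset, float]:
    """Canonical internal bipartitions -> summed branch length."""
    out: dict[frozenset, float] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        key = _canonical(side, taxa, anchor)
        out[key] = out.get(key, 0.0) + max(float(node.length or 0.0), 0.0)
    return out


@dataclass
class DiagTree:
    """An NJ tree with per-bipartition bootstrap support."""

    taxa: list[str]
    tree: TreeNode
    lengths: dict[frozenset, float]
    supports: dict[frozenset, float]
    positions_used: str = "all"
    bootstrap: int = 0

    @property
    def anchor(self) -> str:
        return sorted(self.taxa)[0]

    def newick(self, with_support: bool = True) -> str:
        t = self.tree.copy()
        if with_support and self.bootstrap > 0:
            taxa = frozenset(self.taxa)
            for node in t.traverse(include_self=False):
                if node.is_tip():
                    continue
                side = frozenset(x.name for x in node.tips())
                if len(side) < 2 or len(side) > len(taxa) - 2:
                    continue
                key = _canonical(side, taxa, self.anchor)
                node.name = str(int(round(self.supports.get(key, 0.0))))
        return str(t).strip()


def _nj_tree(dm: np.ndarray, ids: list[str]) -> TreeNode:
    d = np.asarray(dm, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return nj(DistanceMatrix(d, ids))


def build_tree(
    ids: Sequence[str],
    seqs: Sequence[str],
    model: str = "p",
    bootstrap: int = 0,
    seed: int | None = None,
) -> DiagTree:
    """NJ tree with optional column-resampling bootstrap (deterministic for
    a given seed)."""
    ids = list(ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 taxa")
    if bootstrap < 0:
        raise ValueError("bootstrap must be >= 0")
    taxa = frozenset(ids)
    anchor = sorted(ids)[0]
    L = len(seqs[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = _nj_tree(distance_matrix(seqs, model), ids)
    lengths = _bipartitions(point, taxa, anchor)

    supports: dict[frozenset, float] = {}
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {}
        for _ in range(bootstrap):
            cols = rng.integers(0, L, size=L)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = _nj_tree(distance_matrix(seqs, model, cols=cols), ids)
            for key in _bipartitions(rep, taxa, anchor):
                counts[key] = counts.get(key, 0) + 1
        supports = {k: 100.0 * v / bootstrap for k, v in counts.items()}
    return DiagTree(ids, point, lengths, supports, bootstrap=bootstrap)


def group_key(dt: DiagTree, group: Iterable[str]) -> frozenset:
    side = frozenset(group)
    return _canonical(side, frozenset(dt.taxa), dt.anchor)


def group_support(dt: DiagTree, group: Iterable[str]) -> float:
    """Bootstrap support of the bipartition separating ``group`` from the
    rest (0 when never recovered)."""
    return dt.supports.get(group_key(dt, group), 0.0)


def group_stem_length(dt: DiagTree, group: Iterable[str]) -> float:
    """Stem branch length of the group in the point tree (0 when the group
    is not monophyletic there)."""
    return dt.lengths.get(group_key(dt, group), 0.0)


# ---------------------------------------------------------------------------
# resolution retention
# ---------------------------------------------------------------------------


@dataclass
class RetentionRow:
    group: str
    support_all: float
    support_pos1: float
    stem_all: float
    stem_pos1: float
    retained: bool
    degenerate: bool = False
    members: list[str] = field(default_factory=list)


def resolution_retention(
    ids: Sequence[str],
    seqs: Sequence[str],
    groups: dict[str, set[str]],
    frame_offset: int = 0,
    bootstrap: int = 100,
    seed: int = 0,
    model: str = "p",
    tau_support: float = 70.0,
    tau_stem: float = 0.5,
    min_stem_pos1: float = 0.015,
) -> list[RetentionRow]:
    """Compare group resolution between all positions and first positions.

    ``retained`` = (pos1 support >= tau_support) and (pos1 stem >= tau_stem
    x all-positions stem) and (pos1 stem >= min_stem_pos1).  The absolute
    floor encodes "long branch": a single private substitution that happens
    to sit on a first position must not qualify, while a relaxed-selection
    lineage keeps several first-position steps.  A group spanning all taxa
    (or a single taxon) is degenerate: trivially monophyletic, support 100,
    flagged retained with a warning marker.
    """
    ids = list(ids)
    id_set = set(ids)
    for name, members in groups.items():
        missing = set(members) - id_set
        if missing:
            raise ValueError(f"group {name!r}: taxa not in tree: {sorted(missing)}")
    tree_all = build_tree(ids, list(seqs), model, bootstrap, seed)
    pos1 = subset_codon_positions(list(seqs), frame_offset, "pos1")
    tree_p1 = build_tree(ids, pos1, model, bootstrap, seed + 1)

    rows = []
    for name in sorted(groups):
        members = set(groups[name])
        if len(members) >= len(ids) - 1 or len(members) < 2:
            rows.append(
                RetentionRow(name, 100.0, 100.0, 0.0, 0.0, True, degenerate=True,
                             members=sorted(members))
            )
            continue
        s_all = group_support(tree_all, members)
        s_p1 = group_support(tree_p1, members)
        st_all = group_stem_length(tree_all, members)
        st_p1 = group_stem_length(tree_p1, members)
        retained = (
            (s_p1 >= tau_support)
            and (st_p1 >= tau_stem * st_all)
            and (st_p1 >= min_stem_pos1)
        )
        rows.append(RetentionRow(name, s_all, s_p1, st_all, st_p1, retained,
                                 members=sorted(members)))
    return rows


def write_retention_tsv(rows: list[RetentionRow], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("group\tsupport_all\tsupport_pos1\tstem_all\tstem_pos1\t"
                 "retained\tdegenerate\n")
        for r in rows:
            fh.write(
                f"{r.group}\t{r.support_all:.1f}\t{r.support_pos1:.1f}\t"
                f"{r.stem_all:.6f}\t{r.stem_pos1:.6f}\t"
                f"{int(r.retained)}\t{int(r.degenerate)}\n"
            )
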