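"""Sequence-level analysis: alignment dissimilarity, Ward clustering, MDS,
cluster centroids, amino-acid composition, and position frequency matrices.

The dissimilarity between two aligned sequences is the normalized mismatch
fraction under pairwise deletion: alignment columns where either sequence has
a gap are excluded from that pair's comparison. Ward clustering uses the
squared-dissimilarity (ward.D2-style) generalization, i.e. agglomerative
merges minimizing the Ward objective applied to squared dissimilarities with
heights reported on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .sequences import CANONICAL_AA, MSA

GAP = "-"


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix must be finite")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class Dendrogram:
    """Agglomerative merge history: scipy-style linkage plus leaf ids."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def to_newick(self) -> str:
        n = len(self.leaf_ids)
        heights = {i: 0.0 for i in range(n)}
        labels = {i: self.leaf_ids[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = f"{labels[a]}:{h - heights[a]:.6g}"
            lb = f"{labels[b]}:{h - heights[b]:.6g}"
            labels[n + i] = f"({la},{lb})"
            heights[n + i] = float(h)
        return labels[n + len(self.linkage) - 1] + ";"


def msa_dissimilarity(msa: MSA) -> DissimilarityMatrix:
    """Pairwise-deletion normalized mismatch fraction over MSA rows."""
    if msa.n_rows < 2:
        raise ValueError("need at least 2 aligned sequences")
    arr = msa.to_array()
    nongap = arr != GAP
    n = msa.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = int(both.sum())
            if m == 0:
                d = 1.0
            else:
                d = float(np.sum(arr[i, both] != arr[j, both])) / m
            D[i, j] = D[j, i] = d
    return DissimilarityMatrix(ids=list(msa.ids), values=D)


def ward_dendrogram(D: DissimilarityMatrix) -> Dendrogram:
    """Ward agglomeration (ward.D2-style generalization) on a dissimilarity matrix."""
    if D.n < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(squareform(D.values, checks=False), method="ward")
    return Dendrogram(linkage=Z, leaf_ids=list(D.ids))


def cut_clusters(dend: Dendrogram, k: int) -> dict[str, int]:
    """Assign leaves to k clusters (clusters renumbered 1..k by first appearance)."""
    n = len(dend.leaf_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    raw = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = {}
    for leaf, c in zip(dend.leaf_ids, raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[leaf] = remap[c]
    return out


def cluster_centroid(D: DissimilarityMatrix, assignment: dict[str, int]) -> dict[int, str]:
    """Per cluster, the member minimizing the sum of dissimilarities to co-members.

    Ties break toward the lexicographically smallest id.
    """
    index = {sid: i for i, sid in enumerate(D.ids)}
    centroids: dict[int, str] = {}
    for cluster in sorted(set(assignment.values())):
        members = sorted([sid for sid, c in assignment.items() if c == cluster])
        rows = [index[m] for m in members]
        sums = D.values[np.ix_(rows, rows)].sum(axis=1)
        centroids[cluster] = members[int(np.argmin(sums))]
    return centroids


def classical_mds(D: DissimilarityMatrix, dims: int = 2) -> np.ndarray:
    """Torgerson double-centering; negative eigenvalues truncated to zero."""
    n = D.n
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > n:
        raise ValueError(f"dims={dims} exceeds number of points n={n}")
    D2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

DEFAULT_CLASS_MAP = {
    "charged": set("DEKR"),
    "uncharged_polar": set("STNQHYCW"),
    "hydrophobic": set("AVLIMFPG"),
}


@dataclass
class CompositionProfile:
    id: str
    fractions: dict[str, float]
    length: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.length > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


def aa_composition(seq: str, seq_id: str = "") -> CompositionProfile:
    """Letter counts divided by sequence length; X is ignored with a warning."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if "X" in seq:
        warnings.warn(f"{seq_id or 'sequence'}: ignoring {seq.count('X')} X residues")
        seq = seq.replace("X", "")
        if not seq:
            raise ValueError("sequence contains only X")
    n = len(seq)
    fractions = {aa: seq.count(aa) / n for aa in CANONICAL_AA}
    return CompositionProfile(id=seq_id, fractions=fractions, length=n)


def composition_by_class(
    profile: CompositionProfile,
    class_map: dict[str, set[str]] | None = None,
) -> dict[str, float]:
    """Class fractions as sums over class members."""
    class_map = class_map or DEFAULT_CLASS_MAP
    return {
        cls: sum(profile.fractions.get(aa, 0.0) for aa in members)
        for cls, members in class_map.items()
    }


def hydrophobic_class_map(include_pg: bool = True) -> dict[str, set[str]]:
    """Class map with the hydrophobic class defined as KD > 0 (plus P and G)."""
    from .resources import kd_hydropathy

    kd = kd_hydropathy()
    hydrophobic = {aa for aa, v in kd.items() if v > 0}
    if include_pg:
        hydrophobic |= {"P", "G"}
    charged = set("DEKR")
    polar = set(CANONICAL_AA) - hydrophobic - charged
    return {"charged": charged, "uncharged_polar": polar, "hydrophobic": hydrophobic}


def position_frequency_matrix(msa: MSA) -> tuple[np.ndarray, np.ndarray]:
    """Per-column letter frequencies (20 x L) and information content in bits.

    Frequencies are over non-gap symbols; an all-gap column has a zero
    frequency column and zero information. Information is log2(20) - H.
    """
    if msa.n_rows == 0 or msa.n_cols == 0:
        raise ValueError("empty alignment block")
    arr = msa.to_array()
    L = msa.n_cols
    freqs = np.zeros((20, L))
    info = np.zeros(L)
    aa_index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    for col in range(L):
        column = arr[:, col]
        letters = [c for c in column if c != GAP]
        if not letters:
            continue
        for c in letters:
            if c in aa_index:
                freqs[aa_index[c], col] += 1
        total = freqs[:, col].sum()
        if total == 0:
            continue
        freqs[:, col] /= total
        p = freqs[freqs[:, col] > 0, col]
        H = -np.sum(p * np.log2(p))
        info[col] = np.log2(20) - H
    return freqs, info
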