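"""Structural-similarity enrichment of screen hits.

Compounds are represented by binary fingerprints.  Pairwise Tanimoto
coefficients between every hit and every library compound form a similarity
matrix that is hierarchically clustered (Euclidean distance on score vectors,
complete linkage).  Clusters whose members are mutually similar (majority of
within-cluster pairwise Tanimoto scores above a threshold, 0.55 by default)
are "structural clusters"; hit enrichment of each cluster or annotation class
against the library background is assessed with Fisher's exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ChemicalRecord",
    "SimilarityMatrix",
    "Dendrogram",
    "StructuralCluster",
    "EnrichmentResult",
    "tanimoto",
    "pairwise_tanimoto",
    "similarity_matrix",
    "cluster_dendrogram",
    "extract_structural_clusters",
    "fisher_enrichment",
    "enrichment_report",
]


@dataclass(frozen=True)
class ChemicalRecord:
    """One library compound: fingerprint plus screen annotations."""

    compound_id: str
    fingerprint: np.ndarray  # 1-D 0/1 array
    library_id: str = "lib"
    class_labels: frozenset[str] = field(default_factory=frozenset)
    is_hit: bool = False
    smiles: str | None = None

    def __post_init__(self):
        fp = np.asarray(self.fingerprint, dtype=np.uint8)
        if fp.ndim != 1:
            raise ValueError("fingerprint must be a 1-D bit vector")
        if not np.isin(fp, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0/1")
        object.__setattr__(self, "fingerprint", fp)


@dataclass
class SimilarityMatrix:
    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # shape (len(row_ids), len(col_ids)), Tanimoto in [0,1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    ids: list[str]
    leaf_order: list[str]


@dataclass
class StructuralCluster:
    cluster_id: int
    member_ids: list[str]
    cohesion: float  # fraction of member pairs with Tanimoto > threshold; 1 for singletons
    is_structural: bool  # cohesion > 0.5


@dataclass(frozen=True)
class EnrichmentResult:
    group_id: str
    k: int  # hits in group
    K: int  # group size
    n: int  # total hits in library
    N: int  # library size
    odds_ratio: float
    p_two_sided: float


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) coefficient |a AND b| / |a OR b| of two bit vectors.

    Two all-zero vectors score 0 by convention.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _fp_matrix(records: list[ChemicalRecord]) -> np.ndarray:
    lengths = {r.fingerprint.size for r in records}
    if len(lengths) > 1:
        raise ValueError(f"fingerprint lengths are not uniform: {sorted(lengths)}")
    return np.stack([r.fingerprint for r in records]).astype(np.float64)


def _tanimoto_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tanimoto of every row of A against every row of B (0/1 matrices)."""
    inter = A @ B.T
    pops_a = A.sum(axis=1)[:, None]
    pops_b = B.sum(axis=1)[None, :]
    union = pops_a + pops_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return out


def pairwise_tanimoto(records: list[ChemicalRecord]) -> SimilarityMatrix:
    """Square Tanimoto matrix among a set of compounds."""
    ids = [r.compound_id for r in records]
    M = _fp_matrix(records)
    return SimilarityMatrix(row_ids=ids, col_ids=ids, values=_tanimoto_block(M, M))


def similarity_matrix(
    hits: list[ChemicalRecord], library: list[ChemicalRecord]
) -> SimilarityMatrix:
    """Tanimoto scores of each hit (rows) against the full library (columns).

    Hits are typically a subset of the library and therefore appear among the
    columns as well, as in the heat-map presentation of the screen.
    """
    if not hits:
        raise ValueError("hit set is empty")
    if not library:
        raise ValueError("library is empty")
    H = _fp_matrix(hits)
    L = _fp_matrix(library)
    if H.shape[1] != L.shape[1]:
        raise ValueError("hit and library fingerprint lengths differ")
    return SimilarityMatrix(
        row_ids=[r.compound_id for r in hits],
        col_ids=[r.compound_id for r in library],
        values=_tanimoto_block(H, L),
    )


def cluster_dendrogram(matrix: SimilarityMatrix, axis: str = "rows") -> Dendrogram:
    """Agglomerative clustering of similarity-score vectors.

    Items along the chosen axis are clustered by the Euclidean distance
    between their Tanimoto score vectors with complete (maximum) linkage,
    which guarantees monotone merge heights.  A single item yields a trivial
    dendrogram.
    """
    if axis == "rows":
        data, ids = matrix.values, list(matrix.row_ids)
    elif axis == "cols":
        data, ids = matrix.values.T, list(matrix.col_ids)
    else:
        raise ValueError("axis must be 'rows' or 'cols'")
    if len(ids) < 2:
        return Dendrogram(linkage=np.empty((0, 4)), ids=ids, leaf_order=list(ids))
    Z = hierarchy.linkage(data, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return Dendrogram(linkage=Z, ids=ids, leaf_order=[ids[i] for i in order])


def _cohesion(members_idx: list[int], tan: np.ndarray, threshold: float) -> float:
    """Fraction of within-cluster pairs with Tanimoto strictly above threshold.

    Singletons are maximally cohesive by convention (cohesion 1)."""
    m = len(members_idx)
    if m < 2:
        return 1.0
    sub = tan[np.ix_(members_idx, members_idx)]
    iu = np.triu_indices(m, 1)
    return float((sub[iu] > threshold).mean())


def extract_structural_clusters(
    dend: Dendrogram,
    member_tanimoto: SimilarityMatrix,
    tanimoto_threshold: float = 0.55,
    cut: str | float | int = "auto",
) -> list[StructuralCluster]:
    """Cut the dendrogram into clusters and score their structural cohesion.

    ``member_tanimoto`` is the square Tanimoto matrix among the clustered
    items (see :func:`pairwise_tanimoto`).  Cohesion of a cluster is the
    fraction of its member pairs with Tanimoto strictly above
    ``tanimoto_threshold``; a cluster is *structural* when more than half of
    its pairs clear the threshold.  The ``cut`` criterion is one of

    - ``"auto"`` (default): the smallest number of clusters such that every
      non-singleton cluster is structural;
    - a float: cut height on the dendrogram;
    - an int: fixed number of clusters.
    """
    if not 0 <= tanimoto_threshold <= 1:
        raise ValueError("tanimoto_threshold must be in [0, 1]")
    ids = dend.ids
    id_to_col = {cid: j for j, cid in enumerate(member_tanimoto.col_ids)}
    missing = [i for i in ids if i not in id_to_col]
    if missing:
        raise ValueError(f"member Tanimoto matrix lacks entries for {missing[:5]}")
    tan = member_tanimoto.values[
        np.ix_(
            [id_to_col[i] for i in ids],
            [id_to_col[i] for i in ids],
        )
    ] if member_tanimoto.row_ids != ids or member_tanimoto.col_ids != ids else member_tanimoto.values

    def build(labels: np.ndarray) -> list[StructuralCluster]:
        out = []
        for cl in sorted(set(labels)):
            idx = [i for i, lab in enumerate(labels) if lab == cl]
            coh = _cohesion(idx, tan, tanimoto_threshold)
            out.append(
                StructuralCluster(
                    cluster_id=int(cl),
                    member_ids=[ids[i] for i in idx],
                    cohesion=coh,
                    is_structural=coh > 0.5,
                )
            )
        return out

    n = len(ids)
    if n == 1:
        return [StructuralCluster(1, list(ids), 1.0, True)]
    if isinstance(cut, str):
        if cut != "auto":
            raise ValueError(f"unknown cut criterion: {cut!r}")
        all_cuts = hierarchy.cut_tree(dend.linkage)  # column n-k = labels at k clusters
        for k in range(1, n + 1):
            clusters = build(all_cuts[:, n - k])
            if all(c.is_structural for c in clusters if len(c.member_ids) > 1):
                return clusters
        return clusters  # all-singleton fallback, always structural
    if isinstance(cut, bool):
        raise ValueError("cut must be 'auto', a height (float) or a count (int)")
    if isinstance(cut, int):
        labels = hierarchy.fcluster(dend.linkage, t=cut, criterion="maxclust")
        return build(labels)
    labels = hierarchy.fcluster(dend.linkage, t=float(cut), criterion="distance")
    return build(labels)


def fisher_enrichment(k: int, K: int, n: int, N: int, alternative: str = "two-sided") -> EnrichmentResult:
    """Fisher's exact test for hit enrichment of a compound group.

    ``k`` hits in a group of ``K`` compounds, out of ``n`` hits in a library
    of ``N``.  The two-sided p sums hypergeometric point probabilities no
    larger than the observed table's, the convention of the common
    implementations; the odds ratio is the sample odds ratio
    ``k(N-K-n+k) / ((K-k)(n-k))`` with infinity on zero denominators.
    """
    if not (0 <= k <= min(K, n) and k <= K <= N and n <= N):
        raise ValueError(f"inconsistent 2x2 margins: k={k}, K={K}, n={n}, N={N}")
    if (n - k) > (N - K):
        raise ValueError(f"non-hits in group exceed capacity: k={k}, K={K}, n={n}, N={N}")
    table = np.array([[k, n - k], [K - k, (N - K) - (n - k)]])
    _, p = stats.fisher_exact(table, alternative=alternative)
    num = k * table[1, 1]
    den = (K - k) * (n - k)
    if den == 0:
        odds = math.inf if num > 0 else math.nan
    else:
        odds = num / den
    return EnrichmentResult(
        group_id="", k=k, K=K, n=n, N=N, odds_ratio=odds, p_two_sided=float(p)
    )


def enrichment_report(
    groups: dict[str, list[str]],
    library: list[ChemicalRecord],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher enrichment of every compound group against the library
    background, sorted by p.

    ``groups`` maps a group id (structural cluster or annotation class) to
    member compound ids.  Counts are ``k`` = hits in group, ``K`` = group
    size, ``n`` = library hits, ``N`` = library size.  Empty groups are
    skipped with a warning.  Reported p-values are rounded to 4 decimals.
    """
    hit_ids = {r.compound_id for r in library if r.is_hit}
    lib_ids = {r.compound_id for r in library}
    N = len(library)
    n = len(hit_ids)
    rows = []
    for gid, members in groups.items():
        members = [m for m in members if m in lib_ids]
        if not members:
            warnings.warn(f"group {gid!r} has no members in the library; skipped", stacklevel=2)
            continue
        K = len(set(members))
        k = len(set(members) & hit_ids)
        res = fisher_enrichment(k, K, n, N, alternative=alternative)
        rows.append((gid, k, K, n, N, res.odds_ratio, round(res.p_two_sided, 4)))
    df = pd.DataFrame(
        rows, columns=["group_id", "k", "K", "n", "N", "odds_ratio", "p_two_sided"]
    )
    return df.sort_values("p_two_sided", kind="mergesort").reset_index(drop=True)


def clusters_from_records(
    records: list[ChemicalRecord],
    tanimoto_threshold: float = 0.55,
    cut: str | float | int = "auto",
) -> tuple[Dendrogram, list[StructuralCluster]]:
    """Convenience: full-library clustering straight from compound records."""
    tan = pairwise_tanimoto(records)
    dend = cluster_dendrogram(tan, axis="rows")
    clusters = extract_structural_clusters(dend, tan, tanimoto_threshold, cut)
    return dend, clusters
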