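"""Community profiling: binning, diversity, distances and ordination.

Filtered reads are binned by the merge-group representative of their
closest reference, giving a sample x bin count table (the two gene
families are profiled separately and concatenated for whole-community
analyses).  On top of that table this module computes:

* Shannon diversity H = -sum p_i ln p_i (natural log);
* complete-linkage OTU clustering of aligned proteins at distance cutoffs;
* the abundance-based Chao-Jaccard dissimilarity, which corrects the
  shared-species probability estimates U and V for unseen shared species
  using shared singleton/doubleton counts;
* nonmetric multidimensional scaling (Kruskal stress-1, isotonic
  regression on ranks) with seeded random restarts plus one restart
  initialised from metric MDS, reporting Shepard pairs;
* per-column conservation profiles of protein alignments with a > 95%
  conserved-site rule applied jointly to reference and amplicon sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .framealign import FrameAlignment
from .refdb import GAP_CHARS, distance_matrix as _ref_distance_matrix

__all__ = [
    "OrdinationResult",
    "ConservationProfile",
    "bin_counts",
    "relative_abundance",
    "shannon",
    "complete_linkage_from_matrix",
    "complete_linkage_otus",
    "chao_jaccard",
    "chao_jaccard_matrix",
    "nmds",
    "conservation_profile",
]


def bin_counts(
    alignments_by_sample: Mapping[str, Iterable[FrameAlignment]],
    merge_groups: Mapping[str, Sequence[str]],
    gene_family: str = "",
) -> pd.DataFrame:
    """Sample x bin count table; bins are merge-group representatives.

    Every read increments the bin of its best reference's representative.
    Empty samples keep an all-zero row.  Raises on references missing from
    the merge groups (they should have been excluded upstream).
    """
    member_to_rep = {m: rep for rep, members in merge_groups.items() for m in members}
    bins = sorted(merge_groups)
    prefix = f"{gene_family}:" if gene_family else ""
    table = pd.DataFrame(
        0, index=sorted(alignments_by_sample), columns=[prefix + b for b in bins], dtype=int
    )
    for sample, alignments in alignments_by_sample.items():
        for aln in alignments:
            rep = member_to_rep.get(aln.ref_id)
            if rep is None:
                raise ValueError(f"reference {aln.ref_id} is not in any merge group")
            table.loc[sample, prefix + rep] += 1
    table.index.name = "sample"
    return table


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalised abundances; all-zero rows stay zero."""
    totals = counts.sum(axis=1)
    out = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return out


def shannon(row: Sequence[float] | pd.Series) -> float:
    """Shannon index H = -sum p ln p over nonzero bins (natural log)."""
    x = np.asarray(row, dtype=float)
    if x.sum() <= 0:
        return float("nan")
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def complete_linkage_from_matrix(
    dm: DistanceMatrix, cutoffs: Sequence[float]
) -> dict[float, dict[str, int]]:
    """Complete-linkage clustering of a dissimilarity matrix at each cutoff.

    At cutoff c every cluster has maximum intra-cluster dissimilarity <= c.
    Returns, per cutoff, a mapping id -> cluster label (1-based).
    """
    ids = list(dm.ids)
    if len(ids) == 1:
        return {c: {ids[0]: 1} for c in cutoffs}
    condensed = squareform(dm.data, checks=False)
    Z = linkage(condensed, method="complete")
    out: dict[float, dict[str, int]] = {}
    for c in cutoffs:
        labels = fcluster(Z, t=c, criterion="distance")
        out[c] = dict(zip(ids, (int(l) for l in labels)))
    return out


def complete_linkage_otus(
    aligned: Mapping[str, str], cutoffs: Sequence[float]
) -> dict[float, dict[str, int]]:
    """Complete-linkage OTUs of aligned proteins (pairwise-deletion distance)."""
    if len(aligned) == 1:
        only = next(iter(aligned))
        return {c: {only: 1} for c in cutoffs}
    return complete_linkage_from_matrix(_ref_distance_matrix(aligned), cutoffs)


def _chao_shared_probability(x: np.ndarray, y: np.ndarray) -> float:
    """Chao-corrected estimate of the probability mass of x on shared species."""
    n, m = x.sum(), y.sum()
    shared = (x > 0) & (y > 0)
    u = x[shared].sum() / n
    f_plus1 = int(((y == 1) & shared).sum())
    f_plus2 = int(((y == 2) & shared).sum())
    correction = ((m - 1) / m) * (f_plus1 / (2 * max(f_plus2, 1))) \
        * x[shared & (y == 1)].sum() / n
    return min(u + correction, 1.0)


def chao_jaccard(x: Sequence[float], y: Sequence[float]) -> float:
    """Abundance-based Chao-Jaccard dissimilarity between two count rows.

    d = 1 - UV / (U + V - UV), where U and V estimate the total relative
    abundance each assemblage places on shared species, corrected upward
    for unseen shared species via shared singletons/doubletons and capped
    at 1.  Identical rows give 0, disjoint supports give 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rows must cover the same bins")
    if x.sum() <= 0 or y.sum() <= 0:
        return float("nan")
    if not ((x > 0) & (y > 0)).any():
        return 1.0
    u = _chao_shared_probability(x, y)
    v = _chao_shared_probability(y, x)
    j = u * v / (u + v - u * v)
    return float(min(max(1.0 - j, 0.0), 1.0))


def chao_jaccard_matrix(counts: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Chao-Jaccard distances between the rows of a count table."""
    samples = list(counts.index)
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = chao_jaccard(counts.iloc[i].values, counts.iloc[j].values)
    return DistanceMatrix(mat, samples)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1 of the best restart
    shepard_pairs: tuple[tuple[float, float], ...]  # (observed, ordination) per pair
    seed: int
    n_restarts: int


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling: deterministic eigendecomposition start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    comp = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(comp)


def _stress1(observed: np.ndarray, embedded: np.ndarray) -> float:
    iso = IsotonicRegression()
    dhat = iso.fit_transform(observed, embedded)
    denom = (embedded**2).sum()
    if denom == 0:
        return float("nan")
    return float(np.sqrt(((embedded - dhat) ** 2).sum() / denom))


def nmds(d: DistanceMatrix, k: int = 2, seed: int = 0, restarts: int = 20) -> OrdinationResult:
    """Nonmetric MDS by Kruskal stress-1 minimisation.

    Runs `restarts` seeded random initialisations plus one initialisation
    from classical (Torgerson) metric scaling and keeps the lowest-stress
    configuration, so the result is never worse than a metric start.
    Fixed seeds give identical coordinates across runs.
    """
    samples = list(d.ids)
    if len(samples) < k + 2:
        raise ValueError(f"need at least {k + 2} samples for k={k}")
    D = np.asarray(d.data, dtype=float)
    triu = np.triu_indices_from(D, k=1)
    observed = D[triu]
    if np.allclose(observed, observed[0] if observed.size else 0.0):
        warnings.warn("all pairwise distances equal; ordination is arbitrary", stacklevel=2)

    common = dict(n_components=k, metric=False, dissimilarity="precomputed",
                  normalized_stress=True, max_iter=500, eps=1e-9)
    with warnings.catch_warnings():
        # sklearn is mid-rename of the MDS keyword API; the old spelling is correct here
        warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(n_init=restarts, random_state=seed, **common)
        emb = mds.fit_transform(D)
        best_emb, best_stress = emb, float(mds.stress_)

        metric_init = _classical_mds(D, k)
        mds2 = MDS(n_init=1, random_state=seed, **common)
        emb2 = mds2.fit_transform(D, init=metric_init)
        if float(mds2.stress_) < best_stress:
            best_emb, best_stress = emb2, float(mds2.stress_)

    emb_dist = pdist(best_emb)
    shepard = tuple(zip(observed.tolist(), emb_dist.tolist()))
    coords = pd.DataFrame(best_emb, index=samples,
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    coords.index.name = "sample"
    return OrdinationResult(coords, best_stress, shepard, seed, restarts)


@dataclass(frozen=True)
class ConservationProfile:
    frequencies: pd.DataFrame  # columns x residues, rows sum to 1 over non-gap
    consensus: str
    conserved_positions: tuple[int, ...]  # 0-based columns with max freq > 0.95


def _profile(alignment: Sequence[str], threshold: float) -> ConservationProfile:
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    arr = np.array([list(s.upper()) for s in alignment])
    ncol = arr.shape[1]
    residues = sorted(set(arr.ravel()) - GAP_CHARS)
    freq = np.zeros((ncol, len(residues)))
    consensus = []
    conserved = []
    for c in range(ncol):
        col = arr[:, c]
        col = col[~np.isin(col, list(GAP_CHARS))]
        if col.size == 0:
            consensus.append("-")
            continue
        counts = pd.Series(col).value_counts()
        for r, cnt in counts.items():
            freq[c, residues.index(r)] = cnt / col.size
        top = counts.max()
        # modal residue, ties alphabetical
        consensus.append(sorted(counts[counts == top].index)[0])
        if top / col.size > threshold:
            conserved.append(c)
    fdf = pd.DataFrame(freq, columns=residues)
    fdf.index.name = "column"
    return ConservationProfile(fdf, "".join(consensus), tuple(conserved))


def conservation_profile(
    reference_alignment: Sequence[str],
    amplicon_alignment: Sequence[str],
    threshold: float = 0.95,
) -> tuple[ConservationProfile, ConservationProfile, tuple[int, ...]]:
    """Per-column conservation of reference and amplicon protein alignments.

    Both alignments must share model coordinates (equal column count).
    Jointly conserved positions are the columns whose modal residue
    frequency strictly exceeds the threshold in BOTH sets.
    """
    ref = _profile(reference_alignment, threshold)
    amp = _profile(amplicon_alignment, threshold)
    if len(ref.consensus) != len(amp.consensus):
        raise ValueError("alignments do not share model coordinates")
    jointly = tuple(sorted(set(ref.conserved_positions) & set(amp.conserved_positions)))
    return ref, amp, jointly
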