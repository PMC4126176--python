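"""Curation of protein reference sets for butyrate-pathway genes.

Public databases mix bona fide butyryl-CoA:acetate CoA-transferase (*but*)
and butyrate kinase (*buk*) sequences with closely related decoy homologs
(4-hydroxybutyrate CoA-transferase, acetate kinase) and with partial
entries.  This module builds a trustworthy reference set in four steps:

1. drop partial sequences by model coverage, (last filled model position −
   first filled model position) / model length, keeping >= 93% by default;
2. align the survivors and compute pairwise protein dissimilarities
   (pairwise-deletion identity over shared columns);
3. build a neighbor-joining tree and keep the maximal edge-cut partition
   that contains every functionally verified anchor of the target family
   and no verified decoy;
4. merge references under 2% dissimilarity into single bins (single
   linkage), each represented by its lexicographically smallest id.

Trees are :class:`skbio.TreeNode`; distance matrices are
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "ReferenceProtein",
    "CuratedSet",
    "CurationResult",
    "InvalidReferenceError",
    "UndefinedDistanceError",
    "TooFewTaxaError",
    "UnresolvablePartitionError",
    "model_coverage",
    "filter_full_length",
    "protein_distance",
    "align_pair",
    "align_references",
    "distance_matrix",
    "nj_tree",
    "partition_by_anchors",
    "merge_similar",
    "curate",
    "read_reference_set",
]

GAP_CHARS = frozenset("-.")
_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class InvalidReferenceError(ValueError):
    pass


class UndefinedDistanceError(ValueError):
    pass


class TooFewTaxaError(ValueError):
    pass


class UnresolvablePartitionError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceProtein:
    """A full-length protein reference with gene-family-model span metadata."""

    id: str
    gene_family: str  # but | buk | decoy
    sequence: str
    model_first: int = 1
    model_last: int = 1
    model_length: int = 1
    verified: bool = False
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence.upper()) - _AA:
            bad = set(self.sequence.upper()) - _AA
            raise InvalidReferenceError(
                f"{self.id}: sequence empty or has non-amino-acid characters {sorted(bad)}"
            )
        if self.model_length < 1 or self.model_first < 1 or self.model_last < self.model_first:
            raise InvalidReferenceError(f"{self.id}: invalid model span fields")
        if self.model_last > self.model_length:
            raise InvalidReferenceError(f"{self.id}: model_last exceeds model_length")


@dataclass(frozen=True)
class CuratedSet:
    """Outcome of anchor-based curation over coverage-passing references."""

    kept: tuple[str, ...]
    excluded: tuple[str, ...]
    merge_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def representative_of(self, ref_id: str) -> str:
        for rep, members in self.merge_groups.items():
            if ref_id in members:
                return rep
        raise KeyError(f"{ref_id} not in any merge group")


def model_coverage(ref: ReferenceProtein) -> float:
    """Fraction of the family model spanned: (model_last − model_first)/model_length."""
    if ref.model_length == 0:
        raise InvalidReferenceError(f"{ref.id}: zero model length")
    return (ref.model_last - ref.model_first) / ref.model_length


def filter_full_length(
    refs: Sequence[ReferenceProtein], cutoff: float = 0.93
) -> list[ReferenceProtein]:
    """Keep references with model coverage >= cutoff (boundary inclusive)."""
    if not refs:
        raise ValueError("empty reference list")
    passing = [r for r in refs if model_coverage(r) >= cutoff]
    if not passing:
        warnings.warn("no references pass the coverage filter", stacklevel=2)
    return passing


def protein_distance(a: str, b: str) -> float:
    """Pairwise-deletion dissimilarity between two aligned protein rows.

    Columns gapped in either sequence are ignored; the distance is
    1 − identical pairs / compared columns.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    compared = ident = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        compared += 1
        if ca == cb:
            ident += 1
    if compared == 0:
        raise UndefinedDistanceError("no overlapping aligned columns")
    return 1.0 - ident / compared


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global BLOSUM62 alignment of two protein sequences, gapped strings out."""
    aln = _make_aligner().align(a.upper(), b.upper())[0]
    ga, gb = [], []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        if sa > pa:
            ga.append(a[pa:sa])
            gb.append("-" * (sa - pa))
        if sb > pb:
            ga.append("-" * (sb - pb))
            gb.append(b[pb:sb])
        ga.append(a[sa:ea])
        gb.append(b[sb:eb])
        pa, pb = ea, eb
    if pa < len(a):
        ga.append(a[pa:])
        gb.append("-" * (len(a) - pa))
    if pb < len(b):
        ga.append("-" * (len(b) - pb))
        gb.append(b[pb:])
    return "".join(ga).upper(), "".join(gb).upper()


def align_references(seqs: Mapping[str, str]) -> dict[str, str]:
    """Progressive star alignment of full-length references.

    Same-length inputs (the usual case for coverage-filtered references)
    are used as-is.  Otherwise every sequence is aligned to a central
    scaffold (longest sequence, ties by id) and the pairwise gap patterns
    are merged into common columns.
    """
    ids = sorted(seqs)
    lengths = {len(seqs[i]) for i in ids}
    if len(lengths) == 1:
        return {i: seqs[i].upper() for i in ids}

    scaffold_id = min(ids, key=lambda i: (-len(seqs[i]), i))
    scaffold = seqs[scaffold_id].upper()
    L = len(scaffold)
    # per sequence: residue aligned to each scaffold column, plus insertions
    per_seq_cols: dict[str, list[str]] = {}
    per_seq_ins: dict[str, list[str]] = {}
    for sid in ids:
        if sid == scaffold_id:
            per_seq_cols[sid] = list(scaffold)
            per_seq_ins[sid] = [""] * (L + 1)
            continue
        ga, gb = align_pair(scaffold, seqs[sid])
        cols = ["-"] * L
        ins: list[str] = [""] * (L + 1)
        k = 0  # scaffold position
        for ca, cb in zip(ga, gb):
            if ca in GAP_CHARS:
                ins[k] += cb
            else:
                if cb not in GAP_CHARS:
                    cols[k] = cb
                k += 1
        per_seq_cols[sid] = cols
        per_seq_ins[sid] = ins

    ins_width = [max(len(per_seq_ins[sid][k]) for sid in ids) for k in range(L + 1)]
    out: dict[str, str] = {}
    for sid in ids:
        parts = []
        for k in range(L + 1):
            chunk = per_seq_ins[sid][k]
            parts.append(chunk + "-" * (ins_width[k] - len(chunk)))
            if k < L:
                parts.append(per_seq_cols[sid][k])
        out[sid] = "".join(parts)
    return out


def distance_matrix(aligned: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise-deletion dissimilarity matrix over aligned references."""
    ids = sorted(aligned)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = protein_distance(aligned[ids[i]], aligned[ids[j]])
    return DistanceMatrix(mat, ids)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Additive input distances are reproduced exactly by tree path lengths.
    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling edge of the join, so downstream edge cuts see
    non-negative lengths.  The returned tree is unrooted (trifurcating
    root); joins are tie-broken by id order for determinism.
    """
    ids = list(d.ids)
    if len(ids) < 3:
        raise TooFewTaxaError(f"neighbor joining needs >=3 taxa, got {len(ids)}")
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dist[(a, b)] = dist[(b, a)] = float(d[a, b])
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    active = list(ids)
    counter = 0

    def _pair(u: str, v: str) -> float:
        return dist[(u, v)] if u != v else 0.0

    while len(active) > 3:
        n = len(active)
        r = {u: sum(_pair(u, v) for v in active) for u in active}
        best = None
        for i, u in enumerate(active):
            for v in active[i + 1 :]:
                q = (n - 2) * _pair(u, v) - r[u] - r[v]
                if best is None or q < best[0] - 1e-12:
                    best = (q, u, v)
        _, u, v = best
        lu = 0.5 * _pair(u, v) + (r[u] - r[v]) / (2 * (n - 2))
        lv = _pair(u, v) - lu
        if lu < 0:
            lv += -lu
            lu = 0.0
        if lv < 0:
            lu += -lv
            lv = 0.0
        counter += 1
        new_id = f"_nj{counter}"
        parent = TreeNode()
        nodes[u].length = lu
        nodes[v].length = lv
        parent.extend([nodes[u], nodes[v]])
        nodes[new_id] = parent
        for w in active:
            if w in (u, v):
                continue
            dw = 0.5 * (_pair(u, w) + _pair(v, w) - _pair(u, v))
            dist[(new_id, w)] = dist[(w, new_id)] = dw
        active = [w for w in active if w not in (u, v)] + [new_id]

    a, b, c = active
    la = 0.5 * (_pair(a, b) + _pair(a, c) - _pair(b, c))
    lb = 0.5 * (_pair(a, b) + _pair(b, c) - _pair(a, c))
    lc = 0.5 * (_pair(a, c) + _pair(b, c) - _pair(a, b))
    root = TreeNode()
    for node_id, length in ((a, la), (b, lb), (c, lc)):
        nodes[node_id].length = max(length, 0.0)
        root.append(nodes[node_id])
    return root


def partition_by_anchors(
    tree: TreeNode,
    positive_anchors: Iterable[str],
    negative_anchors: Iterable[str],
) -> CuratedSet:
    """Maximal edge-cut partition separating verified targets from decoys.

    Scans every bipartition induced by an edge of the (unrooted) tree and
    keeps the largest leaf set that contains all positive anchors and no
    negative anchor.  Invariant to rooting and leaf order.  Raises
    :class:`UnresolvablePartitionError` when no edge separates the anchors.
    """
    pos = frozenset(positive_anchors)
    neg = frozenset(negative_anchors)
    leaves = frozenset(t.name for t in tree.tips())
    if pos & neg:
        raise ValueError(f"anchors overlap: {sorted(pos & neg)}")
    missing = (pos | neg) - leaves
    if missing:
        raise ValueError(f"anchors not in tree: {sorted(missing)}")
    if not pos:
        raise ValueError("at least one positive anchor required")
    if not neg:
        return CuratedSet(kept=tuple(sorted(leaves)), excluded=())

    best: frozenset[str] | None = None
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips(include_self=True))
        for cand in (side, leaves - side):
            if pos <= cand and not (neg & cand):
                if best is None or (len(cand), sorted(cand)) > (len(best), sorted(best)):
                    best = cand
    if best is None:
        raise UnresolvablePartitionError(
            f"no edge separates positives {sorted(pos)} from negatives {sorted(neg)}"
        )
    return CuratedSet(
        kept=tuple(sorted(best)),
        excluded=tuple(sorted(leaves - best)),
    )


def merge_similar(
    ref_ids: Sequence[str], d: DistanceMatrix, cutoff: float = 0.02
) -> dict[str, tuple[str, ...]]:
    """Single-linkage merge of references under the dissimilarity cutoff.

    Any pair strictly below `cutoff` joins a group (transitively); the
    representative is the lexicographically smallest member id.
    """
    ids = sorted(ref_ids)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if float(d[a, b]) < cutoff:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return {rep: tuple(sorted(members)) for rep, members in sorted(groups.items())}


@dataclass(frozen=True)
class CurationResult:
    curated: CuratedSet
    tree: TreeNode
    distances: DistanceMatrix
    aligned: dict[str, str]
    report: pd.DataFrame  # id, status, reason


def curate(
    refs: Sequence[ReferenceProtein],
    coverage_cutoff: float = 0.93,
    merge_cutoff: float = 0.02,
) -> CurationResult:
    """Full curation: coverage filter, alignment, NJ tree, anchor partition, merge."""
    passing = filter_full_length(refs, coverage_cutoff)
    dropped_cov = [r for r in refs if r not in passing]
    aligned = align_references({r.id: r.sequence for r in passing})
    dm = distance_matrix(aligned)
    tree = nj_tree(dm)
    positives = [r.id for r in passing if r.verified and r.gene_family != "decoy"]
    negatives = [r.id for r in passing if r.verified and r.gene_family == "decoy"]
    part = partition_by_anchors(tree, positives, negatives)
    groups = merge_similar(part.kept, dm, merge_cutoff)
    curated = replace(part, merge_groups=groups)

    rows = [{"id": r.id, "status": "dropped", "reason": "coverage_below_cutoff"} for r in dropped_cov]
    rows += [{"id": i, "status": "excluded", "reason": "outside_anchor_cluster"} for i in curated.excluded]
    rows += [{"id": i, "status": "kept", "reason": ""} for i in curated.kept]
    report = pd.DataFrame(rows, columns=["id", "status", "reason"]).sort_values("id", ignore_index=True)
    return CurationResult(curated, tree, dm, aligned, report)


def read_reference_set(fasta_path, meta_tsv_path) -> list[ReferenceProtein]:
    """Load references from FASTA plus a sidecar TSV of model spans.

    TSV columns: id, model_first, model_last, model_length, verified,
    taxon_label, gene_family.
    """
    meta = pd.read_csv(meta_tsv_path, sep="\t", dtype={"id": str})
    meta = meta.set_index("id")
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise ValueError(f"no metadata row for sequence {rec.id}")
        row = meta.loc[rec.id]
        refs.append(
            ReferenceProtein(
                id=rec.id,
                gene_family=str(row["gene_family"]),
                sequence=str(rec.seq),
                model_first=int(row["model_first"]),
                model_last=int(row["model_last"]),
                model_length=int(row["model_length"]),
                verified=bool(row["verified"]),
                taxon_label=str(row.get("taxon_label", "")),
            )
        )
    return refs
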