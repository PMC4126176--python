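"""Frameshift-aware alignment of amplicon reads to protein references.

Pyrosequencing reads of protein-coding amplicons carry homopolymer indels
that shift the reading frame, so naive six-frame translation destroys the
encoded protein.  This module aligns a DNA read directly against an
amino-acid reference with a local dynamic program whose states are
(nucleotides consumed, reference residues consumed):

* match       — 3 nt + 1 aa, scored by a substitution matrix (BLOSUM62)
                on the translated codon;
* frameshift  — 1, 2 or 4 nt + 1 aa, a flat penalty per event;
* codon gap   — 3 nt and no reference residue (affine, aa units);
* residue gap — 1 aa and no read nucleotides (affine).

The traceback yields a frameshift-corrected protein: matched codons are
translated in the phase the optimum chose, and frameshifted columns
contribute the reference residue (a correction, not a literal
translation).  Identity is computed on the corrected protein over aligned
columns, so frameshift columns count as identical by construction.  Both
strands are searched and the better-scoring one wins.

Downstream gates reproduce the profiling workflow: a read is kept when it
reaches 30% identity and a family-specific aligned length (100 aa for
*but*, 125 aa for *buk*); only reads at >= 70% identity to their closest
match feed ordination and binning.

The matrix fill is JIT-compiled with numba; the first alignment in a
process pays the compilation cost.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from numba import njit

from .refdb import CuratedSet

__all__ = [
    "AmpliconRead",
    "QCParams",
    "ScoringParams",
    "FrameAlignment",
    "FilterThresholds",
    "FilterOutcome",
    "FrameStats",
    "quality_filter",
    "frame_align",
    "closest_match",
    "apply_filters",
    "frameshift_stats",
    "exclude_outside_cluster",
    "translate",
    "reverse_complement",
]

_NEG = -1.0e18

_BLOSUM = substitution_matrices.load("BLOSUM62")
AA_ALPHABET = "".join(_BLOSUM.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_SUB = np.asarray(_BLOSUM, dtype=np.float64)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_CODON_TABLE.forward_table)
for _stop in _CODON_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def translate(dna: str) -> str:
    """Codon-wise translation; ambiguous or partial codons become X."""
    dna = dna.upper()
    return "".join(
        _CODON_TO_AA.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3)
    )


def reverse_complement(dna: str) -> str:
    return dna.upper().translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconRead:
    id: str
    dna: str
    sample_id: str = ""
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.dna:
            raise ValueError(f"{self.id}: empty read")
        if self.qualities is not None and len(self.qualities) != len(self.dna):
            raise ValueError(f"{self.id}: quality length != read length")


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds applied after barcode/primer trimming."""

    min_length_nt: int = 300
    max_ambiguous_bases: int = 0
    min_mean_quality: float = 20.0
    barcode_map: dict[str, str] | None = None  # barcode -> sample id
    trim_primers: tuple[str, ...] = ()  # IUPAC prefixes removed when present


@dataclass(frozen=True)
class ScoringParams:
    gap_open: float = 10.0
    gap_extend: float = 1.0
    frameshift: float = 12.0


@dataclass(frozen=True)
class FrameAlignment:
    read_id: str
    ref_id: str
    strand: str  # '+' or '-'
    score: float
    identity_pct: float
    aligned_len_aa: int
    frameshift_count: int
    frameshift_positions: tuple[int, ...]  # 0-based offsets on the aligned strand
    corrected_protein: str
    read_start: int = 0
    read_end: int = 0
    ref_start: int = 0
    ref_end: int = 0

    @property
    def is_aligned(self) -> bool:
        return self.aligned_len_aa > 0


@dataclass(frozen=True)
class FilterThresholds:
    min_identity_initial: float = 30.0
    min_identity_downstream: float = 70.0
    min_len_aa: dict[str, int] = field(default_factory=lambda: {"but": 100, "buk": 125})


@dataclass(frozen=True)
class FilterOutcome:
    initial_pass: tuple[FrameAlignment, ...]
    downstream_pass: tuple[FrameAlignment, ...]
    n_input: int

    @property
    def initial_fraction(self) -> float:
        return len(self.initial_pass) / self.n_input if self.n_input else 0.0

    @property
    def downstream_fraction(self) -> float:
        return len(self.downstream_pass) / len(self.initial_pass) if self.initial_pass else 0.0


@dataclass(frozen=True)
class FrameStats:
    mean_frameshifts_per_read: float
    fraction_with_frameshift: float
    n_reads: int


@njit(cache=True)
def _fill(aa_at, ref, sub, fs_pen, gap_open, gap_ext):  # pragma: no cover - numba
    n = aa_at.shape[0] - 1
    m = ref.shape[0]
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = 0.0
            # match: consume codon i-3..i against ref j-1
            if i >= 3 and aa_at[i] >= 0:
                prev = M[i - 3, j - 1]
                if Ix[i - 3, j - 1] > prev:
                    prev = Ix[i - 3, j - 1]
                if Iy[i - 3, j - 1] > prev:
                    prev = Iy[i - 3, j - 1]
                s = prev + sub[aa_at[i], ref[j - 1]]
                if s > best:
                    best = s
            # frameshift: consume 1, 2 or 4 nt against ref j-1
            for k in (1, 2, 4):
                if i >= k:
                    prev = M[i - k, j - 1]
                    if Ix[i - k, j - 1] > prev:
                        prev = Ix[i - k, j - 1]
                    if Iy[i - k, j - 1] > prev:
                        prev = Iy[i - k, j - 1]
                    s = prev - fs_pen
                    if s > best:
                        best = s
            M[i, j] = best
            # codon insertion in the read (gap in the reference)
            if i >= 3:
                a = M[i - 3, j] - gap_open
                b = Ix[i - 3, j] - gap_ext
                Ix[i, j] = a if a > b else b
            # gap in the read (reference residue skipped)
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_ext
            Iy[i, j] = a if a > b else b
    return M, Ix, Iy


def _encode_ref(protein: str) -> np.ndarray:
    return np.asarray([_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in protein.upper()],
                      dtype=np.int64)


def _codon_profile(dna: str) -> np.ndarray:
    """aa_at[i] = substitution-matrix index of the codon ending at nt i."""
    n = len(dna)
    aa_at = np.full(n + 1, -1, dtype=np.int64)
    for i in range(3, n + 1):
        aa = _CODON_TO_AA.get(dna[i - 3 : i], "X")
        aa_at[i] = _AA_INDEX[aa]
    return aa_at


def _cell_state(M, Ix, Iy, i, j) -> str:
    if M[i, j] >= Ix[i, j] and M[i, j] >= Iy[i, j]:
        return "M"
    return "Ix" if Ix[i, j] >= Iy[i, j] else "Iy"


def _traceback(M, Ix, Iy, aa_at, ref_idx, scoring: ScoringParams):
    i, j = (int(v) for v in np.unravel_index(int(np.argmax(M)), M.shape))
    score = float(M[i, j])
    if score <= 0.0:
        return score, []
    cols: list[tuple] = []  # ('M'|'F'|'Ix'|'Iy', i, j, k)
    state = "M"
    tol = 1e-9

    def prevmax(pi, pj):
        return max(M[pi, pj], Ix[pi, pj], Iy[pi, pj])

    while True:
        if state == "M":
            v = M[i, j]
            if v <= tol:
                break
            moved = False
            if i >= 3 and j >= 1 and aa_at[i] >= 0:
                if abs(v - (prevmax(i - 3, j - 1) + _SUB[aa_at[i], ref_idx[j - 1]])) <= tol:
                    cols.append(("M", i, j, 3))
                    ni, nj = i - 3, j - 1
                    state = _cell_state(M, Ix, Iy, ni, nj)
                    i, j = ni, nj
                    moved = True
            if not moved:
                for k in (1, 2, 4):
                    if i >= k and j >= 1 and abs(v - (prevmax(i - k, j - 1) - scoring.frameshift)) <= tol:
                        cols.append(("F", i, j, k))
                        ni, nj = i - k, j - 1
                        state = _cell_state(M, Ix, Iy, ni, nj)
                        i, j = ni, nj
                        moved = True
                        break
            if not moved:
                break
        elif state == "Ix":
            v = Ix[i, j]
            cols.append(("Ix", i, j, 3))
            if abs(v - (M[i - 3, j] - scoring.gap_open)) <= tol:
                state = "M"
            i -= 3
        else:  # Iy
            v = Iy[i, j]
            cols.append(("Iy", i, j, 0))
            if abs(v - (M[i, j - 1] - scoring.gap_open)) <= tol:
                state = "M"
            j -= 1
    cols.reverse()
    return score, cols


def _align_one_strand(dna: str, aa_at: np.ndarray, ref_idx: np.ndarray,
                      scoring: ScoringParams):
    M, Ix, Iy = _fill(aa_at, ref_idx, _SUB, scoring.frameshift,
                      scoring.gap_open, scoring.gap_extend)
    return M, Ix, Iy


def _build_alignment(read_id: str, ref_id: str, strand: str, score: float,
                     cols, aa_at, ref_idx) -> FrameAlignment:
    if not cols:
        return FrameAlignment(read_id, ref_id, strand, 0.0, 0.0, 0, 0, (), "")
    protein = []
    n_aligned = n_ident = 0
    fs_positions = []
    for kind, i, j, k in cols:
        if kind == "M":
            aa = AA_ALPHABET[aa_at[i]]
            protein.append(aa)
            n_aligned += 1
            if aa_at[i] == ref_idx[j - 1]:
                n_ident += 1
        elif kind == "F":
            protein.append(AA_ALPHABET[ref_idx[j - 1]])
            n_aligned += 1
            n_ident += 1  # corrected to the reference residue
            fs_positions.append(i - k)
        elif kind == "Ix":
            if aa_at[i] >= 0:
                protein.append(AA_ALPHABET[aa_at[i]])
    first, last = cols[0], cols[-1]
    read_start = first[1] - first[3]
    ref_start = first[2] - (0 if first[0] == "Ix" else 1)
    identity = 100.0 * n_ident / n_aligned if n_aligned else 0.0
    return FrameAlignment(
        read_id=read_id,
        ref_id=ref_id,
        strand=strand,
        score=score,
        identity_pct=identity,
        aligned_len_aa=n_aligned,
        frameshift_count=len(fs_positions),
        frameshift_positions=tuple(fs_positions),
        corrected_protein="".join(protein),
        read_start=read_start,
        read_end=last[1],
        ref_start=ref_start,
        ref_end=last[2],
    )


class ReadProfile:
    """Per-read precomputation shared across references (both strands)."""

    def __init__(self, read: AmpliconRead):
        if len(read.dna) < 3:
            raise ValueError(f"{read.id}: read shorter than one codon")
        self.read = read
        self.fwd = read.dna.upper()
        self.rev = reverse_complement(read.dna)
        self.aa_at = {"+": _codon_profile(self.fwd), "-": _codon_profile(self.rev)}


def frame_align(read: AmpliconRead | str, ref_protein: str,
                scoring: ScoringParams | None = None,
                ref_id: str = "ref") -> FrameAlignment:
    """Best frameshift-aware local alignment of a read to one reference.

    Both strands are searched; ties go to the forward strand.  An all-N or
    unalignable read yields a no-alignment result with score 0.
    """
    scoring = scoring or ScoringParams()
    if len(ref_protein) < 10:
        raise ValueError("reference shorter than 10 aa")
    if isinstance(read, str):
        read = AmpliconRead(id="read", dna=read)
    profile = ReadProfile(read)
    ref_idx = _encode_ref(ref_protein)
    best = None
    for strand in ("+", "-"):
        M, Ix, Iy = _align_one_strand(None, profile.aa_at[strand], ref_idx, scoring)
        score = float(M.max())
        if best is None or score > best[0] + 1e-9:
            best = (score, strand, M, Ix, Iy)
    score, strand, M, Ix, Iy = best
    score, cols = _traceback(M, Ix, Iy, profile.aa_at[strand], ref_idx, scoring)
    return _build_alignment(read.id, ref_id, strand, score, cols,
                            profile.aa_at[strand], ref_idx)


def closest_match(read: AmpliconRead, refs: Mapping[str, str],
                  scoring: ScoringParams | None = None) -> FrameAlignment:
    """Align a read against every reference and keep the best.

    Ties are broken by higher identity, then by lexicographic reference
    id.  A read with no positive-scoring alignment is reported unassigned
    (ref_id "", score 0).
    """
    if not refs:
        raise ValueError("empty reference set")
    scoring = scoring or ScoringParams()
    profile = ReadProfile(read)
    fills = {}
    best_score = 0.0
    for ref_name in sorted(refs):
        ref_idx = _encode_ref(refs[ref_name])
        for strand in ("+", "-"):
            M, Ix, Iy = _align_one_strand(None, profile.aa_at[strand], ref_idx, scoring)
            s = float(M.max())
            fills[(ref_name, strand)] = (s, M, Ix, Iy, ref_idx)
            if s > best_score:
                best_score = s
    if best_score <= 0.0:
        return FrameAlignment(read.id, "", "+", 0.0, 0.0, 0, 0, (), "")
    candidates = [k for k, v in fills.items() if v[0] >= best_score - 1e-9]
    alignments = []
    for ref_name, strand in candidates:
        s, M, Ix, Iy, ref_idx = fills[(ref_name, strand)]
        score, cols = _traceback(M, Ix, Iy, profile.aa_at[strand], ref_idx, scoring)
        alignments.append(_build_alignment(read.id, ref_name, strand, score, cols,
                                           profile.aa_at[strand], ref_idx))
    alignments.sort(key=lambda a: (-a.score, -a.identity_pct, a.ref_id, a.strand))
    return alignments[0]


def _count_ambiguous(dna: str) -> int:
    return sum(1 for c in dna.upper() if c not in "ACGT")


def _matches_iupac_prefix(dna: str, pattern: str) -> bool:
    from .primertools import IUPAC_SETS

    if len(dna) < len(pattern):
        return False
    return all(dna[i] in IUPAC_SETS.get(p.upper(), frozenset())
               for i, p in enumerate(pattern))


def quality_filter(
    reads: Iterable[AmpliconRead], params: QCParams | None = None
) -> tuple[list[AmpliconRead], dict[str, str]]:
    """Demultiplex, trim and quality-filter raw reads.

    Returns the passing reads (trimmed, sample-assigned) and a per-read
    reason code: pass, unassigned, short, ambiguous or low_quality.
    Reads without quality scores skip the mean-quality check.
    """
    params = params or QCParams()
    passing: list[AmpliconRead] = []
    reasons: dict[str, str] = {}
    for read in reads:
        dna = read.dna.upper()
        quals = read.qualities
        sample = read.sample_id
        if params.barcode_map is not None:
            hit = next((bc for bc in sorted(params.barcode_map, key=len, reverse=True)
                        if dna.startswith(bc.upper())), None)
            if hit is None:
                reasons[read.id] = "unassigned"
                continue
            sample = params.barcode_map[hit]
            dna = dna[len(hit):]
            quals = quals[len(hit):] if quals is not None else None
        for pattern in params.trim_primers:
            if _matches_iupac_prefix(dna, pattern):
                dna = dna[len(pattern):]
                quals = quals[len(pattern):] if quals is not None else None
                break
        if len(dna) < params.min_length_nt:
            reasons[read.id] = "short"
            continue
        if _count_ambiguous(dna) > params.max_ambiguous_bases:
            reasons[read.id] = "ambiguous"
            continue
        if quals is not None and statistics.fmean(quals) < params.min_mean_quality:
            reasons[read.id] = "low_quality"
            continue
        reasons[read.id] = "pass"
        passing.append(AmpliconRead(read.id, dna, sample, tuple(quals) if quals else None))
    return passing, reasons


def apply_filters(
    alignments: Iterable[FrameAlignment],
    family: str,
    thresholds: FilterThresholds | None = None,
) -> FilterOutcome:
    """Apply the initial (identity + length) and downstream (identity) gates."""
    th = thresholds or FilterThresholds()
    if family not in th.min_len_aa:
        raise ValueError(f"unknown gene family {family!r}")
    min_len = th.min_len_aa[family]
    alignments = list(alignments)
    initial = tuple(
        a for a in alignments
        if a.identity_pct >= th.min_identity_initial and a.aligned_len_aa >= min_len
    )
    downstream = tuple(a for a in initial if a.identity_pct >= th.min_identity_downstream)
    return FilterOutcome(initial, downstream, n_input=len(alignments))


def frameshift_stats(alignments: Sequence[FrameAlignment]) -> FrameStats:
    """Mean frameshifts per sequence and fraction with at least one."""
    if not alignments:
        raise ValueError("no alignments")
    counts = [a.frameshift_count for a in alignments]
    return FrameStats(
        mean_frameshifts_per_read=statistics.fmean(counts),
        fraction_with_frameshift=sum(1 for c in counts if c > 0) / len(counts),
        n_reads=len(counts),
    )


def exclude_outside_cluster(
    alignments: Iterable[FrameAlignment], curated: CuratedSet
) -> tuple[list[FrameAlignment], float]:
    """Drop reads whose best reference fell outside the anchor cluster.

    Returns the kept alignments and the dropped fraction.
    """
    alignments = list(alignments)
    excluded = set(curated.excluded)
    kept = [a for a in alignments if a.ref_id not in excluded]
    dropped = (len(alignments) - len(kept)) / len(alignments) if alignments else 0.0
    return kept, dropped
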