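"""Degenerate-primer algebra and amplification-coverage prediction.

Degenerate PCR primers are written in the IUPAC nucleotide code (R = A/G,
Y = C/T, ..., N = any).  This module expands such strings, computes their
degeneracy (the number of distinct plain-ACGT oligos a primer mixture
contains; primer design here keeps this at or below 100), and scores how
well a primer set covers a panel of target genes by the minimum number of
mismatches at the best binding site.  Targets are classified per primer set
into the green (predicted to amplify well), yellow (marginal) and red
(predicted to fail) categories used when evaluating primer coverage tables.

Inosine (``I``) is accepted as a universal base: it pairs with any target
base and contributes a factor of 1 to degeneracy, so an I-containing primer
expands to more plain oligos than its nominal degeneracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IUPAC_SETS",
    "DegeneratePrimer",
    "PrimerMatch",
    "SetThresholds",
    "expand_degenerate",
    "degeneracy",
    "min_mismatches",
    "best_site",
    "coverage_report",
    "reverse_complement_iupac",
    "read_primer_tsv",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    # universal base (inosine): binds everything, costs no degeneracy
    "I": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "U": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "I": "I",
}


class PrimerParseError(ValueError):
    """Raised for characters outside the IUPAC (+ inosine) alphabet."""


def _validate(iupac: str) -> str:
    seq = iupac.upper()
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise PrimerParseError(
                f"illegal IUPAC character {ch!r} at position {pos} in {iupac!r}"
            )
    return seq


def reverse_complement_iupac(iupac: str) -> str:
    """Reverse complement preserving ambiguity codes (Y -> R etc.)."""
    seq = _validate(iupac)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def expand_degenerate(iupac: str) -> set[str]:
    """Cartesian expansion of a degenerate primer into plain ACGT strings."""
    seq = _validate(iupac)
    return {"".join(t) for t in itertools.product(*(sorted(IUPAC_SETS[c]) for c in seq))}


def degeneracy(iupac: str) -> int:
    """Product of per-position code sizes (inosine counts as 1)."""
    seq = _validate(iupac)
    n = 1
    for c in seq:
        n *= 1 if c == "I" else len(IUPAC_SETS[c])
    return n


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named degenerate primer with orientation and set membership."""

    name: str
    iupac: str
    orientation: str = "forward"  # forward | reverse
    set_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "iupac", _validate(self.iupac))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.iupac)

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class PrimerMatch:
    primer_name: str
    target_id: str
    min_mismatches: int
    start: int  # 0-based offset on the forward strand of the target
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class SetThresholds:
    """Category bands for one primer set (inclusive maxima)."""

    green_max: int = 1
    yellow_max: int = 2


def min_mismatches(primer_iupac: str, window: str) -> int:
    """Mismatches between a degenerate primer and an equal-length window.

    A position matches when the target base's code is a subset of the
    primer's code; ambiguous target bases therefore count as mismatches
    unless fully covered (conservative amplification prediction).  Equals
    the minimum Hamming distance over the primer's full expansion.
    """
    p = _validate(primer_iupac)
    w = _validate(window)
    if len(p) != len(w):
        raise ValueError(f"window length {len(w)} != primer length {len(p)}")
    return sum(1 for pc, wc in zip(p, w) if not IUPAC_SETS[wc] <= IUPAC_SETS[pc])


def best_site(primer: DegeneratePrimer, target: str, target_id: str = "") -> PrimerMatch | None:
    """Best (fewest-mismatch) binding site of a primer on a target gene.

    Reverse primers are reverse-complemented and slid along the forward
    strand; coordinates are reported on the forward strand, 0-based.
    Returns None when the target is shorter than the primer.
    """
    query = primer.iupac if primer.orientation == "forward" else reverse_complement_iupac(primer.iupac)
    strand = "+" if primer.orientation == "forward" else "-"
    tgt = _validate(target)
    k = len(query)
    if len(tgt) < k:
        return None
    best_mm, best_start = None, 0
    for start in range(len(tgt) - k + 1):
        mm = min_mismatches(query, tgt[start : start + k])
        if best_mm is None or mm < best_mm:
            best_mm, best_start = mm, start
            if mm == 0:
                break
    return PrimerMatch(primer.name, target_id, best_mm, best_start, strand)


def _categorize(mm: int | None, th: SetThresholds) -> str:
    if mm is None:
        return "red"
    if mm <= th.green_max:
        return "green"
    if mm <= th.yellow_max:
        return "yellow"
    return "red"


def coverage_report(
    primers: Iterable[DegeneratePrimer],
    targets: Mapping[str, str],
    thresholds: Mapping[str, SetThresholds] | None = None,
) -> pd.DataFrame:
    """Per-target, per-primer-set minimum mismatches and color category.

    For each set the reported mismatch count is the minimum over the set's
    members and over all binding sites (forward primers on the forward
    strand, reverse primers against the reverse complement), mirroring
    coverage tables where results are merged across all primers of a set.
    Returns a tidy frame with columns target, set, min_mismatches, category.
    Targets shorter than every primer of a set are red with mismatches NA.
    """
    thresholds = thresholds or {}
    by_set: dict[str, list[DegeneratePrimer]] = {}
    seen: set[tuple[str, str, str]] = set()
    for p in primers:
        key = (p.set_name, p.iupac, p.orientation)
        if key in seen:  # duplicate primers within a set are inert
            continue
        seen.add(key)
        by_set.setdefault(p.set_name or p.name, []).append(p)

    rows = []
    for tid in sorted(targets):
        for set_name in sorted(by_set):
            th = thresholds.get(set_name, SetThresholds())
            mms = [m.min_mismatches for p in by_set[set_name]
                   if (m := best_site(p, targets[tid], tid)) is not None]
            mm = min(mms) if mms else None
            rows.append({
                "target": tid,
                "set": set_name,
                "min_mismatches": mm,
                "category": _categorize(mm, th),
            })
    return pd.DataFrame(rows, columns=["target", "set", "min_mismatches", "category"])


def read_primer_tsv(path) -> list[DegeneratePrimer]:
    """Read a primer table: name<TAB>iupac<TAB>orientation<TAB>set."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"name", "iupac", "orientation", "set"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer TSV missing columns: {sorted(missing)}")
    return [
        DegeneratePrimer(r["name"], r["iupac"], r["orientation"], r["set"])
        for r in df.to_dict("records")
    ]
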