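"""Synthetic fixtures with known truth for every pipeline stage.

Real input data for this workflow are protein reference databases,
454-style amplicon reads and qPCR plates.  This module fabricates all of
them from a single seed so that every stage can be tested against planted
truth without downloads:

* mock reference families — proteins evolved from a random ancestor by
  point substitution, plus earlier-branching decoy homologs (the
  4-hydroxybutyrate CoA-transferase / acetate kinase role), a
  near-duplicate pair to exercise <2% merging, and a configurable
  fraction of partial entries that must fail the 93% coverage filter;
* reads — reference windows reverse-translated with uniform synonymous
  codon choice, point substitutions, and homopolymer-run +-1 indels (the
  dominant 454 error mode) planted at a configured per-read distribution;
  half the reads are emitted reverse-complemented;
* read-level contaminants matching the observed composition of real
  runs: planted quality-control failures, off-target (host-derived-like)
  random reads, reads from unreferenced diverged variants that fall below
  the 70% identity gate, and reads from decoy references that the
  tree-based curation later excludes;
* qPCR standard curves and duplicate Cq tables with Gaussian noise, and
  16S taxon count tables with per-taxon copy numbers.

Default rates mirror the sequencing-run statistics the workflow was built
around: 87%/94% of *but*/*buk* reads passing quality control, 59%/97%
passing the identity/length gates, frameshifts at mean 0.6/1.6 per read
with 30%/58% of reads affected, 97%/93% at >=70% identity, under 1% of
amplicons matching out-of-cluster references, and amplicons around
425/500 nt.  The planted frameshift count is zero-inflated Poisson with
parameters solved from the target mean and nonzero fraction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .framealign import AmpliconRead, _CODON_TO_AA
from .quantify import QpcrMeasurement
from .refdb import ReferenceProtein

__all__ = [
    "FamilySynthConfig",
    "SynthConfig",
    "SynthFamily",
    "ReadTruth",
    "TruthSet",
    "QpcrFixture",
    "TaxonFixture",
    "solve_zero_inflated_poisson",
    "make_reference_families",
    "make_reads",
    "make_qpcr",
    "make_taxon_table",
    "write_fixtures",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class FamilySynthConfig:
    """Per-gene-family generator settings (defaults = study conditions)."""

    name: str
    n_refs: int = 6
    n_decoys: int = 3
    protein_len: int = 160
    read_len: int = 425
    member_divergence: tuple[float, float] = (0.05, 0.15)
    decoy_divergence: tuple[float, float] = (0.45, 0.55)
    partial_fraction: float = 0.15
    near_dup_distance: float = 0.01
    subst_rate: float = 0.01  # per-nt read substitutions
    fs_mean: float = 0.6
    fs_fraction: float = 0.30  # fraction of reads with >=1 planted frameshift
    fs_exact: int | None = None  # plant exactly this many indels per read instead
    qc_fail_fraction: float = 0.13
    off_target_fraction: float = 0.41
    # fraction of QC-passing reads drawn from an unreferenced diverged
    # variant; 0.018 of passing reads = 3% of gate-passing reads when 41%
    # are off-target, so 97% of gate-passing reads clear the 70% identity cut
    novel_fraction: float = 0.018
    decoy_read_fraction: float = 0.005


def default_families() -> dict[str, FamilySynthConfig]:
    return {
        "but": FamilySynthConfig(name="but"),
        "buk": FamilySynthConfig(
            name="buk", protein_len=180, read_len=500,
            fs_mean=1.6, fs_fraction=0.58,
            qc_fail_fraction=0.06, off_target_fraction=0.03,
            novel_fraction=0.068,  # 7% of gate-passing reads below 70% identity
        ),
    }


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_samples: int = 8
    n_reads_per_sample: int = 250
    dirichlet_alpha: float = 0.7
    qpcr_cq_noise: float = 0.05
    families: dict[str, FamilySynthConfig] = field(default_factory=default_families)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_samples))


@dataclass(frozen=True)
class SynthFamily:
    """A generated reference family plus everything reads are drawn from."""

    config: FamilySynthConfig
    refs: tuple[ReferenceProtein, ...]  # targets + decoys (+ near-duplicate)
    positive_anchors: tuple[str, ...]
    negative_anchors: tuple[str, ...]
    ghost_protein: str  # diverged unreferenced variant (below the 70% gate)
    window_start: int
    window_len: int

    @property
    def target_ids(self) -> tuple[str, ...]:
        """Read-source references: full-coverage targets (no decoys/duplicates)."""
        return tuple(
            r.id for r in self.refs
            if r.gene_family != "decoy" and not r.id.endswith("b")
            and (r.model_last - r.model_first) / r.model_length >= 0.93
        )

    @property
    def decoy_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.refs if r.gene_family == "decoy")


@dataclass(frozen=True)
class ReadTruth:
    category: str  # target | novel | decoy | off_target | qc_fail
    sample: str
    source_ref: str | None
    planted_frameshifts: int
    strand: str


@dataclass
class TruthSet:
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    composition: dict[str, dict[str, float]] = field(default_factory=dict)  # sample -> ref -> p

    def to_jsonable(self) -> dict:
        return {
            "reads": {k: dataclasses.asdict(v) for k, v in self.reads.items()},
            "composition": self.composition,
        }


def solve_zero_inflated_poisson(mean: float, nonzero_fraction: float) -> tuple[float, float]:
    """(pi, lambda) of a zero-inflated Poisson with the given mean and P(X>0).

    With probability pi a read receives Poisson(lambda) indels, else none:
    pi*lambda = mean and pi*(1-exp(-lambda)) = nonzero_fraction.
    """
    if mean <= 0:
        return 0.0, 0.0
    if not 0 < nonzero_fraction <= mean:
        raise ValueError("need 0 < nonzero_fraction <= mean")
    ratio = nonzero_fraction / mean  # = (1-exp(-lam))/lam, in (0,1)
    if ratio >= 1 - 1e-9:
        return mean, 1e-9  # Poisson limit lambda -> 0
    lam = brentq(lambda l: (1 - np.exp(-l)) / l - ratio, 1e-9, 100.0)
    pi = mean / lam
    if pi > 1 + 1e-9:
        raise ValueError("mean/nonzero_fraction combination not reachable")
    return min(pi, 1.0), lam


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate_protein(seq: str, distance: float, rng: np.random.Generator) -> str:
    n_sub = int(round(distance * len(seq)))
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in AA20 if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein
    )


def _substitute(dna: str, rate: float, rng: np.random.Generator) -> str:
    out = list(dna)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[rng.integers(4)]  # may be silent
    return "".join(out)


def _homopolymer_runs(dna: str, min_len: int = 3) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of at least min_len."""
    runs = []
    i = 0
    while i < len(dna):
        j = i
        while j < len(dna) and dna[j] == dna[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def plant_homopolymer_indels(
    dna: str, k: int, rng: np.random.Generator,
    edge_margin: int = 21, min_separation: int = 21,
) -> tuple[str, list[int]]:
    """Plant k +-1 indels, preferring homopolymer runs of >=3 nt.

    Each indel duplicates or deletes one base of a distinct run.  Sites
    stay away from the read ends and from each other so that every
    planted indel is one genuine, independently recoverable frameshift:
    an indel inside the terminal codons can be soft-clipped by a local
    aligner, and two indels a few bases apart are cheaper to explain as a
    substitution than as two frameshift events.  Random interior
    positions are used only when the sequence lacks enough usable runs.
    Returns the mutated sequence and the 0-based positions touched
    (original coordinates).
    """
    if k == 0:
        return dna, []
    lo, hi = edge_margin, len(dna) - edge_margin
    if hi <= lo:  # very short sequence: fall back to the middle third
        lo, hi = len(dna) // 3, max(len(dna) // 3 + 1, 2 * len(dna) // 3)

    def _ok(p: int, chosen: list[int]) -> bool:
        return lo <= p < hi and all(abs(p - c) >= min_separation for c in chosen)

    runs = _homopolymer_runs(dna)
    rng.shuffle(runs)
    sites: list[int] = []
    for start, length in runs:
        if len(sites) == k:
            break
        p = start + int(length // 2)
        if _ok(p, sites):
            sites.append(p)
    attempts = 0
    while len(sites) < k and attempts < 200:  # fallback: random interior sites
        p = int(rng.integers(lo, hi))
        if _ok(p, sites):
            sites.append(p)
        attempts += 1
    out = dna
    for p in sorted(sites, reverse=True):
        if rng.random() < 0.5:
            out = out[:p] + out[p] + out[p:]  # insertion (run grows)
        else:
            out = out[:p] + out[p + 1 :]  # deletion (run shrinks)
    return out, sorted(sites)


def _family_rng(cfg: SynthConfig, family: str, stream: str) -> np.random.Generator:
    # stable (non-hash-randomised) stream key for cross-process determinism
    key = tuple(family.encode()) + (0,) + tuple(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def make_reference_families(cfg: SynthConfig) -> dict[str, SynthFamily]:
    """Generate target + decoy reference proteins with anchors and spans."""
    out: dict[str, SynthFamily] = {}
    for fam_name in sorted(cfg.families):
        fc = cfg.families[fam_name]
        if fc.n_refs < 4:
            raise ValueError("need at least 4 references per family")
        rng = _family_rng(cfg, fam_name, "refs")
        L = fc.protein_len
        ancestor = _random_protein(L, rng)
        refs: list[ReferenceProtein] = []
        lo, hi = fc.member_divergence
        for i in range(fc.n_refs):
            d = rng.uniform(lo, hi)
            refs.append(ReferenceProtein(
                id=f"{fam_name}_ref{i:02d}",
                gene_family=fam_name,
                sequence=_mutate_protein(ancestor, d, rng),
                model_first=1, model_last=L, model_length=L,
                verified=i < 2,
                taxon_label=f"{fam_name.capitalize()}ibacter synthetica {i}",
            ))
        # near-duplicate of one non-anchor member, to exercise <2% merging
        dup_src = refs[2]
        refs.append(dataclasses.replace(
            dup_src,
            id=dup_src.id + "b",
            sequence=_mutate_protein(dup_src.sequence, fc.near_dup_distance, rng),
            verified=False,
        ))
        dlo, dhi = fc.decoy_divergence
        for i in range(fc.n_decoys):
            d = rng.uniform(dlo, dhi)
            refs.append(ReferenceProtein(
                id=f"{fam_name}_dec{i:02d}",
                gene_family="decoy",
                sequence=_mutate_protein(ancestor, d, rng),
                model_first=1, model_last=L, model_length=L,
                verified=i < 2,
                taxon_label=f"Decoybacter homologus {i}",
            ))
        # plant partial entries among non-anchor targets, sparing the
        # near-duplicate pair so the <2% merge case survives curation
        n_partial = int(round(fc.partial_fraction * len(refs)))
        partial_pool = [k for k, r in enumerate(refs)
                        if not r.verified and r.gene_family != "decoy"
                        and r.id not in (dup_src.id, dup_src.id + "b")]
        for k in partial_pool[:n_partial]:
            cov = rng.uniform(0.75, 0.90)
            span = int(round(cov * L))
            first = int(rng.integers(1, L - span + 1))
            refs[k] = dataclasses.replace(
                refs[k], model_first=first, model_last=first + span
            )
        window_len = fc.read_len // 3
        if window_len > L:
            raise ValueError("read window longer than the protein")
        ghost = _mutate_protein(ancestor, 0.40, rng)
        out[fam_name] = SynthFamily(
            config=fc,
            refs=tuple(refs),
            positive_anchors=tuple(r.id for r in refs
                                   if r.verified and r.gene_family != "decoy"),
            negative_anchors=tuple(r.id for r in refs
                                   if r.verified and r.gene_family == "decoy"),
            ghost_protein=ghost,
            window_start=(L - window_len) // 2,
            window_len=window_len,
        )
    return out


def _planted_fs_count(fc: FamilySynthConfig, rng: np.random.Generator) -> int:
    if fc.fs_exact is not None:
        return fc.fs_exact
    if fc.fs_mean <= 0:
        return 0
    pi, lam = solve_zero_inflated_poisson(fc.fs_mean, fc.fs_fraction)
    if rng.random() >= pi:
        return 0
    return int(rng.poisson(lam))


def _encode_read(protein_window: str, fc: FamilySynthConfig, n_fs: int,
                 rng: np.random.Generator) -> tuple[str, str, int]:
    dna = _reverse_translate(protein_window, rng)
    dna = _substitute(dna, fc.subst_rate, rng)
    dna, _ = plant_homopolymer_indels(dna, n_fs, rng)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        dna = dna.translate(comp)[::-1]
    return dna, strand, n_fs


def _qualities(n: int, rng: np.random.Generator) -> tuple[int, ...]:
    q = np.clip(np.rint(rng.normal(35, 2, size=n)), 20, 40).astype(int)
    return tuple(int(v) for v in q)


def make_reads(
    families: Mapping[str, SynthFamily], cfg: SynthConfig
) -> tuple[dict[str, list[AmpliconRead]], dict[str, TruthSet]]:
    """Generate per-family read sets over all samples, with truth labels.

    Returns {family: reads} and {family: TruthSet}; reads carry sample ids
    and constant-plus-noise quality strings.
    """
    reads_by_family: dict[str, list[AmpliconRead]] = {}
    truth_by_family: dict[str, TruthSet] = {}
    for fam_name in sorted(families):
        fam = families[fam_name]
        fc = fam.config
        rng = _family_rng(cfg, fam_name, "reads")
        truth = TruthSet()
        reads: list[AmpliconRead] = []
        targets = fam.target_ids
        ref_seq = {r.id: r.sequence for r in fam.refs}
        w0, wl = fam.window_start, fam.window_len
        for sample in cfg.sample_ids:
            comp = rng.dirichlet([cfg.dirichlet_alpha] * len(targets))
            truth.composition[sample] = dict(zip(targets, comp.tolist()))
            for r in range(cfg.n_reads_per_sample):
                rid = f"{fam_name}_{sample}_r{r:05d}"
                u = rng.random()
                if u < fc.qc_fail_fraction:
                    category = "qc_fail"
                else:
                    v = rng.random()
                    if v < fc.off_target_fraction:
                        category = "off_target"
                    elif v < fc.off_target_fraction + fc.novel_fraction:
                        category = "novel"
                    elif v < (fc.off_target_fraction + fc.novel_fraction
                              + fc.decoy_read_fraction):
                        category = "decoy"
                    else:
                        category = "target"
                source = None
                n_fs = 0
                strand = "+"
                if category == "off_target":
                    dna = "".join("ACGT"[i] for i in rng.integers(4, size=fc.read_len))
                elif category == "qc_fail":
                    src = targets[rng.choice(len(targets), p=comp)]
                    dna, strand, _ = _encode_read(ref_seq[src][w0:w0 + wl], fc, 0, rng)
                    if rng.random() < 0.5:
                        dna = dna[: int(rng.integers(50, 250))]  # too short
                    else:
                        pos = rng.choice(len(dna), size=3, replace=False)
                        dna = "".join("N" if i in set(int(p) for p in pos) else c
                                      for i, c in enumerate(dna))
                else:
                    if category == "target":
                        source = targets[rng.choice(len(targets), p=comp)]
                        window = ref_seq[source][w0:w0 + wl]
                    elif category == "novel":
                        window = fam.ghost_protein[w0:w0 + wl]
                    else:  # decoy
                        source = fam.decoy_ids[rng.integers(len(fam.decoy_ids))]
                        window = ref_seq[source][w0:w0 + wl]
                    n_fs = _planted_fs_count(fc, rng)
                    dna, strand, n_fs = _encode_read(window, fc, n_fs, rng)
                reads.append(AmpliconRead(rid, dna, sample, _qualities(len(dna), rng)))
                truth.reads[rid] = ReadTruth(category, sample, source, n_fs, strand)
        reads_by_family[fam_name] = reads
        truth_by_family[fam_name] = truth
    return reads_by_family, truth_by_family


# --- qPCR fixtures ---------------------------------------------------------

# Per-sample truth, percent of total community (five-copy basis).
DEFAULT_QPCR_PERCENT = {
    "but": {"H1": 4.4, "H2": 2.6, "H3": 74.1, "P200_v4": 5.0, "P206_v4": 0.3,
            "P207_v1": 0.0, "P210_v3": 15.5, "P210_v4": 26.0},
    "buk": {"H1": 0.5, "H2": 0.3, "H3": 1.0, "P200_v4": 8.0, "P206_v4": 19.9,
            "P207_v1": 0.0, "P210_v3": 1.0, "P210_v4": 2.0},
}


@dataclass(frozen=True)
class QpcrFixture:
    curve_points: dict[str, tuple[tuple[float, float], ...]]  # assay -> (log10c, Cq)
    measurements: tuple[QpcrMeasurement, ...]
    truth_copies: dict[tuple[str, str], float]  # (sample, assay) -> copies
    truth_percent: dict[tuple[str, str], float]  # functional assays only
    total_assay: str = "total_16S"


def make_qpcr(cfg: SynthConfig, percent_truth: Mapping[str, Mapping[str, float]] | None = None,
              cq_noise: float | None = None) -> QpcrFixture:
    """Standard-curve points and duplicate Cq tables with planted truth.

    Functional-gene targets are single copy per genome; truth copies are
    percent/100 * total-16S / 5.  A planted 0% sample lands below the
    10^2-copy detection limit (emitted at 50 copies).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(901,)))
    noise = cfg.qpcr_cq_noise if cq_noise is None else cq_noise
    percent_truth = percent_truth or DEFAULT_QPCR_PERCENT
    samples = sorted({s for fam in percent_truth.values() for s in fam})
    assays = {f"{fam}_qPCR": fam for fam in sorted(percent_truth)}
    curves: dict[str, tuple[tuple[float, float], ...]] = {}
    curve_params: dict[str, tuple[float, float]] = {}
    for assay, span in [(a, (2, 7)) for a in assays] + [("total_16S", (3, 8))]:
        eff = rng.uniform(0.92, 1.02)
        slope = -1.0 / np.log10(1.0 + eff)
        intercept = rng.uniform(36.0, 39.0)
        curve_params[assay] = (slope, intercept)
        pts = tuple(
            (float(lc), float(slope * lc + intercept + rng.normal(0, noise)))
            for lc in range(span[0], span[1] + 1)
        )
        curves[assay] = pts

    truth_copies: dict[tuple[str, str], float] = {}
    truth_percent: dict[tuple[str, str], float] = {}
    measurements: list[QpcrMeasurement] = []
    total_by_sample = {s: 10 ** rng.uniform(6.5, 7.5) for s in samples}
    for sample in samples:
        total = total_by_sample[sample]
        for assay, fam in assays.items():
            pct = percent_truth[fam].get(sample, 0.0)
            copies = pct / 100.0 * total / 5.0
            if copies < 100.0:
                copies = 50.0  # planted below-detection signal
            truth_copies[(sample, assay)] = copies
            truth_percent[(sample, assay)] = pct
            slope, intercept = curve_params[assay]
            cq = slope * np.log10(copies) + intercept
            measurements.append(QpcrMeasurement(
                sample, assay,
                tuple(float(cq + rng.normal(0, noise)) for _ in range(2)),
            ))
        truth_copies[(sample, "total_16S")] = total
        slope, intercept = curve_params["total_16S"]
        cq = slope * np.log10(total) + intercept
        measurements.append(QpcrMeasurement(
            sample, "total_16S",
            tuple(float(cq + rng.normal(0, noise)) for _ in range(2)),
        ))
    return QpcrFixture(curves, tuple(measurements), truth_copies, truth_percent)


# --- 16S taxon tables ------------------------------------------------------

DEFAULT_COPY_NUMBERS = {
    "Faecalibacterium": 6.0, "Roseburia": 6.0, "Eubacterium": 6.0,
    "Acidaminococcus": 4.0, "Coprococcus": 5.0, "Anaerostipes": 6.0,
    "Clostridium_butyricum": 10.0, "Clostridium_perfringens": 10.0,
    "Subdoligranulum": 5.0, "Bacteroides": 5.0, "Escherichia": 7.0,
    "Bifidobacterium": 4.0,
}

DEFAULT_CANDIDATES = {
    "Faecalibacterium": "but", "Roseburia": "but", "Eubacterium": "but",
    "Acidaminococcus": "but", "Anaerostipes": "but",
    "Clostridium_butyricum": "buk", "Clostridium_perfringens": "buk",
    "Subdoligranulum": "buk", "Coprococcus": "both",
}


@dataclass(frozen=True)
class TaxonFixture:
    counts: "object"  # pandas DataFrame, samples x taxa
    copy_numbers: dict[str, float]
    candidates: dict[str, str]
    truth_pathway_percent: "object"  # DataFrame samples x {but, buk}


def make_taxon_table(cfg: SynthConfig, depth: int = 50000) -> TaxonFixture:
    """16S count tables with planted genome-equivalent fractions."""
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(902,)))
    taxa = sorted(DEFAULT_COPY_NUMBERS)
    rows = {}
    for sample in cfg.sample_ids:
        ge = rng.dirichlet([0.8] * len(taxa))  # genome-equivalent fractions
        weights = ge * np.array([DEFAULT_COPY_NUMBERS[t] for t in taxa])
        counts = np.rint(depth * weights / weights.sum()).astype(int)
        rows[sample] = counts
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    counts.index.name = "sample"

    totals = counts.sum(axis=1).astype(float)
    truth = pd.DataFrame(0.0, index=counts.index, columns=["but", "buk"])
    for taxon, pw in DEFAULT_CANDIDATES.items():
        share = 100.0 * 5.0 * (counts[taxon] / DEFAULT_COPY_NUMBERS[taxon]) / totals
        if pw in ("but", "both"):
            truth["but"] += share
        if pw in ("buk", "both"):
            truth["buk"] += share
    return TaxonFixture(counts, dict(DEFAULT_COPY_NUMBERS),
                        dict(DEFAULT_CANDIDATES), truth)


# --- file emission ---------------------------------------------------------

def _phred(quals: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def write_fixtures(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit every fixture as plain-text files; byte-identical per seed."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    families = make_reference_families(cfg)
    reads, truth = make_reads(families, cfg)
    for fam_name, fam in sorted(families.items()):
        fasta = outdir / f"{fam_name}_refs.faa"
        with fasta.open("w") as fh:
            for r in fam.refs:
                fh.write(f">{r.id}\n{r.sequence}\n")
        meta = outdir / f"{fam_name}_refs_meta.tsv"
        pd.DataFrame([
            {"id": r.id, "model_first": r.model_first, "model_last": r.model_last,
             "model_length": r.model_length, "verified": r.verified,
             "taxon_label": r.taxon_label, "gene_family": r.gene_family}
            for r in fam.refs
        ]).to_csv(meta, sep="\t", index=False)
        fastq = outdir / f"{fam_name}_reads.fastq"
        with fastq.open("w") as fh:
            for rd in reads[fam_name]:
                fh.write(f"@{rd.id} sample={rd.sample_id}\n{rd.dna}\n+\n"
                         f"{_phred(rd.qualities)}\n")
        truth_path = outdir / f"{fam_name}_truth.json"
        truth_path.write_text(json.dumps(truth[fam_name].to_jsonable(), indent=0,
                                         sort_keys=True))
        paths.update({f"{fam_name}_refs": fasta, f"{fam_name}_meta": meta,
                      f"{fam_name}_reads": fastq, f"{fam_name}_truth": truth_path})

    qpcr = make_qpcr(cfg)
    curve_rows = [
        {"assay": assay, "log10_copies": lc, "cq": cq}
        for assay, pts in sorted(qpcr.curve_points.items()) for lc, cq in pts
    ]
    curves_path = outdir / "qpcr_curves.tsv"
    pd.DataFrame(curve_rows).to_csv(curves_path, sep="\t", index=False)
    cq_path = outdir / "qpcr_cq.tsv"
    pd.DataFrame([
        {"sample": m.sample, "assay": m.assay,
         "cq1": m.cq_replicates[0], "cq2": m.cq_replicates[1]}
        for m in qpcr.measurements
    ]).to_csv(cq_path, sep="\t", index=False)
    paths["qpcr_curves"] = curves_path
    paths["qpcr_cq"] = cq_path

    taxa = make_taxon_table(cfg)
    taxon_path = outdir / "taxon_counts.tsv"
    taxa.counts.to_csv(taxon_path, sep="\t")
    copies_path = outdir / "copy_numbers.tsv"
    pd.DataFrame(sorted(taxa.copy_numbers.items()),
                 columns=["taxon", "copies"]).to_csv(copies_path, sep="\t", index=False)
    cand_path = outdir / "candidates.tsv"
    pd.DataFrame(sorted(taxa.candidates.items()),
                 columns=["taxon", "pathway"]).to_csv(cand_path, sep="\t", index=False)
    paths.update({"taxon_counts": taxon_path, "copy_numbers": copies_path,
                  "candidates": cand_path})
    return paths
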