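"""Frameshift-aware DP, quality gates and per-read statistics."""

import numpy as np
import pytest

from _dp_oracle import oracle_score
from butyragene.framealign import (
    AmpliconRead,
    FilterThresholds,
    FrameAlignment,
    QCParams,
    ScoringParams,
    apply_filters,
    closest_match,
    exclude_outside_cluster,
    frame_align,
    frameshift_stats,
    quality_filter,
    reverse_complement,
    translate,
)
from butyragene.refdb import CuratedSet
from butyragene.synthfix import _reverse_translate
from conftest import random_protein


def encode(protein, seed=0):
    return _reverse_translate(protein, np.random.default_rng(seed))


class TestFrameAlign:
    def test_clean_encoding_is_perfect(self, rng):
        prot = random_protein(rng, 80)
        dna = encode(prot[10:70])
        a = frame_align(AmpliconRead("r", dna), prot)
        assert a.identity_pct == 100.0
        assert a.aligned_len_aa == 60
        assert a.frameshift_count == 0
        assert a.corrected_protein == prot[10:70]
        assert a.strand == "+"

    def test_single_deletion_corrected(self, rng):
        prot = random_protein(rng, 80)
        dna = encode(prot[10:70])
        dna = dna[:90] + dna[91:]  # delete 1 nt inside codon 30
        a = frame_align(AmpliconRead("r", dna), prot)
        assert a.frameshift_count == 1
        assert a.corrected_protein == prot[10:70]
        assert a.identity_pct == 100.0

    def test_single_insertion_corrected(self, rng):
        prot = random_protein(rng, 80)
        dna = encode(prot[10:70])
        dna = dna[:45] + "A" + dna[45:]
        a = frame_align(AmpliconRead("r", dna), prot)
        assert a.frameshift_count == 1
        assert a.corrected_protein == prot[10:70]

    def test_reverse_complement_symmetry(self, rng):
        prot = random_protein(rng, 60)
        dna = encode(prot[5:55])
        fwd = frame_align(AmpliconRead("r", dna), prot)
        rev = frame_align(AmpliconRead("r", reverse_complement(dna)), prot)
        assert rev.score == fwd.score
        assert rev.identity_pct == fwd.identity_pct
        assert rev.strand == "-"
        assert rev.corrected_protein == fwd.corrected_protein

    def test_all_n_read_has_no_alignment(self):
        a = frame_align(AmpliconRead("r", "N" * 60), "ACDEFGHIKLMNPQRSTVWY")
        assert a.score == 0.0
        assert not a.is_aligned

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            frame_align(AmpliconRead("r", "ATGGCTGCT"), "ACDEF")

    @pytest.mark.parametrize("seed", range(4))
    def test_score_matches_exhaustive_oracle(self, seed, rng):
        """DP optimum equals an independent memoised-recursion oracle."""
        local = np.random.default_rng(seed)
        for _ in range(20):
            m = int(local.integers(10, 21))
            prot = random_protein(local, m)
            if local.random() < 0.5:
                n = int(local.integers(3, 60))
                dna = "".join(local.choice(list("ACGT"), size=n))
            else:  # reads derived from the protein with an indel
                dna = encode(prot, seed=int(local.integers(1 << 30)))
                p = int(local.integers(1, len(dna)))
                dna = dna[:p] + dna[p + 1:] if local.random() < 0.5 else dna[:p] + "C" + dna[p:]
            got = frame_align(AmpliconRead("r", dna), prot).score
            expected = max(oracle_score(dna, prot),
                           oracle_score(reverse_complement(dna), prot))
            assert got == pytest.approx(expected, abs=1e-6)

    def test_zero_frameshift_reads_translate_cleanly(self, rng):
        for _ in range(5):
            prot = random_protein(rng, 40)
            dna = encode(prot, seed=int(rng.integers(1 << 30)))
            a = frame_align(AmpliconRead("r", dna), prot)
            assert a.frameshift_count == 0
            assert a.corrected_protein == translate(dna)


class TestClosestMatch:
    def test_recovers_source_against_decoys(self, rng):
        src = random_protein(rng, 120)
        refs = {"src": src}
        for i in range(3):
            decoy = list(src)
            idx = rng.choice(len(src), size=55, replace=False)
            for p in idx:
                decoy[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            refs[f"decoy{i}"] = "".join(decoy)
        hits = 0
        for k in range(25):
            dna = encode(src[10:110], seed=k)
            # ~5% substitutions
            dna = list(dna)
            for p in rng.choice(len(dna), size=15, replace=False):
                dna[p] = "ACGT"[rng.integers(4)]
            a = closest_match(AmpliconRead(f"r{k}", "".join(dna)), refs)
            hits += a.ref_id == "src"
        assert hits == 25

    def test_tie_break_prefers_smaller_id(self, rng):
        prot = random_protein(rng, 60)
        dna = encode(prot[5:55])
        a = closest_match(AmpliconRead("r", dna), {"zzz": prot, "aaa": prot})
        assert a.ref_id == "aaa"

    def test_unalignable_read_unassigned(self):
        a = closest_match(AmpliconRead("r", "N" * 50), {"x": "ACDEFGHIKLMNPQRSTVWY"})
        assert a.ref_id == "" and a.score == 0.0


def _aln(identity, length, ref="refA", read="r"):
    return FrameAlignment(read, ref, "+", 100.0, identity, length, 0, (), "X" * length)


class TestApplyFilters:
    @pytest.mark.parametrize(
        "identity,length,family,initial,downstream",
        [
            (29.0, 130, "buk", False, False),
            (30.0, 125, "buk", True, False),   # boundaries inclusive
            (65.0, 130, "buk", True, False),
            (70.0, 130, "buk", True, True),
            (75.0, 90, "but", False, False),   # below but length 100
            (75.0, 100, "but", True, True),
            (75.0, 124, "buk", False, False),  # below buk length 125
        ],
    )
    def test_gate_boundaries(self, identity, length, family, initial, downstream):
        out = apply_filters([_aln(identity, length)], family)
        assert (len(out.initial_pass) == 1) is initial
        assert (len(out.downstream_pass) == 1) is downstream

    def test_downstream_subset_of_initial(self, rng):
        alns = [_aln(float(rng.uniform(0, 100)), int(rng.integers(50, 200)))
                for _ in range(50)]
        out = apply_filters(alns, "buk")
        assert set(out.downstream_pass) <= set(out.initial_pass)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            apply_filters([], "xyz")


class TestFrameshiftStats:
    def test_arithmetic(self):
        alns = [FrameAlignment("r", "x", "+", 1.0, 90.0, 100, c, tuple(range(c)), "")
                for c in (0, 0, 1, 3)]
        st = frameshift_stats(alns)
        assert st.mean_frameshifts_per_read == pytest.approx(1.0)
        assert st.fraction_with_frameshift == pytest.approx(0.5)
        assert st.n_reads == 4

    def test_all_zero(self):
        alns = [FrameAlignment("r", "x", "+", 1.0, 90.0, 100, 0, (), "")] * 3
        st = frameshift_stats(alns)
        assert (st.mean_frameshifts_per_read, st.fraction_with_frameshift) == (0, 0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            frameshift_stats([])


class TestExcludeOutsideCluster:
    def test_drops_excluded_refs(self):
        curated = CuratedSet(kept=("a",), excluded=("z",))
        alns = [_aln(90, 120, ref="a"), _aln(90, 120, ref="z")]
        kept, dropped = exclude_outside_cluster(alns, curated)
        assert [a.ref_id for a in kept] == ["a"]
        assert dropped == pytest.approx(0.5)

    def test_identity_when_none_excluded(self):
        curated = CuratedSet(kept=("a",), excluded=())
        alns = [_aln(90, 120, ref="a")]
        kept, dropped = exclude_outside_cluster(alns, curated)
        assert kept == alns and dropped == 0.0


class TestQualityFilter:
    def test_reason_codes(self):
        reads = [
            AmpliconRead("ok", "ACGT" * 100, "s", (35,) * 400),
            AmpliconRead("short", "ACGT" * 50, "s", (35,) * 200),
            AmpliconRead("ambig", "N" + "ACGT" * 100, "s", (35,) * 401),
            AmpliconRead("lowq", "ACGT" * 100, "s", (10,) * 400),
        ]
        passing, reasons = quality_filter(reads, QCParams())
        assert [r.id for r in passing] == ["ok"]
        assert reasons == {"ok": "pass", "short": "short",
                           "ambig": "ambiguous", "lowq": "low_quality"}

    def test_no_qualities_skips_quality_check(self):
        reads = [AmpliconRead("r", "ACGT" * 100, "s")]
        passing, _ = quality_filter(reads, QCParams())
        assert len(passing) == 1

    def test_barcode_demultiplex_and_unknown(self):
        params = QCParams(min_length_nt=8, barcode_map={"AAAA": "s1"})
        reads = [AmpliconRead("a", "AAAA" + "ACGTACGT"),
                 AmpliconRead("b", "CCCC" + "ACGTACGT")]
        passing, reasons = quality_filter(reads, params)
        assert [r.sample_id for r in passing] == ["s1"]
        assert passing[0].dna == "ACGTACGT"  # barcode trimmed
        assert reasons["b"] == "unassigned"

    def test_primer_trimming_before_length_check(self):
        params = QCParams(min_length_nt=8, trim_primers=("ACGN",))
        reads = [AmpliconRead("a", "ACGT" + "AAAATTTT")]
        passing, _ = quality_filter(reads, params)
        assert passing[0].dna == "AAAATTTT"
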