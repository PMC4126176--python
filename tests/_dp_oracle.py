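"""Independent oracle for the frameshift-aware local alignment score.

A top-down memoised recursion over the same state machine (match /
frameshift / codon-insertion / residue-gap), written without arrays or
vectorisation so it shares no code with the production kernel.
"""

from functools import lru_cache

from butyragene.framealign import _AA_INDEX, _CODON_TO_AA, _SUB, ScoringParams

NEG = float("-inf")


def oracle_score(dna: str, protein: str, scoring: ScoringParams | None = None) -> float:
    scoring = scoring or ScoringParams()
    fs, open_, ext = scoring.frameshift, scoring.gap_open, scoring.gap_extend
    dna = dna.upper()
    protein = protein.upper()
    n, m = len(dna), len(protein)
    ref = [_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in protein]

    def sub_score(i: int, j: int) -> float:
        aa = _CODON_TO_AA.get(dna[i - 3 : i], "X")
        return float(_SUB[_AA_INDEX[aa], ref[j - 1]])

    @lru_cache(maxsize=None)
    def M(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0.0
        best = 0.0
        if i >= 3:
            best = max(best, C(i - 3, j - 1) + sub_score(i, j))
        for k in (1, 2, 4):
            if i >= k:
                best = max(best, C(i - k, j - 1) - fs)
        return best

    @lru_cache(maxsize=None)
    def Ix(i: int, j: int) -> float:
        if j == 0 or i < 3:
            return NEG
        return max(M(i - 3, j) - open_, Ix(i - 3, j) - ext)

    @lru_cache(maxsize=None)
    def Iy(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return NEG
        return max(M(i, j - 1) - open_, Iy(i, j - 1) - ext)

    def C(i: int, j: int) -> float:
        return max(M(i, j), Ix(i, j), Iy(i, j))

    return max(M(i, j) for i in range(n + 1) for j in range(m + 1))
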