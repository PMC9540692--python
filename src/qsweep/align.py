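"""Deterministic global pairwise alignment with affine gap penalties.

The CahR residue screen needs a reproducible mapping from reference
coordinates onto candidate domains.  This module implements the Gotoh
three-state dynamic program (Needleman-Wunsch with affine gaps) with a fixed,
documented tie-break so that the mapping is a pure function of the two
sequences and the scoring parameters:

* substitution scores come from BLOSUM62;
* a gap of length L costs ``gap_open + L * gap_extend`` (default 10 + L);
* at equal score the traceback prefers a substitution column over a gap
  column, and a gap in the candidate (reference residue unmatched) over a gap
  in the reference.

End gaps are penalised like internal gaps, i.e. the alignment is fully
global.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices

#: Residues with defined substitution scores (20 standard + ambiguity codes).
ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX"

GAP_OPEN = 10.0
GAP_EXTEND = 1.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_INDEX = {aa: _BLOSUM62.alphabet.index(aa) for aa in ALPHABET}

_NEG_INF = float("-inf")

# traceback states
_M, _IY, _IX = 0, 1, 2  # substitution, gap-in-candidate, gap-in-reference


def substitution_score(a: str, b: str) -> float:
    """BLOSUM62 score for aligning residue ``a`` with residue ``b``."""
    return float(_BLOSUM62[_INDEX[a], _INDEX[b]])


@dataclass(frozen=True)
class Alignment:
    """A global alignment as a list of columns.

    ``columns`` holds ``(i, j)`` pairs of 1-based indices into the candidate
    and reference respectively; ``None`` marks a gap on that side.
    """

    candidate: str
    reference: str
    columns: tuple[tuple[int | None, int | None], ...]
    score: float

    def reference_to_candidate(self) -> dict[int, int]:
        """Map of reference position -> candidate position (matched columns only)."""
        return {j: i for i, j in self.columns if i is not None and j is not None}

    def as_strings(self) -> tuple[str, str]:
        cand = "".join("-" if i is None else self.candidate[i - 1] for i, _ in self.columns)
        ref = "".join("-" if j is None else self.reference[j - 1] for _, j in self.columns)
        return cand, ref


def global_align(
    candidate: str,
    reference: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Alignment:
    """Optimal global alignment of ``candidate`` against ``reference``.

    Raises ``ValueError`` on empty sequences or residues outside the BLOSUM62
    alphabet (the 20 standard amino acids plus B/Z/X).
    """
    if not candidate or not reference:
        raise ValueError("cannot align empty sequences")
    for seq, label in ((candidate, "candidate"), (reference, "reference")):
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise ValueError(f"{label} contains non-amino-acid letters: {sorted(bad)}")

    n, m = len(candidate), len(reference)
    first = gap_open + gap_extend  # cost of the first residue of a gap

    a_idx = [_INDEX[c] for c in candidate]
    b_idx = [_INDEX[c] for c in reference]
    blosum = _BLOSUM62

    # DP matrices: M substitution, Iy gap in candidate (consumes reference),
    # Ix gap in reference (consumes candidate).  Rows indexed by candidate.
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Iy = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)

    for i in range(1, n + 1):
        Mi, Mp = M[i], M[i - 1]
        Iyi, Iyp = Iy[i], Iy[i - 1]
        Ixi, Ixp = Ix[i], Ix[i - 1]
        ai = a_idx[i - 1]
        row_scores = blosum[ai]
        for j in range(1, m + 1):
            diag = max(Mp[j - 1], Iyp[j - 1], Ixp[j - 1])
            Mi[j] = diag + row_scores[b_idx[j - 1]]
            # gap in candidate: consume reference residue j
            Iyi[j] = max(Mi[j - 1] - first, Iyi[j - 1] - gap_extend, Ixi[j - 1] - first)
            # gap in reference: consume candidate residue i
            Ixi[j] = max(Mp[j] - first, Iyp[j] - first, Ixp[j] - gap_extend)

    # Final state: prefer M, then Iy, then Ix at equal score.
    end_scores = (M[n][m], Iy[n][m], Ix[n][m])
    best = max(end_scores)
    state = end_scores.index(best)  # tuple order encodes the preference

    columns: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            columns.append((i, j))
            prev = (M[i - 1][j - 1], Iy[i - 1][j - 1], Ix[i - 1][j - 1])
            i, j = i - 1, j - 1
            state = prev.index(max(prev))
        elif state == _IY:
            columns.append((None, j))
            here = Iy[i][j]
            # which predecessor reproduces this score? preference M > Iy > Ix
            if i >= 0 and M[i][j - 1] - first == here:
                state = _M
            elif Iy[i][j - 1] - gap_extend == here:
                state = _IY
            else:
                state = _IX
            j -= 1
        else:  # _IX
            columns.append((i, None))
            here = Ix[i][j]
            if M[i - 1][j] - first == here:
                state = _M
            elif Iy[i - 1][j] - first == here:
                state = _IY
            else:
                state = _IX
            i -= 1

    columns.reverse()
    return Alignment(candidate=candidate, reference=reference, columns=tuple(columns), score=best)
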