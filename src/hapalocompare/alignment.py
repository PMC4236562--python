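"""Global pairwise alignment and percent identity.

Every homology statement in the cluster comparison rests on a percent
identity from an optimal global (Needleman-Wunsch) alignment with affine
gap penalties.  The dynamic programming itself is executed by Biopython's
``PairwiseAligner`` (C implementation); this module fixes the scoring
conventions, the deterministic choice among co-optimal alignments, and the
identity definition (identical residue pairs over *all* alignment columns,
gap columns included — the conservative denominator).

A small center-star progressive aligner is provided for multiple
alignments ("once a gap, always a gap" merging), sufficient for the 16S
and prenyltransferase alignment slices used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")
NUCLEOTIDE_ALPHABET = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: substitution model plus affine gap penalties.

    ``matrix`` names a substitution matrix (e.g. ``"BLOSUM62"``); when
    empty, ``match``/``mismatch`` scores apply.  A gap of length *k* costs
    ``gap_open + (k - 1) * gap_extend``.
    """

    matrix: str = ""
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError(
                f"require gap_open <= gap_extend <= 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )
        if self.alphabet not in {"protein", "nucleotide"}:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    @property
    def letters(self) -> set:
        return PROTEIN_ALPHABET if self.alphabet == "protein" else NUCLEOTIDE_ALPHABET


#: Default protein scheme: BLOSUM62 with gap open -10 / extend -1.
PROTEIN_SCHEME = ScoringScheme(matrix="BLOSUM62", gap_open=-10, gap_extend=-1,
                               alphabet="protein")
#: Default nucleotide scheme: +2/-3 with gap open -5 / extend -2.
NUCLEOTIDE_SCHEME = ScoringScheme(match=2, mismatch=-3, gap_open=-5,
                                  gap_extend=-2, alphabet="nucleotide")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with its score and identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@lru_cache(maxsize=None)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scheme.matrix:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    else:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _check_sequence(seq: str, scheme: ScoringScheme, name: str) -> str:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    seq = seq.upper()
    bad = set(seq) - scheme.letters
    if bad:
        raise ValueError(
            f"sequence {name} contains symbols outside the {scheme.alphabet} "
            f"alphabet: {sorted(bad)}"
        )
    return seq


def _columns_identity(aligned_a: str, aligned_b: str) -> float:
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != GAP
    )
    return 100.0 * matches / len(aligned_a)


def needleman_wunsch(
    a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gap costs.

    Among co-optimal alignments the first of the aligner's deterministic
    enumeration is returned, so repeated calls give identical output.
    """
    a = _check_sequence(a, scheme, "a")
    b = _check_sequence(b, scheme, "b")
    alignments = _aligner(scheme).align(a, b)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best.score),
        identity_pct=round(_columns_identity(aligned_a, aligned_b), 1),
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """Percent identity over all alignment columns, to 1 decimal.

    Identical aligned residue pairs divided by the total number of
    columns (gap columns count in the denominator).
    """
    if len(aln.aligned_a) == 0:
        raise ValueError("zero-length alignment")
    return round(_columns_identity(aln.aligned_a, aln.aligned_b), 1)


def identity(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``."""
    return needleman_wunsch(a, b, scheme).identity_pct


def _merge_into_msa(rows: list[str], new_center: str, new_seq: str) -> list[str]:
    # Merge a (center, seq) pairwise alignment into the running MSA whose
    # first row is the (gapped) center: once a gap, always a gap.
    master = rows[0]
    out_rows = [[] for _ in rows]
    out_new: list[str] = []
    i = j = 0
    while i < len(master) or j < len(new_center):
        take_master = i < len(master)
        take_pair = j < len(new_center)
        if take_master and master[i] == GAP:
            for k, row in enumerate(rows):
                out_rows[k].append(row[i])
            out_new.append(GAP)
            i += 1
        elif take_pair and new_center[j] == GAP:
            for k in range(len(rows)):
                out_rows[k].append(GAP)
            out_new.append(new_seq[j])
            j += 1
        elif take_master and take_pair:
            for k, row in enumerate(rows):
                out_rows[k].append(row[i])
            out_new.append(new_seq[j])
            i += 1
            j += 1
        else:  # pragma: no cover - exhausted side always a gap run
            raise AssertionError("center residues out of sync during merge")
    return ["".join(r) for r in out_rows] + ["".join(out_new)]


def center_star_msa(
    seqs: list[str], scheme: ScoringScheme = PROTEIN_SCHEME
) -> list[str]:
    """Center-star multiple alignment.

    The center is the sequence maximizing summed pairwise identity to all
    others (ties to the lowest index); every other sequence is aligned to
    the center and merged by the "once a gap, always a gap" rule.  Rows
    are returned in the input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for an MSA")
    seqs = [_check_sequence(s, scheme, f"seqs[{i}]") for i, s in enumerate(seqs)]
    n = len(seqs)
    total = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            pid = identity(seqs[i], seqs[j], scheme)
            total[i] += pid
            total[j] += pid
    center = max(range(n), key=lambda i: (total[i], -i))
    rows = [seqs[center]]
    order = [center]
    for i in range(n):
        if i == center:
            continue
        aln = needleman_wunsch(seqs[center], seqs[i], scheme)
        rows = _merge_into_msa(rows, aln.aligned_a, aln.aligned_b)
        order.append(i)
    # restore input order
    by_input = [""] * n
    for pos, idx in enumerate(order):
        by_input[idx] = rows[pos]
    return by_input
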