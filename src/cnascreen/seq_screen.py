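"""Sequence-level candidate screening.

Candidate domains for new tag/catcher systems are required to be
mutually divergent — below 30% pairwise sequence identity to each other
and to the template of the original system — so that the resulting
tag/catcher pairs are orthogonal.  This module provides the identity
screen (global Needleman-Wunsch alignment, percent identical columns)
and average molecular-mass computation used for construct sanity checks
against gel-estimated sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.SeqUtils import molecular_weight

__all__ = [
    "IdentityParams",
    "IdentityMatrix",
    "pairwise_identity",
    "screen_candidates",
    "compute_mass",
    "DEFAULT_IDENTITY_THRESHOLD",
]

DEFAULT_IDENTITY_THRESHOLD = 30.0  # percent

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class IdentityParams:
    """Alignment settings for the identity screen.

    Identity is 100 x (identical columns) / denominator, where the
    denominator is either the full alignment length excluding terminal
    gap overhangs (default) or the length of the shorter sequence.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_denominator: str = "alignment_length"  # or "shorter_sequence"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.identity_denominator not in ("alignment_length", "shorter_sequence"):
            raise ValueError(f"unknown denominator {self.identity_denominator!r}")

    def describe(self) -> str:
        return (f"global NW, {self.matrix}, open {self.gap_open}, "
                f"extend {self.gap_extend}, denominator {self.identity_denominator}")


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # percent, symmetric, diagonal 100
    params: IdentityParams = field(default_factory=IdentityParams)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append("\t".join([lab] + [f"{v:.1f}" for v in self.values[i]]))
        lines.append(f"# identity method: {self.params.describe()}")
        return "\n".join(lines) + "\n"


def _make_aligner(params: IdentityParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _AA - {"X"}
    if bad:
        raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
    return seq


def pairwise_identity(a: str, b: str,
                      params: IdentityParams = IdentityParams()) -> float:
    """Percent identity of two sequences under a global alignment."""
    a, b = _check_sequence(a), _check_sequence(b)
    # Symmetry: the optimal alignment picked among co-optimal ones can
    # depend on argument order; canonicalize.
    if b < a:
        a, b = b, a
    aln = _make_aligner(params).align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    identical = sum(1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-")
    if params.identity_denominator == "shorter_sequence":
        denom = min(len(a), len(b))
    else:
        denom = end - start
    if denom == 0:
        return 0.0
    return 100.0 * identical / denom


def screen_candidates(seqs: dict[str, str], threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                      params: IdentityParams = IdentityParams()
                      ) -> tuple[IdentityMatrix, dict[tuple[str, str], bool]]:
    """All-against-all identity matrix plus a pass/fail verdict per pair.

    A pair passes the divergence screen iff its identity is strictly
    below ``threshold`` percent.
    """
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least two sequences to screen")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(labels)
    values = np.full((n, n), 100.0)
    verdicts: dict[tuple[str, str], bool] = {}
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(seqs[labels[i]], seqs[labels[j]], params)
            values[i, j] = values[j, i] = ident
            verdicts[(labels[i], labels[j])] = ident < threshold
    return IdentityMatrix(labels=labels, values=values, params=params), verdicts


def compute_mass(seq: str) -> float:
    """Average molecular mass of a peptide in Da (residue masses + one water).

    Average, not monoisotopic, masses are used so values compare with
    gel-estimated "approx. kDa" figures.
    """
    seq = _check_sequence(seq)
    if "X" in seq:
        raise ValueError("cannot compute mass of sequence with unknown residue 'X'")
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))
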