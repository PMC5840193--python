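"""Somatic mutation counting against germline V-gene sequences.

An antibody is called *mature* when its heavy or light variable-region
sequence differs from the assigned germline V-gene by at least one amino
acid; with zero mutations in both chains it is *naive*.  Mutations are the
mismatched residue pairs of a local alignment under the BLOSUM50 matrix
with affine gap penalties (open 10, extend 1); gap columns are not counted
as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["GermlineAssignment", "count_mutations", "classify_maturity"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM50")
    al.mode = "local"
    al.open_gap_score = -10.0
    al.extend_gap_score = -1.0
    return al


@dataclass(frozen=True)
class GermlineAssignment:
    chain: str  # "H" or "L"
    query_seq: str
    germline_seq: str
    mismatches: int
    aligned_length: int

    def __post_init__(self) -> None:
        if self.mismatches > self.aligned_length:
            raise ValueError("mismatches cannot exceed the aligned length")


def count_mutations(query: str, germline: str, chain: str = "H") -> GermlineAssignment:
    """Count amino-acid differences between a sequence and its germline.

    Performs a local BLOSUM50 alignment and counts aligned position pairs
    with differing residues; gapped columns (insertions/deletions) do not
    count.  Ties between equally optimal alignments are resolved by taking
    the aligner's first reported alignment, which cannot change the score
    and in practice not the mismatch count either.
    """
    query = query.strip().upper()
    germline = germline.strip().upper()
    if not query or not germline:
        raise ValueError("sequences must be non-empty")
    for name, seq in (("query", query), ("germline", germline)):
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    aln = _aligner().align(query, germline)[0]
    mismatches = 0
    aligned = 0
    for (q0, q1), (g0, g1) in zip(*aln.aligned):
        aligned += q1 - q0
        for qc, gc in zip(query[q0:q1], germline[g0:g1]):
            if qc != gc:
                mismatches += 1
    return GermlineAssignment(
        chain=chain,
        query_seq=query,
        germline_seq=germline,
        mismatches=mismatches,
        aligned_length=aligned,
    )


def classify_maturity(heavy: GermlineAssignment | None, light: GermlineAssignment | None) -> str:
    """``"mature"`` iff the chains carry at least one V-gene mutation.

    Either assignment may be None (sequence unavailable); with both missing
    the label is ``"unknown"``.
    """
    if heavy is None and light is None:
        return "unknown"
    total = (heavy.mismatches if heavy else 0) + (light.mismatches if light else 0)
    return "mature" if total >= 1 else "naive"
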