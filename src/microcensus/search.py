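"""Top-hit search against a cultured 16S reference database.

For each query the single most similar cultured reference is found and the
percent identity, alignment length (columns, gaps included) and query
coverage of the optimal local alignment are reported — the same quantities a
BLASTn top hit supplies.

Candidates are pre-ranked by shared k-mer count (a word-based prefilter in
the spirit of BLAST seeding) and the top ``prefilter_top_m`` are aligned
with an affine-gap Smith–Waterman (Biopython's ``PairwiseAligner``).
Queries sharing no k-mer with any reference are reported as no-hit.

Scoring convention: match +2, mismatch -3, and a gap of length k costs
``gap_open + k * gap_extend`` (default 5 + 2k) — megablast-like defaults.
``N`` never matches anything, including another ``N``. Percent identity is
100 x identical columns / alignment columns, where the denominator counts
substitution and gap columns alike (standard BLAST identity reporting).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DataError, ParameterError, UsageError

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and prefilter parameters for the top-hit search."""

    match_score: int = 2
    mismatch_penalty: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    kmer_size: int = 12
    prefilter_top_m: int = 50

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ParameterError("match_score must be positive")
        if min(self.mismatch_penalty, self.gap_open, self.gap_extend) < 0:
            raise ParameterError("penalties must be >= 0")
        if not (8 <= self.kmer_size <= 16):
            raise ParameterError("kmer_size must be in [8, 16]")
        if self.prefilter_top_m < 1:
            raise ParameterError("prefilter_top_m must be >= 1")


@dataclass(frozen=True)
class PairwiseResult:
    """Optimal local alignment summary for one query/subject pair."""

    score: float
    identity: float
    alignment_length: int
    query_alignment_length: int


@dataclass(frozen=True)
class HitResult:
    """Top cultured hit of one query; numeric fields are None for no-hit."""

    query_id: str
    subject_id: str | None = None
    percent_identity: float | None = None
    alignment_length: int | None = None
    query_alignment_length: int | None = None
    score: float | None = None
    no_hit: bool = False


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            matched = x == y and x != "N"
            matrix[x, y] = params.match_score if matched else -params.mismatch_penalty
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # first gap column costs open+extend, each further column extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ParameterError(f"{name} sequence is empty")
    invalid = set(seq) - set(_ALPHABET)
    if invalid:
        raise DataError(f"{name} sequence has non-IUPAC characters: {sorted(invalid)}")


def align_pair(query: str, subject: str, params: AlignmentParams | None = None) -> PairwiseResult:
    """Optimal local alignment of two sequences.

    Returns score, percent identity (gap columns in the denominator), total
    alignment columns, and the number of query bases the alignment spans.
    """
    params = params or AlignmentParams()
    _check_sequence(query, "query")
    _check_sequence(subject, "subject")
    aligner = _aligner(params)
    alignment = aligner.align(query, subject)[0]
    return _summarize(alignment)


def _summarize(alignment) -> PairwiseResult:
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    qranges = alignment.aligned[0]
    qspan = int(qranges[-1][-1] - qranges[0][0]) if len(qranges) else 0
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return PairwiseResult(
        score=float(alignment.score),
        identity=identity,
        alignment_length=int(columns),
        query_alignment_length=qspan,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class ReferenceIndex:
    """K-mer-prefiltered top-hit search against one reference database.

    Build once per database; ``best_hit`` then ranks references by shared
    k-mer count, aligns the top ``prefilter_top_m``, and returns the hit
    with maximal score. Ties are broken by higher identity, then by
    lexicographically smallest subject id.
    """

    def __init__(self, references: Mapping[str, str] | Iterable, params: AlignmentParams | None = None):
        self.params = params or AlignmentParams()
        if hasattr(references, "sequences"):  # ReferenceSet
            references = references.sequences()
        self.sequences: dict[str, str] = dict(references)
        if not self.sequences:
            raise DataError("reference set is empty")
        for rid, seq in self.sequences.items():
            _check_sequence(seq, f"reference {rid}")
        k = self.params.kmer_size
        self._kmers = {rid: _kmer_set(seq, k) for rid, seq in self.sequences.items()}
        self._aligner = _aligner(self.params)

    def candidates(self, query: str) -> list[tuple[str, int]]:
        """(reference id, shared k-mer count), best first, zero-sharers dropped."""
        qset = _kmer_set(query, self.params.kmer_size)
        shared = [
            (rid, len(qset & kset))
            for rid, kset in self._kmers.items()
        ]
        shared = [(rid, c) for rid, c in shared if c > 0]
        shared.sort(key=lambda t: (-t[1], t[0]))
        return shared[: self.params.prefilter_top_m]

    def best_hit(self, query_id: str, query: str) -> HitResult:
        _check_sequence(query, f"query {query_id}")
        candidates = self.candidates(query)
        if not candidates:
            return HitResult(query_id=query_id, no_hit=True)
        scores = {
            rid: float(self._aligner.score(query, self.sequences[rid]))
            for rid, _ in candidates
        }
        best_score = max(scores.values())
        tied = sorted(rid for rid, sc in scores.items() if sc == best_score)
        if len(tied) == 1:
            best_id = tied[0]
            result = _summarize(self._aligner.align(query, self.sequences[best_id])[0])
        else:
            summaries = {
                rid: _summarize(self._aligner.align(query, self.sequences[rid])[0])
                for rid in tied
            }
            best_id = min(tied, key=lambda rid: (-summaries[rid].identity, rid))
            result = summaries[best_id]
        return HitResult(
            query_id=query_id,
            subject_id=best_id,
            percent_identity=result.identity,
            alignment_length=result.alignment_length,
            query_alignment_length=result.query_alignment_length,
            score=result.score,
        )


def best_cultured_hit(query_id: str, query: str, references, params: AlignmentParams | None = None) -> HitResult:
    """Single-query convenience wrapper around :class:`ReferenceIndex`."""
    return ReferenceIndex(references, params).best_hit(query_id, query)


HITS_COLUMNS = ["query_id", "subject_id", "pident", "length", "qlen_aligned", "score", "no_hit"]


def search_all(queries: Mapping[str, str], references, params: AlignmentParams | None = None) -> pd.DataFrame:
    """Top-hit search for a batch of queries.

    Returns a hits table whose columns mirror BLAST outfmt-6 meanings
    (query_id, subject_id, pident, length, qlen_aligned, score) plus a
    ``no_hit`` flag; numeric fields are NaN for no-hit rows.
    """
    index = ReferenceIndex(references, params)
    rows = []
    for qid, seq in queries.items():
        hit = index.best_hit(qid, seq)
        rows.append((
            hit.query_id,
            hit.subject_id if not hit.no_hit else "",
            hit.percent_identity if not hit.no_hit else np.nan,
            hit.alignment_length if not hit.no_hit else np.nan,
            hit.query_alignment_length if not hit.no_hit else np.nan,
            hit.score if not hit.no_hit else np.nan,
            hit.no_hit,
        ))
    return pd.DataFrame(rows, columns=HITS_COLUMNS)


def query_alignment_fraction(hit: HitResult, query_length: int) -> float:
    """Fraction of the query spanned by its top-hit alignment, in (0, 1]."""
    if hit.no_hit:
        raise UsageError("query_alignment_fraction is undefined for no-hit results")
    if query_length <= 0:
        raise ParameterError("query_length must be positive")
    return hit.query_alignment_length / query_length
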