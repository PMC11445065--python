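"""Locate reference regulator genes in genomes by exact local alignment.

Replaces a blastn homology search with an exact affine-gap Smith–Waterman
(via Biopython's ``PairwiseAligner``) and a score floor in place of an
E-value: the floor defaults to 60% of the perfect-match score of the query.
Both strands are scanned; only the optimal local alignment per strand is
reported, since downstream analysis consumes the single best hit per
(genome, gene) and excises it with 75 nt of flanking sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .simulate import revcomp

_ALPHABET = "ACGTN"
_VALID = set(_ALPHABET)


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap nucleotide scoring.  A gap of length L scores
    ``gap_open + (L-1) * gap_extend``.  N never scores as a match."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_report_score: float | None = None  # default: 0.6 * match * |query|
    max_hits: int = 100

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")

    def floor(self, query_length: int) -> float:
        if self.min_report_score is not None:
            return self.min_report_score
        return 0.6 * self.match * query_length


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            # N is ambiguous: conservatively a mismatch against everything
            m[a, b] = match if (a == b and a != "N") else mismatch
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = m
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


@dataclass
class HomologyHit:
    genome_id: str
    contig_id: str
    sstart: int  # 0-based half-open, forward strand of subject
    send: int
    strand: str
    score: float
    identity: float
    qstart: int
    qend: int

    @property
    def hit_length(self) -> int:
        return self.send - self.sstart


@dataclass
class FlankedRegion:
    """Excised hit plus flanking sequence, in gene-sense orientation."""

    sequence: str
    window_start: int
    window_end: int
    hit_offset: int
    hit_length: int
    left_flank: int
    right_flank: int
    genome_id: str = ""
    contig_id: str = ""
    strand: str = "+"


def _check_alphabet(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label} contains invalid symbol(s): {sorted(bad)!r}")


def align_local(
    query: str,
    subject: str,
    scoring: AlignmentScoring = AlignmentScoring(),
    genome_id: str = "",
    contig_id: str = "",
) -> list[HomologyHit]:
    """Optimal local alignment of ``query`` against both strands of
    ``subject``; hits sorted by score descending, floored at
    ``scoring.floor(len(query))``, at most ``scoring.max_hits`` returned."""
    query, subject = query.upper(), subject.upper()
    _check_alphabet(query, "query")
    _check_alphabet(subject, "subject")
    al = _aligner(scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    floor = scoring.floor(len(query))
    hits: list[HomologyHit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        # score-only pass is ~2.5x cheaper than a full traceback; only
        # strands clearing the floor pay for the alignment
        score = al.score(subject, q)
        if score < floor or score <= 0:
            continue
        aln = al.align(subject, q)[0]
        score = aln.score
        coords = aln.coordinates
        sstart, send = int(coords[0][0]), int(coords[0][-1])
        q0, q1 = int(coords[1][0]), int(coords[1][-1])
        if strand == "-":
            qstart, qend = len(query) - q1, len(query) - q0
        else:
            qstart, qend = q0, q1
        counts = aln.counts()
        ncols = counts.gaps + counts.identities + counts.mismatches
        identity = counts.identities / ncols if ncols else 0.0
        hits.append(
            HomologyHit(
                genome_id=genome_id,
                contig_id=contig_id,
                sstart=sstart,
                send=send,
                strand=strand,
                score=float(score),
                identity=identity,
                qstart=qstart,
                qend=qend,
            )
        )
    hits.sort(key=_tiebreak_key)
    return hits[: scoring.max_hits]


def _tiebreak_key(h: HomologyHit):
    return (-h.score, h.sstart, 0 if h.strand == "+" else 1, h.contig_id)


def best_hit(hits: list[HomologyHit]) -> HomologyHit | None:
    """Highest-scoring hit; ties broken by smaller sstart, then + strand,
    then lexicographic contig id.  None for an empty list."""
    if not hits:
        return None
    return min(hits, key=_tiebreak_key)


def extract_flanked_region(
    contig: str, hit: HomologyHit, flank: int = 75
) -> FlankedRegion:
    """Cut out the hit plus up to ``flank`` nt on either end (clipped at the
    contig edges).  Minus-strand hits are reverse-complemented so the gene
    reads 5'->3'; flank sizes are recorded in gene-sense orientation."""
    if not (0 <= hit.sstart < hit.send <= len(contig)):
        raise ValueError(
            f"hit [{hit.sstart},{hit.send}) outside contig of length {len(contig)}"
        )
    ws = max(0, hit.sstart - flank)
    we = min(len(contig), hit.send + flank)
    window = contig[ws:we].upper()
    if hit.strand == "+":
        seq = window
        left, right = hit.sstart - ws, we - hit.send
    else:
        seq = revcomp(window)
        left, right = we - hit.send, hit.sstart - ws
    return FlankedRegion(
        sequence=seq,
        window_start=ws,
        window_end=we,
        hit_offset=left,
        hit_length=hit.hit_length,
        left_flank=left,
        right_flank=right,
        genome_id=hit.genome_id,
        contig_id=hit.contig_id,
        strand=hit.strand,
    )


def hits_table(hits: list[HomologyHit]):
    """Blast-tabular-style hits table (qseqid left to the caller)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                sseqid=h.contig_id,
                genome_id=h.genome_id,
                pident=round(100 * h.identity, 3),
                length=h.hit_length,
                sstart=h.sstart,
                send=h.send,
                strand=h.strand,
                score=h.score,
                qstart=h.qstart,
                qend=h.qend,
            )
            for h in hits
        ]
    )
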