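"""Start-codon calling with a trainable start + ribosome-binding-site model.

Given a flanked homology region, this module enumerates every in-frame
ATG/GTG/TTG candidate start sharing the gene's stop codon, scores each with
log-odds terms for (a) the start codon identity and (b) the best
Shine–Dalgarno-like k-mer upstream at a binned spacer distance, and resolves
ambiguous loci with three rules before fractional counting:

1. a candidate's ORF must span at least 90% of the best-hit length
   (shorter, fragmented products are assumed non-functional);
2. its score must lie within 80% of the best surviving candidate's score;
3. if the top candidate has a predicted RBS, alternatives without one are
   dropped.

Each of the k retained candidates then contributes 1/k to its codon class —
e.g. retained {ATG, GTG, GTG} counts as 2/3 GTG and 1/3 ATG, reported as
0.66/0.33 under two-decimal truncation.  Exact fractions are kept in machine
output.

The model is a deliberately simple, fully specified stand-in for a
Prodigal-style start scorer: it is trained on one annotated genome and its
scores are not numerically comparable to Prodigal's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction

from .homology import (
    AlignmentScoring,
    FlankedRegion,
    align_local,
    best_hit,
    extract_flanked_region,
)
from .simulate import START_CODONS, STOP_CODONS, read_fasta, read_gff3_genes, revcomp

CODON_CLASSES = ("ATG", "GTG", "TTG", "other")

#: spacer bins (nt between SD 3' end and start codon), half-open
DEFAULT_SPACER_BINS = ((3, 5), (5, 7), (7, 9), (9, 11), (11, 13), (13, 16))

#: SD-like k-mer vocabulary: all 3..6-mers of the extended anti-anti-SD
#: consensus AAGGAGGTGA
_SD_CONSENSUS = "AAGGAGGTGA"
SD_VOCABULARY = tuple(
    sorted(
        {
            _SD_CONSENSUS[i : i + k]
            for k in range(3, 7)
            for i in range(len(_SD_CONSENSUS) - k + 1)
        }
    )
)


class NoStopError(ValueError):
    """The flanked region contains no in-frame stop downstream of the hit."""


class TrainingError(ValueError):
    pass


@dataclass
class StartModel:
    """Log-odds start-site scorer.

    ``start_weights[c]`` is log(smoothed frequency of start codon c at
    annotated starts / uniform 1/3).  ``rbs_table[(kmer, bin_index)]`` is
    log(P(k-mer present with its 3' end at a spacer in the bin | true start)
    / P(present by chance in background)).  A candidate with no vocabulary
    k-mer upstream scores ``no_motif_score`` (a fixed penalty below the
    presence threshold, so such candidates never count as having an RBS).
    """

    start_weights: dict[str, float]
    rbs_table: dict[tuple[str, int], float]
    spacer_bins: tuple[tuple[int, int], ...] = DEFAULT_SPACER_BINS
    rbs_present_threshold: float = 0.0
    background: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in "ACGT"}
    )
    no_motif_score: float = -2.0
    trained_on: str = ""

    @property
    def max_upstream(self) -> int:
        return max(hi for _, hi in self.spacer_bins) - 1 + 6

    def rbs_score(self, upstream: str) -> tuple[float, str | None, int | None]:
        """Best (score, k-mer, spacer) over all vocabulary k-mer occurrences
        in ``upstream`` (the sequence ending immediately before the start)."""
        best = (self.no_motif_score, None, None)
        U = len(upstream)
        for kmer in SD_VOCABULARY:
            k = len(kmer)
            pos = upstream.find(kmer)
            while pos != -1:
                spacer = U - (pos + k)
                bi = self._bin_index(spacer)
                if bi is not None:
                    s = self.rbs_table.get((kmer, bi))
                    if s is not None and s > best[0]:
                        best = (s, kmer, spacer)
                pos = upstream.find(kmer, pos + 1)
        return best

    def _bin_index(self, spacer: int) -> int | None:
        for i, (lo, hi) in enumerate(self.spacer_bins):
            if lo <= spacer < hi:
                return i
        return None

    # -- serialization (versioned JSON) --
    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "altstart-start-model/1",
                "start_weights": self.start_weights,
                "rbs_table": [
                    [k, b, v] for (k, b), v in sorted(self.rbs_table.items())
                ],
                "spacer_bins": [list(b) for b in self.spacer_bins],
                "rbs_present_threshold": self.rbs_present_threshold,
                "background": self.background,
                "no_motif_score": self.no_motif_score,
                "trained_on": self.trained_on,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StartModel":
        d = json.loads(text)
        if d.get("format") != "altstart-start-model/1":
            raise ValueError("unrecognized model format")
        return cls(
            start_weights=d["start_weights"],
            rbs_table={(k, int(b)): float(v) for k, b, v in d["rbs_table"]},
            spacer_bins=tuple(tuple(b) for b in d["spacer_bins"]),
            rbs_present_threshold=d["rbs_present_threshold"],
            background=d["background"],
            no_motif_score=d["no_motif_score"],
            trained_on=d["trained_on"],
        )


@dataclass
class StartCandidate:
    pos: int  # 0-based offset within the flanked region
    codon: str
    frame_anchor: int
    stop_pos: int
    orf_length: int
    rbs_score: float = 0.0
    rbs_present: bool = False
    rbs_motif: str | None = None
    rbs_spacer: int | None = None
    start_score: float = 0.0
    total_score: float = 0.0
    truncated_context: bool = False


@dataclass
class StartCall:
    genome_id: str
    gene: str
    retained: list[StartCandidate]
    weights: dict[str, Fraction]
    flags: tuple[str, ...] = ()

    def display_weights(self) -> dict[str, float]:
        """Fractions truncated (not rounded) to two decimals, matching the
        human-readable reporting convention (2/3 -> 0.66, 1/3 -> 0.33)."""
        return {c: truncate2(w) for c, w in self.weights.items()}


def truncate2(x: Fraction | float) -> float:
    f = Fraction(x) if not isinstance(x, Fraction) else x
    return (f.numerator * 100 // f.denominator) / 100


def _zero_weights() -> dict[str, Fraction]:
    return {c: Fraction(0) for c in CODON_CLASSES}


# ---------------------------------------------------------------------------
# training

def train_start_model(
    genome: dict[str, str] | str,
    annotation,
    spacer_bins=DEFAULT_SPACER_BINS,
    rbs_present_threshold: float = 0.0,
    min_genes: int = 50,
) -> StartModel:
    """Train the start + RBS model from one annotated genome.

    ``genome`` is a contig dict (or FASTA path) and ``annotation`` a gene
    table (or GFF3 path) with 0-based half-open ``start``/``end`` and strand.
    Genes need at least 16 nt of upstream context to be usable; fewer than
    ``min_genes`` usable genes is an error.
    """
    if isinstance(genome, str):
        genome = read_fasta(genome)
    if isinstance(annotation, str):
        annotation = read_gff3_genes(annotation)

    max_up = max(hi for _, hi in spacer_bins) - 1 + 6
    starts: list[str] = []
    upstreams: list[str] = []
    for r in annotation.itertuples():
        contig = genome.get(r.contig_id)
        if contig is None:
            continue
        if r.strand == "+":
            codon = contig[r.start : r.start + 3]
            up = contig[max(0, r.start - max_up) : r.start]
        else:
            codon = revcomp(contig[r.end - 3 : r.end])
            up = revcomp(contig[r.end : r.end + max_up])
        if len(up) < 16 or codon not in START_CODONS:
            continue
        starts.append(codon)
        upstreams.append(up)
    n = len(starts)
    if n < min_genes:
        raise TrainingError(
            f"only {n} usable annotated genes (need >= {min_genes}); "
            "provide a larger training set"
        )

    counts = {c: starts.count(c) for c in START_CODONS}
    start_weights = {
        c: math.log(((counts[c] + 1) / (n + 3)) / (1 / 3)) for c in START_CODONS
    }

    all_bases = "".join(genome.values())
    background = {
        b: max(1e-6, all_bases.count(b) / max(1, len(all_bases))) for b in "ACGT"
    }

    present_counts = {(k, i): 0 for k in SD_VOCABULARY for i in range(len(spacer_bins))}
    for up in upstreams:
        U = len(up)
        seen = set()
        for kmer in SD_VOCABULARY:
            k = len(kmer)
            pos = up.find(kmer)
            while pos != -1:
                spacer = U - (pos + k)
                for i, (lo, hi) in enumerate(spacer_bins):
                    if lo <= spacer < hi:
                        seen.add((kmer, i))
                pos = up.find(kmer, pos + 1)
        for key in seen:
            present_counts[key] += 1

    rbs_table = {}
    for (kmer, i), c in present_counts.items():
        lo, hi = spacer_bins[i]
        width = hi - lo
        p_kmer = 1.0
        for b in kmer:
            p_kmer *= background[b]
        p_bg = max(1e-9, 1.0 - (1.0 - p_kmer) ** width)
        p_obs = (c + 1) / (n + 2)
        rbs_table[(kmer, i)] = math.log(p_obs / p_bg)

    return StartModel(
        start_weights=start_weights,
        rbs_table=rbs_table,
        spacer_bins=tuple(tuple(b) for b in spacer_bins),
        rbs_present_threshold=rbs_present_threshold,
        background=background,
        trained_on="|".join(sorted(genome)),
    )


# ---------------------------------------------------------------------------
# candidate enumeration and scoring

def enumerate_candidates(region: FlankedRegion) -> list[StartCandidate]:
    """All in-frame ATG/GTG/TTG candidates in the frame of the homology hit,
    downstream of any upstream in-frame stop and closed by the shared stop."""
    seq = region.sequence
    frame = region.hit_offset % 3
    # shared stop: first in-frame stop at or after the hit start
    stop_pos = None
    for q in range(region.hit_offset, len(seq) - 2, 3):
        if seq[q : q + 3] in STOP_CODONS:
            stop_pos = q
            break
    if stop_pos is None:
        raise NoStopError(
            "no in-frame stop codon downstream of the hit within the region"
        )
    lower = frame
    for q in range(frame, stop_pos, 3):
        if seq[q : q + 3] in STOP_CODONS:
            lower = q + 3
    out = []
    for q in range(lower, stop_pos, 3):
        tri = seq[q : q + 3]
        if tri in START_CODONS:
            out.append(
                StartCandidate(
                    pos=q,
                    codon=tri,
                    frame_anchor=frame,
                    stop_pos=stop_pos,
                    orf_length=stop_pos + 3 - q,
                )
            )
    return out


def score_candidates(
    candidates: list[StartCandidate], model: StartModel, region: FlankedRegion
) -> list[StartCandidate]:
    """Attach RBS and start-codon log-odds scores (in place; returned for
    chaining).  Candidates with less upstream context than the widest spacer
    window are scored over what is available and flagged truncated."""
    W = model.max_upstream
    for c in candidates:
        up = region.sequence[max(0, c.pos - W) : c.pos]
        c.truncated_context = c.pos < W
        c.rbs_score, c.rbs_motif, c.rbs_spacer = model.rbs_score(up)
        c.rbs_present = c.rbs_score >= model.rbs_present_threshold
        c.start_score = model.start_weights[c.codon]
        c.total_score = c.rbs_score + c.start_score
    return candidates


def resolve_starts(
    candidates: list[StartCandidate],
    hit_length: int,
    genome_id: str = "",
    gene: str = "",
    score_ratio: float = 0.8,
    min_length_frac: float = 0.9,
    require_rbs_consistency: bool = True,
    length_rule_first: bool = True,
) -> StartCall:
    """Apply the disambiguation rules and produce the fractional call.

    The 80%-of-best score rule is applied on scores shifted to be
    non-negative (log-odds can be negative, under which a plain ratio is
    ill-defined): every score is shifted by ``-min(0, min score) + eps``
    before the ratio test, which keeps near-ties retained regardless of sign.
    """
    flags: list[str] = []
    pool = list(candidates)

    def length_rule(cands):
        kept = [c for c in cands if c.orf_length >= min_length_frac * hit_length]
        if len(kept) < len(cands):
            flags.append("fragmented")
        return kept

    def score_rule(cands):
        if not cands:
            return cands
        shift = -min(0.0, min(c.total_score for c in cands)) + 1e-9
        best = max(c.total_score for c in cands) + shift
        return [c for c in cands if c.total_score + shift >= score_ratio * best]

    rules = [length_rule, score_rule] if length_rule_first else [score_rule, length_rule]
    for rule in rules:
        pool = rule(pool)

    if pool and require_rbs_consistency:
        top = min(pool, key=lambda c: (-c.total_score, c.pos))
        if top.rbs_present:
            kept = [c for c in pool if c.rbs_present]
            if len(kept) < len(pool):
                flags.append("rbs_filtered")
            pool = kept

    if not pool:
        return StartCall(
            genome_id, gene, [], _zero_weights(), flags=tuple(flags + ["no_candidate"])
        )
    pool.sort(key=lambda c: c.pos)
    weights = _zero_weights()
    share = Fraction(1, len(pool))
    for c in pool:
        cls = c.codon if c.codon in START_CODONS else "other"
        weights[cls] += share
    return StartCall(genome_id, gene, pool, weights, flags=tuple(flags))


# ---------------------------------------------------------------------------
# per-genome composition

def call_genome(
    genome: dict[str, str],
    references: dict[str, str],
    model: StartModel,
    genome_id: str = "",
    scoring: AlignmentScoring | None = None,
    flank: int = 75,
    score_ratio: float = 0.8,
    min_length_frac: float = 0.9,
) -> list[StartCall]:
    """Run homology search -> flank excision -> candidate scoring ->
    resolution for every reference gene in one genome.

    Per-gene failures never abort the other genes: a gene without a
    reportable hit is flagged ``absent``; a region without an in-frame stop
    is flagged ``no_stop``.  Both carry all-zero weights.
    """
    scoring = scoring or AlignmentScoring()
    calls = []
    for gene in sorted(references):
        query = references[gene]
        hits = []
        for contig_id in sorted(genome):
            hits.extend(
                align_local(
                    query,
                    genome[contig_id],
                    scoring,
                    genome_id=genome_id,
                    contig_id=contig_id,
                )
            )
        top = best_hit(hits)
        if top is None:
            calls.append(
                StartCall(genome_id, gene, [], _zero_weights(), flags=("absent",))
            )
            continue
        region = extract_flanked_region(genome[top.contig_id], top, flank=flank)
        try:
            cands = enumerate_candidates(region)
        except NoStopError:
            calls.append(
                StartCall(genome_id, gene, [], _zero_weights(), flags=("no_stop",))
            )
            continue
        score_candidates(cands, model, region)
        calls.append(
            resolve_starts(
                cands,
                top.hit_length,
                genome_id=genome_id,
                gene=gene,
                score_ratio=score_ratio,
                min_length_frac=min_length_frac,
            )
        )
    return calls


def calls_to_table(calls: list[StartCall]):
    """Long-format calls table: one row per (genome, gene, codon class) with
    exact fractional weight, plus retained-candidate count and flags."""
    import pandas as pd

    rows = []
    for call in calls:
        for cls in CODON_CLASSES:
            rows.append(
                dict(
                    genome_id=call.genome_id,
                    gene=call.gene,
                    codon=cls,
                    weight=float(call.weights[cls]),
                    weight_exact=str(call.weights[cls]),
                    n_retained=len(call.retained),
                    flags=",".join(call.flags),
                )
            )
    return pd.DataFrame(rows)
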