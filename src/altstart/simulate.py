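"""Synthetic genome cohorts with planted regulator loci and known ground truth.

Every downstream stage of the start-codon survey (homology localization,
RBS-aware start scoring, fractional counting, aggregation) is tested against
cohorts produced here: random-background contigs carrying planted regulator
genes with a Shine–Dalgarno motif at a chosen spacer, a chosen start codon
(ATG/GTG/TTG), optional in-frame secondary starts within ten nucleotides,
optional out-of-frame overlapping ATGTG configurations, and point-mutation
divergence between genomes.  A manifest records the planted truth so recovery
can be scored exactly.

The module also simulates two-strain competition experiments (cfu counts with
log-normal plating noise around a known competitive index) so the fitness
arithmetic can be validated on data with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: nt of upstream context built for every planted gene: an in-frame stop is
#: planted 24 nt upstream of the start so the candidate search window is
#: bounded, and the SD motif + spacer must fit between that stop and the start.
UPSTREAM_LEN = 30
_UPSTREAM_STOP_OFFSET = 24  # in-frame TAA at start-24

DEFAULT_SD_MOTIF = "AGGAGG"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PlantedGeneSpec:
    """One regulator locus to plant in every genome of the cohort.

    ``orf_length`` counts nucleotides from the first base of the start codon
    through the last base of the stop codon (inclusive), so it is a multiple
    of 3 and at least 60.  ``sd_spacer`` is the number of nucleotides between
    the 3' end of the SD motif and the start codon.  ``secondary_start``
    plants an extra in-frame candidate start at a signed offset (multiple of
    3, at most 9 nt — i.e. "in frame and within ten nucleotides").
    ``atgtg_overlap`` plants the ambiguous ATGTG arrangement: an out-of-frame
    ATG two nucleotides upstream of an in-frame GTG, whose reading frame
    terminates at its second codon.
    """

    name: str
    orf_length: int = 300
    start_codon: str = "ATG"
    strand: str = "+"
    sd_motif: str = DEFAULT_SD_MOTIF
    sd_spacer: int = 7
    secondary_start: tuple[str, int] | None = None  # (codon, offset nt)
    atgtg_overlap: bool = False
    category: str = "carbohydrate"
    mode: str = "negative"

    def validate(self) -> None:
        if self.orf_length % 3 != 0:
            raise ValueError(
                f"{self.name}: orf_length {self.orf_length} is not a multiple of 3"
            )
        if self.orf_length < 60:
            raise ValueError(f"{self.name}: orf_length must be >= 60")
        if self.start_codon not in START_CODONS:
            raise ValueError(f"{self.name}: start_codon must be one of {START_CODONS}")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        if self.sd_spacer < 2:
            raise ValueError(f"{self.name}: sd_spacer must be >= 2")
        if self.sd_spacer + len(self.sd_motif) > _UPSTREAM_STOP_OFFSET - 3:
            raise ValueError(
                f"{self.name}: SD motif at spacer {self.sd_spacer} collides with "
                "the upstream in-frame stop"
            )
        if self.secondary_start is not None:
            codon, off = self.secondary_start
            if codon not in START_CODONS:
                raise ValueError(f"{self.name}: secondary start codon {codon}")
            if off == 0 or off % 3 != 0 or abs(off) > 9:
                raise ValueError(
                    f"{self.name}: secondary start offset must be a non-zero "
                    "multiple of 3 within ten nucleotides"
                )
            if off < 0 and self.atgtg_overlap:
                raise ValueError(
                    f"{self.name}: upstream secondary start and ATGTG overlap "
                    "occupy the same bases"
                )
        if self.atgtg_overlap and self.start_codon != "GTG":
            raise ValueError(f"{self.name}: atgtg_overlap requires a GTG start")


@dataclass
class SimulationConfig:
    seed: int
    n_genomes: int
    contig_length: int = 10_000
    gc_content: float = 0.5
    genes: list[PlantedGeneSpec] = field(default_factory=list)
    divergence_rate: float = 0.0
    genus_labels: dict[str, str] | None = None
    species: str = "Escherichia coli"
    mask_planted_signals: bool = True
    metadata_overrides: dict[str, dict] | None = None
    #: genome_id -> {gene name -> start codon}: per-genome swap of the
    #: planted start codon (the rest of the locus stays ancestral), for
    #: cohorts with mixed codon usage at one locus
    start_codon_overrides: dict[str, dict[str, str]] | None = None

    def validate(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0,1]")
        if not 0.0 <= self.divergence_rate <= 0.2:
            raise ValueError("divergence_rate must lie in [0, 0.2]")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        for g in self.genes:
            g.validate()
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in config")


@dataclass
class Cohort:
    """In-memory result of :func:`generate_cohort`."""

    genomes: dict[str, dict[str, str]]  # genome_id -> {contig_id: sequence}
    annotations: dict[str, pd.DataFrame]  # genome_id -> gene feature table
    metadata: pd.DataFrame
    manifest: pd.DataFrame
    config: SimulationConfig

    def reference_sequences(self, genome_id: str | None = None) -> dict[str, str]:
        """Planted gene sequences (start through stop, gene-sense) from one
        genome — by default the undiverged training genome (index 0)."""
        gid = genome_id or sorted(self.genomes)[0]
        rows = self.manifest[self.manifest.genome_id == gid]
        out = {}
        for r in rows.itertuples():
            contig = self.genomes[gid][r.contig_id]
            if r.strand == "+":
                seq = contig[r.start_pos : r.start_pos + r.orf_length]
            else:
                seq = revcomp(contig[r.start_pos + 3 - r.orf_length : r.start_pos + 3])
            out[r.gene] = seq
        return out


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_codons(rng: np.random.Generator, n: int, gc: float, forbid: set[str]) -> list[str]:
    out = []
    while len(out) < n:
        c = _random_seq(rng, 3, gc)
        if c not in forbid:
            out.append(c)
    return out


def _build_locus(spec: PlantedGeneSpec, rng: np.random.Generator, gc: float):
    """Construct one gene locus in gene-sense orientation.

    Returns (sequence, protected relative positions, annotation dict).  The
    locus layout is ``[upstream 30 nt][start codon][body][stop codon]`` with
    an in-frame TAA planted 24 nt upstream of the start, the SD motif ending
    ``sd_spacer`` nt before the start, and all other in-frame triplets in the
    upstream window scrubbed of start/stop codons so the planted candidate
    set is exactly the recorded one.
    """
    p = UPSTREAM_LEN  # start codon position within locus
    n_codons = spec.orf_length // 3
    forbid = set(STOP_CODONS)
    # keep the first 10% of the ORF (the span where a spurious in-frame start
    # would survive the 90%-length rule) free of start codons
    n_guard = max(4, n_codons // 10 + 1)
    body = []
    for i in range(n_codons - 2):
        forbid_i = forbid | set(START_CODONS) if i < n_guard else forbid
        body.append(_random_codons(rng, 1, gc, forbid_i)[0])
    stop = STOP_CODONS[rng.integers(0, 3)]
    upstream = list(_random_seq(rng, p, gc))

    protected: set[int] = set()

    def write(pos: int, s: str, protect: bool = True) -> None:
        for i, b in enumerate(s):
            upstream[pos + i] = b
            if protect:
                protected.add(pos + i)

    write(p - _UPSTREAM_STOP_OFFSET, "TAA")
    sd_start = p - spec.sd_spacer - len(spec.sd_motif)
    write(sd_start, spec.sd_motif)

    decoys: list[tuple[int, str]] = []
    if spec.secondary_start is not None:
        codon, off = spec.secondary_start
        if off < 0:
            if not (p + off >= p - _UPSTREAM_STOP_OFFSET + 3):
                raise ValueError(f"{spec.name}: secondary start above upstream stop")
            lo, hi = p + off, p + off + 3
            if max(lo, sd_start) < min(hi, sd_start + len(spec.sd_motif)):
                raise ValueError(f"{spec.name}: secondary start overlaps SD motif")
            write(p + off, codon)
        decoys.append((off, codon))

    if spec.atgtg_overlap:
        write(p - 2, "AT")
        # out-of-frame ATG at p-2 reads ATG, then T G A using the first base
        # of the gene's second codon -> immediate termination
        body[0] = "AAA"

    # scrub remaining in-frame start/stop triplets between the upstream stop
    # and the start codon (they would alter the candidate set)
    keep = {p - _UPSTREAM_STOP_OFFSET}
    if spec.secondary_start is not None and spec.secondary_start[1] < 0:
        keep.add(p + spec.secondary_start[1])
    for q in range(p - _UPSTREAM_STOP_OFFSET + 3, p, 3):
        if q in keep:
            continue
        for _ in range(4):
            tri = "".join(upstream[q : q + 3])
            if tri not in START_CODONS and tri not in STOP_CODONS:
                break
            free = [i for i in range(q, q + 3) if i not in protected]
            if not free:
                break  # triplet fully inside a planted signal; leave it
            upstream[free[0]] = "C" if upstream[free[0]] != "C" else "A"

    seq = "".join(upstream) + spec.start_codon + "".join(body) + stop
    # protect start, stop, SD (already), secondary start, ATGTG bases
    protected.update(range(p, p + 3))
    protected.update(range(p + spec.orf_length - 3, p + spec.orf_length))
    if spec.secondary_start is not None:
        off = spec.secondary_start[1]
        if off > 0:
            write_pos = p + off
            seq = seq[:write_pos] + spec.secondary_start[0] + seq[write_pos + 3 :]
            protected.update(range(write_pos, write_pos + 3))
        else:
            protected.update(range(p + off, p + off + 3))
    if spec.atgtg_overlap:
        protected.update(range(p + 3, p + 6))

    ann = {
        "start_rel": p,
        "orf_length": spec.orf_length,
        "spacer": spec.sd_spacer,
        "decoys": decoys,
    }
    return seq, protected, ann


def _diverge(
    contig: list[str],
    rng: np.random.Generator,
    rate: float,
    masked: set[int],
    orf_ranges: list[tuple[int, int, str]],
) -> None:
    """Apply i.i.d. substitutions in place.

    Masked positions (planted starts/stops/SD and friends) are never touched.
    A substitution that would create an in-frame stop codon inside a planted
    ORF is skipped: the emulated genomes are under purifying selection and a
    cohort full of prematurely terminated regulators would measure ORF
    destruction rather than start-calling accuracy.
    """
    if rate <= 0:
        return
    bases = "ACGT"
    hit = np.flatnonzero(rng.random(len(contig)) < rate)
    # map position -> (orf_start, strand) for in-frame stop checking
    orf_of: dict[int, tuple[int, str]] = {}
    for s, e, strand in orf_ranges:
        for q in range(s, e):
            orf_of[q] = (s, strand) if strand == "+" else (e, strand)
    for pos in hit:
        pos = int(pos)
        if pos in masked:
            continue
        old = contig[pos]
        choices = [b for b in bases if b != old]
        new = choices[int(rng.integers(0, 3))]
        if pos in orf_of:
            anchor, strand = orf_of[pos]
            if strand == "+":
                c0 = pos - (pos - anchor) % 3
                tri = contig[c0:pos] + [new] + contig[pos + 1 : c0 + 3]
                if "".join(tri) in STOP_CODONS:
                    continue
            else:
                c1 = pos + (anchor - 1 - pos) % 3 + 1
                tri = contig[c1 - 3 : pos] + [new] + contig[pos + 1 : c1]
                if revcomp("".join(tri)) in STOP_CODONS:
                    continue
        contig[pos] = new


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a genome cohort with planted regulator loci.

    Genome index 0 is emitted undiverged and serves as the training genome;
    its planted gene sequences double as the homology-search references.
    Identical ``config`` (including seed) yields byte-identical artifacts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_genomes - 1)))
    genome_ids = [f"g{str(i).zfill(width)}" for i in range(config.n_genomes)]

    min_gap = 150
    total_locus = sum(UPSTREAM_LEN + g.orf_length for g in config.genes)
    needed = total_locus + min_gap * (len(config.genes) + 1)
    if needed > config.contig_length:
        raise ValueError(
            f"contig_length {config.contig_length} too small for "
            f"{len(config.genes)} planted loci (need >= {needed})"
        )

    # ancestral loci, shared by the whole cohort; divergence then acts on
    # per-genome copies so genomes are point-mutated relatives, not novelties
    loci = []
    for spec in config.genes:
        seq, protected, ann = _build_locus(spec, rng, config.gc_content)
        loci.append((spec, seq, protected, ann))

    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, pd.DataFrame] = {}
    manifest_rows = []
    meta_rows = []
    for gi, gid in enumerate(genome_ids):
        contig_id = f"{gid}_c1"
        slack = config.contig_length - total_locus
        # sequential placement: gaps between loci each >= min_gap
        gaps = []
        prev = 0
        for j in range(len(loci)):
            lo = prev + min_gap
            hi = slack - min_gap * (len(loci) - j)
            g = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
            gaps.append(g - prev)
            prev = g
        contig_parts = []
        pos = 0
        masked: set[int] = set()
        orf_ranges: list[tuple[int, int, str]] = []
        ann_rows = []
        overrides = (config.start_codon_overrides or {}).get(gid, {})
        for (spec, lseq, lprot, lann), gap in zip(loci, gaps):
            codon = overrides.get(spec.name, spec.start_codon)
            if codon != spec.start_codon:
                if codon not in START_CODONS:
                    raise ValueError(f"override codon {codon} for {spec.name}")
                sr = lann["start_rel"]
                lseq = lseq[:sr] + codon + lseq[sr + 3 :]
            contig_parts.append(_random_seq(rng, gap, config.gc_content))
            pos += gap
            if spec.strand == "+":
                contig_parts.append(lseq)
                start_pos = pos + lann["start_rel"]
                masked.update(pos + q for q in lprot)
                orf_s, orf_e = start_pos, start_pos + spec.orf_length
                decoy_abs = [(start_pos + off, c) for off, c in lann["decoys"]]
            else:
                contig_parts.append(revcomp(lseq))
                L = len(lseq)
                # gene-sense index q maps to forward index pos + L - 1 - q
                masked.update(pos + L - 1 - q for q in lprot)
                # start codon occupies gene-sense [start_rel, start_rel+3)
                start_pos = pos + L - 1 - (lann["start_rel"] + 2)
                orf_s = pos + L - (lann["start_rel"] + spec.orf_length)
                orf_e = pos + L - lann["start_rel"]
                decoy_abs = [
                    (pos + L - 1 - (lann["start_rel"] + off + 2), c)
                    for off, c in lann["decoys"]
                ]
            orf_ranges.append((orf_s, orf_e, spec.strand))
            manifest_rows.append(
                dict(
                    genome_id=gid,
                    gene=spec.name,
                    contig_id=contig_id,
                    start_pos=start_pos,
                    strand=spec.strand,
                    codon=codon,
                    orf_length=spec.orf_length,
                    sd_spacer=spec.sd_spacer,
                    decoy_starts=";".join(f"{q}:{c}" for q, c in decoy_abs),
                    category=spec.category,
                    mode=spec.mode,
                )
            )
            ann_rows.append(
                dict(
                    contig_id=contig_id,
                    gene=spec.name,
                    start=orf_s,
                    end=orf_e,
                    strand=spec.strand,
                )
            )
            pos += len(lseq)
        tail = config.contig_length - pos
        contig_parts.append(_random_seq(rng, tail, config.gc_content))
        contig = list("".join(contig_parts))
        if gi > 0:
            mask = masked if config.mask_planted_signals else set()
            _diverge(contig, rng, config.divergence_rate, mask, orf_ranges)
        genomes[gid] = {contig_id: "".join(contig)}
        annotations[gid] = pd.DataFrame(
            ann_rows, columns=["contig_id", "gene", "start", "end", "strand"]
        )
        genus = (config.genus_labels or {}).get(gid, "Escherichia")
        row = dict(
            genome_id=gid,
            genus=genus,
            species=config.species,
            completeness=100.0,
            contamination=0.0,
            n_contigs=1,
            genome_size=config.contig_length,
        )
        if config.metadata_overrides and gid in config.metadata_overrides:
            row.update(config.metadata_overrides[gid])
        meta_rows.append(row)

    manifest = pd.DataFrame(manifest_rows)
    metadata = pd.DataFrame(meta_rows)
    return Cohort(genomes, annotations, metadata, manifest, config)


# ---------------------------------------------------------------------------
# serialization

def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write gene features (0-based half-open in memory, 1-based inclusive on
    disk per the GFF3 standard)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotation.itertuples():
            attrs = f"ID={r.gene};Name={r.gene}"
            fh.write(
                f"{r.contig_id}\taltstart_sim\tgene\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t0\t{attrs}\n"
            )


def read_gff3_genes(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                dict(
                    contig_id=f[0],
                    gene=attrs.get("ID", attrs.get("Name", "?")),
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6],
                )
            )
    return pd.DataFrame(rows, columns=["contig_id", "gene", "start", "end", "strand"])


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Emit FASTA per genome, GFF3 per genome, metadata TSV, manifest TSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for gid, contigs in cohort.genomes.items():
        write_fasta(contigs, os.path.join(out_dir, f"{gid}.fasta"))
        write_gff3(cohort.annotations[gid], os.path.join(out_dir, f"{gid}.gff3"))
    cohort.metadata.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)
    cohort.manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees

def generate_tree(
    genome_ids,
    seed: int,
    group_by: dict[str, str] | None = None,
) -> str:
    """Random rooted binary tree over the given genome ids, as newick.

    With ``group_by`` (tip -> state), tips sharing a state are forced into one
    clade each, so every state is monophyletic by construction.
    """
    ids = list(genome_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 genomes for a tree")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    rng = np.random.default_rng(seed)

    def join(tips: list[str]) -> str:
        nodes = list(tips)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b1 = round(float(rng.uniform(0.01, 0.1)), 6)
            b2 = round(float(rng.uniform(0.01, 0.1)), 6)
            merged = f"({nodes[i]}:{b1},{nodes[j]}:{b2})"
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        return nodes[0]

    if group_by is None:
        return join(ids) + ";"
    clades = []
    for state in sorted(set(group_by[t] for t in ids)):
        members = [t for t in ids if group_by[t] == state]
        clades.append(join(members))
    return join(clades) + ";"


# ---------------------------------------------------------------------------
# competition experiments

@dataclass
class CompetitionSimConfig:
    seed: int
    n_subjects: int
    timepoints: list[int] = field(default_factory=lambda: [1, 3])
    true_ci: float = 1.0
    inoculum_fractions: tuple[float, float] = (0.5, 0.5)  # (mutant, wt)
    total_load: float = 1e8
    noise_cv: float = 0.0

    def validate(self) -> None:
        if self.true_ci <= 0:
            raise ValueError("true_ci must be positive")
        m, w = self.inoculum_fractions
        if abs(m + w - 1.0) > 1e-9:
            raise ValueError("inoculum fractions must sum to 1")
        if m <= 0 or w <= 0:
            raise ValueError("inoculum fractions must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_competition(config: CompetitionSimConfig) -> pd.DataFrame:
    """Simulate selective-plating observations for a mutant/WT competition.

    The mutant:WT ratio in each sample equals ``true_ci`` times the inoculum
    ratio, perturbed by multiplicative log-normal noise of the given CV
    (median 1, so the noise-free and median-over-subjects competitive index
    both recover ``true_ci``).  ``cfu_total`` is the antibiotic-free plate
    count, mutant + WT, so mutant <= total always holds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    inoc_m, inoc_w = config.inoculum_fractions
    rho = config.true_ci * inoc_m / inoc_w  # mutant/wt ratio in output
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    rows = []
    for subj in range(config.n_subjects):
        for day in config.timepoints:
            wt = config.total_load / (1.0 + rho)
            mut = config.total_load * rho / (1.0 + rho)
            if sigma > 0:
                wt *= float(np.exp(rng.normal(0.0, sigma)))
                mut *= float(np.exp(rng.normal(0.0, sigma)))
            rows.append(
                dict(
                    subject_id=f"m{subj + 1}",
                    day=day,
                    cfu_total=wt + mut,
                    cfu_mutant=mut,
                    inoc_mutant_frac=inoc_m,
                    inoc_wt_frac=inoc_w,
                    true_ci=config.true_ci,
                )
            )
    return pd.DataFrame(rows)
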