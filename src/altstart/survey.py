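"""End-to-end synthetic survey: the study conditions, composed.

This module fixes the cohort designs used throughout the analyses and wires
the pipeline stages together:

* a training genome with 80 annotated genes at E. coli-like start-codon
  usage (~80% ATG / 15% GTG / 5% TTG) and SD motifs at spacers 5-9;
* a lacI-like cohort: 200 genomes carrying one GTG regulator with a planted
  AGGAGG at spacer 7, 3% background divergence, and 0.5% of genomes switched
  to an ATG start — emulating the near-fixation of the non-canonical start
  observed at that locus;
* a category cohort: 20 carbohydrate regulators planted with GTG starts and
  20 carbohydrate-unrelated regulators planted with ATG starts, surveyed
  across a genome panel and compared by Mann-Whitney U on per-regulator
  non-ATG percentages.

Gene lengths are desk-scale (150-300 nt ORFs) so a full cohort survey runs
in seconds to minutes on one CPU; the calling logic is length-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import CategoryComparison, aggregate_usage, compare_categories
from .simulate import Cohort, PlantedGeneSpec, SimulationConfig, generate_cohort
from .startcall import StartModel, calls_to_table, call_genome, train_start_model

TRAIN_CODON_PROBS = {"ATG": 0.80, "GTG": 0.15, "TTG": 0.05}


def training_config(seed: int, n_genes: int = 80) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    codons = list(TRAIN_CODON_PROBS)
    probs = list(TRAIN_CODON_PROBS.values())
    genes = [
        PlantedGeneSpec(
            f"tg{i:03d}",
            orf_length=120,
            start_codon=str(rng.choice(codons, p=probs)),
            sd_spacer=int(rng.integers(5, 10)),
        )
        for i in range(n_genes)
    ]
    return SimulationConfig(
        seed=seed, n_genomes=1, contig_length=n_genes * 300 + 5000, genes=genes
    )


def train_default_model(seed: int) -> tuple[StartModel, Cohort]:
    cohort = generate_cohort(training_config(seed))
    gid = sorted(cohort.genomes)[0]
    return train_start_model(cohort.genomes[gid], cohort.annotations[gid]), cohort


def survey_cohort(cohort: Cohort, model: StartModel) -> pd.DataFrame:
    """Call every reference gene in every genome; references are the planted
    gene sequences of the undiverged genome 0."""
    refs = cohort.reference_sequences()
    calls = []
    for gid in sorted(cohort.genomes):
        calls.extend(call_genome(cohort.genomes[gid], refs, model, genome_id=gid))
    return calls_to_table(calls)


def majority_recovery(calls: pd.DataFrame, manifest: pd.DataFrame) -> float:
    """Fraction of (genome, gene) calls assigning strict majority weight
    (> 1/2) to the planted start codon."""
    truth = manifest.set_index(["genome_id", "gene"]).codon
    wide = calls.pivot_table(
        index=["genome_id", "gene"], columns="codon", values="weight", aggfunc="sum"
    )
    ok = total = 0
    for key, row in wide.iterrows():
        total += 1
        if row.get(truth.loc[key], 0.0) > 0.5:
            ok += 1
    return ok / total if total else 0.0


@dataclass
class LacSurveyResult:
    cohort: Cohort
    calls: pd.DataFrame
    summary: pd.DataFrame
    majority_recovery: float
    planted_pct: dict[str, float]
    called_pct: dict[str, float]


def run_lac_survey(
    seed: int,
    n_genomes: int = 200,
    atg_fraction: float = 0.005,
    divergence: float = 0.03,
    orf_length: int = 300,
) -> LacSurveyResult:
    """The lacI-like cohort: one GTG regulator near fixation, a small
    minority of genomes carrying an ATG start."""
    spec = PlantedGeneSpec(
        "lacI", orf_length=orf_length, start_codon="GTG", sd_spacer=7,
        category="carbohydrate", mode="negative",
    )
    rng = np.random.default_rng(seed + 1)
    n_atg = int(round(atg_fraction * n_genomes))
    width = max(3, len(str(n_genomes - 1)))
    # genome 0 stays GTG: it is the reference/training genome
    switched = rng.choice(np.arange(1, n_genomes), size=n_atg, replace=False)
    overrides = {
        f"g{str(int(i)).zfill(width)}": {"lacI": "ATG"} for i in switched
    }
    cfg = SimulationConfig(
        seed=seed,
        n_genomes=n_genomes,
        contig_length=6000,
        genes=[spec],
        divergence_rate=divergence,
        start_codon_overrides=overrides,
    )
    cohort = generate_cohort(cfg)
    model, _ = train_default_model(seed)
    calls = survey_cohort(cohort, model)
    from .aggregate import records_from_calls

    summary = aggregate_usage(records_from_calls(calls))
    planted = cohort.manifest.codon.value_counts(normalize=True) * 100
    row = summary.iloc[0]
    return LacSurveyResult(
        cohort=cohort,
        calls=calls,
        summary=summary,
        majority_recovery=majority_recovery(calls, cohort.manifest),
        planted_pct={c: float(planted.get(c, 0.0)) for c in ("ATG", "GTG", "TTG")},
        called_pct={c: float(row[f"pct_{c}"]) for c in ("ATG", "GTG", "TTG")},
    )


@dataclass
class CategorySurveyResult:
    cohort: Cohort
    calls: pd.DataFrame
    summary: pd.DataFrame
    comparisons: list[CategoryComparison]


def category_genes(
    seed: int, n_carb: int = 20, n_noncarb: int = 20
) -> list[PlantedGeneSpec]:
    """Carbohydrate regulators planted GTG-rich, carbohydrate-unrelated
    regulators planted ATG-only."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_carb):
        genes.append(
            PlantedGeneSpec(
                f"carb{i:02d}",
                orf_length=150,
                start_codon="GTG",
                sd_spacer=int(rng.integers(5, 10)),
                category="carbohydrate",
                mode=("negative", "positive", "bidirectional")[i % 3],
            )
        )
    for i in range(n_noncarb):
        genes.append(
            PlantedGeneSpec(
                f"ctrl{i:02d}",
                orf_length=150,
                start_codon="ATG",
                sd_spacer=int(rng.integers(5, 10)),
                category="non-carbohydrate",
                mode=("negative", "positive", "bidirectional")[i % 3],
            )
        )
    return genes


def run_category_survey(
    seed: int,
    n_genomes: int = 20,
    n_carb: int = 20,
    n_noncarb: int = 20,
    divergence: float = 0.03,
) -> CategorySurveyResult:
    genes = category_genes(seed + 2, n_carb=n_carb, n_noncarb=n_noncarb)
    n = len(genes)
    cfg = SimulationConfig(
        seed=seed,
        n_genomes=n_genomes,
        contig_length=n * 180 + (n + 1) * 160 + 500,
        genes=genes,
        divergence_rate=divergence,
    )
    cohort = generate_cohort(cfg)
    model, _ = train_default_model(seed)
    calls = survey_cohort(cohort, model)
    from .aggregate import records_from_calls

    summary = aggregate_usage(records_from_calls(calls))
    categories = (
        cohort.manifest[["gene", "category", "mode"]].drop_duplicates("gene")
    )
    comparisons = compare_categories(summary, categories)
    return CategorySurveyResult(
        cohort=cohort, calls=calls, summary=summary, comparisons=comparisons
    )
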