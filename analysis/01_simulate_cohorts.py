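#!/usr/bin/env python
"""Generate the synthetic study cohorts and write their artifacts.

Emits the training genome (80 annotated genes, E. coli-like start usage),
the lacI-like cohort (one GTG regulator near fixation with a 0.5% ATG
minority), the category cohort (20 GTG carbohydrate regulators vs 20 ATG
controls), a random genome tree, and a simulated competition table —
FASTA/GFF3/TSV/newick under results/sim/.
"""

import argparse
import os

from altstart.simulate import (
    CompetitionSimConfig,
    generate_competition,
    generate_cohort,
    generate_tree,
    write_cohort,
)
from altstart.survey import training_config, run_lac_survey, category_genes
from altstart.simulate import SimulationConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/sim")
    ap.add_argument("--n-genomes", type=int, default=60)
    args = ap.parse_args()

    os.makedirs(args.out, exist_ok=True)

    train = generate_cohort(training_config(args.seed))
    write_cohort(train, os.path.join(args.out, "training"))
    print(f"training genome: {len(train.manifest)} annotated genes")

    lac = run_lac_survey(args.seed, n_genomes=args.n_genomes).cohort
    write_cohort(lac, os.path.join(args.out, "lac_cohort"))
    counts = lac.manifest.codon.value_counts()
    print(f"lac cohort: {args.n_genomes} genomes, planted codons: {dict(counts)}")

    genes = category_genes(args.seed + 2)
    cat_cfg = SimulationConfig(
        seed=args.seed, n_genomes=8,
        contig_length=len(genes) * 180 + (len(genes) + 1) * 160 + 500,
        genes=genes, divergence_rate=0.03,
    )
    cat = generate_cohort(cat_cfg)
    write_cohort(cat, os.path.join(args.out, "category_cohort"))
    print(f"category cohort: {len(genes)} regulators x {len(cat.genomes)} genomes")

    nwk = generate_tree(sorted(lac.genomes), seed=args.seed)
    with open(os.path.join(args.out, "lac_cohort.nwk"), "w") as fh:
        fh.write(nwk + "\n")

    comp = generate_competition(
        CompetitionSimConfig(seed=args.seed, n_subjects=8, true_ci=0.03,
                             noise_cv=0.3)
    )
    comp.to_csv(os.path.join(args.out, "competition_mutant.tsv"), sep="\t",
                index=False)
    print(f"competition table: {len(comp)} observations (true C.I. = 0.03)")


if __name__ == "__main__":
    main()
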