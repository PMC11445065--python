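"""Cohort QC, fractional-usage aggregation, category statistics, phylogeny checks.

Genome cohorts are filtered on assembly quality (completeness >= 95%,
contamination <= 10%, contig count, species-relative size), large genera are
subsampled to at most 100 genomes while genera under 10 genomes are dropped,
and per-genome fractional start-codon calls are averaged into per-regulator
(and per-genus) percentage tables.  Carbohydrate vs non-carbohydrate
regulators are compared with a self-contained two-tailed Mann–Whitney U test
(exact enumeration at small n without ties, tie-corrected normal
approximation with continuity correction otherwise).  Supplied newick trees
support Fitch parsimony counts and monophyly checks of codon states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .startcall import CODON_CLASSES

REQUIRED_META_COLUMNS = (
    "genome_id",
    "genus",
    "species",
    "completeness",
    "contamination",
    "n_contigs",
    "genome_size",
)


# ---------------------------------------------------------------------------
# QC filtering and genus subsampling

def qc_filter(
    metadata: pd.DataFrame,
    min_completeness: float = 95.0,
    max_contamination: float = 10.0,
    max_contigs: int = 200,
    size_mad_factor: float = 3.0,
) -> tuple[list[str], pd.DataFrame]:
    """Keep genomes with completeness >= 95, contamination <= 10 (the rule
    excludes only contamination *larger than* 10), n_contigs <= max_contigs,
    and genome size no smaller than the species median minus 3 MAD
    ("exceptionally small genomes compared with those annotated with the
    same species").  Returns (kept ids, exclusion log with failed rule)."""
    missing = [c for c in REQUIRED_META_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    med = metadata.groupby("species")["genome_size"].transform("median")
    mad = metadata.groupby("species")["genome_size"].transform(
        lambda s: (s - s.median()).abs().median()
    )
    floor = med - size_mad_factor * mad

    kept, log_rows = [], []
    for r, size_floor in zip(metadata.itertuples(), floor):
        reasons = []
        if r.completeness < min_completeness:
            reasons.append("completeness")
        if r.contamination > max_contamination:
            reasons.append("contamination")
        if r.n_contigs > max_contigs:
            reasons.append("n_contigs")
        if r.genome_size < size_floor:
            reasons.append("small_genome")
        if reasons:
            log_rows.append(dict(genome_id=r.genome_id, reason=";".join(reasons)))
        else:
            kept.append(r.genome_id)
    return kept, pd.DataFrame(log_rows, columns=["genome_id", "reason"])


def subsample_genera(
    metadata: pd.DataFrame,
    max_per_genus: int = 100,
    min_per_genus: int = 10,
    seed: int = 0,
) -> list[str]:
    """Discard genera with fewer than ``min_per_genus`` genomes; uniformly
    subsample genera above ``max_per_genus`` down to exactly that many.
    Deterministic for a given seed."""
    if "genus" not in metadata.columns:
        raise ValueError("metadata is missing required column(s): ['genus']")
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for genus in sorted(metadata.genus.unique()):
        ids = sorted(metadata.loc[metadata.genus == genus, "genome_id"])
        if len(ids) < min_per_genus:
            continue
        if len(ids) > max_per_genus:
            pick = rng.choice(len(ids), size=max_per_genus, replace=False)
            ids = [ids[i] for i in sorted(pick)]
        kept.extend(ids)
    return kept


# ---------------------------------------------------------------------------
# usage aggregation

def records_from_calls(calls_table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(genome, gene) fraction table from the long calls table,
    dropping flagged (all-zero) calls."""
    wide = calls_table.pivot_table(
        index=["genome_id", "gene"], columns="codon", values="weight", aggfunc="sum"
    ).reindex(columns=list(CODON_CLASSES), fill_value=0.0)
    wide = wide.reset_index()
    total = wide[list(CODON_CLASSES)].sum(axis=1)
    return wide[total > 0.5].reset_index(drop=True)


def aggregate_usage(
    records: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    by_genus: bool = False,
    method: str = "fraction",
) -> pd.DataFrame:
    """Per-gene (optionally per-genus) start-codon usage percentages.

    ``method='fraction'`` (default) averages the per-genome fractional
    weights; ``method='majority'`` first collapses each genome to its
    majority codon class (ties split equally) and then averages.  Every row's
    percentages sum to 100; ``non_atg_percent = 100 - pct_ATG``.
    """
    df = records.copy()
    classes = list(CODON_CLASSES)
    if method == "majority":
        vals = df[classes].to_numpy()
        top = vals.max(axis=1, keepdims=True)
        is_top = (vals == top) & (top > 0)
        df[classes] = is_top / is_top.sum(axis=1, keepdims=True)
    elif method != "fraction":
        raise ValueError("method must be 'fraction' or 'majority'")
    keys = ["gene"]
    if by_genus:
        if metadata is None:
            raise ValueError("by_genus requires metadata")
        df = df.merge(metadata[["genome_id", "genus"]], on="genome_id", how="left")
        keys = ["gene", "genus"]
    grouped = df.groupby(keys)
    out = grouped[classes].mean().mul(100.0)
    out.columns = [f"pct_{c}" for c in classes]
    out["n_genomes"] = grouped.size()
    out["non_atg_percent"] = 100.0 - out["pct_ATG"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass
class MWUResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str


def _ranks_with_midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def mann_whitney_u(x, y, exact_limit: int = 12) -> MWUResult:
    """Two-tailed Mann–Whitney U test, self-contained.

    U is computed from rank sums with midranks for ties.  When
    n1 + n2 <= ``exact_limit`` and there are no ties, the two-tailed p is
    exact by enumeration of all rank arrangements
    (P(|U - n1 n2 / 2| >= |u - n1 n2 / 2|)); otherwise a tie-corrected
    normal approximation with continuity correction is used.  Swapping the
    groups maps U -> n1 n2 - U and leaves p unchanged.
    """
    x, y = [float(v) for v in x], [float(v) for v in y]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    ranks = _ranks_with_midranks(pooled)
    r1 = sum(ranks[:n1])
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2

    has_ties = len(set(pooled)) < len(pooled)
    if n1 + n2 <= exact_limit and not has_ties:
        n = n1 + n2
        obs = abs(u1 - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n), n1):
            # U for this arrangement: sum of ranks of chosen positions
            u = sum(i + 1 for i in idx) - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= obs - 1e-12:
                hits += 1
        return MWUResult(u1, hits / total, n1, n2, "exact")

    n = n1 + n2
    tie_term = 0.0
    seen: dict[float, int] = {}
    for v in pooled:
        seen[v] = seen.get(v, 0) + 1
    for t in seen.values():
        tie_term += t**3 - t
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MWUResult(u1, 1.0, n1, n2, "normal")
    diff = u1 - mu
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / math.sqrt(var)
    p = min(1.0, math.erfc(z / math.sqrt(2)))
    return MWUResult(u1, p, n1, n2, "normal")


def significance_band(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


# ---------------------------------------------------------------------------
# category comparison

@dataclass
class CategoryComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    values_a: list[float]
    values_b: list[float]
    u: float
    p: float
    band: str
    subset: str = "all"


def compare_categories(
    summary: pd.DataFrame,
    categories: pd.DataFrame,
    value_column: str = "non_atg_percent",
) -> list[CategoryComparison]:
    """Compare non-ATG usage between carbohydrate and non-carbohydrate
    regulators, overall and within each regulatory mode
    (positive/negative/bidirectional) when mode labels are present.

    ``categories`` needs columns gene, category (and optionally mode).
    """
    merged = summary.merge(categories, on="gene", how="left")
    missing = merged.loc[merged.category.isna(), "gene"].tolist()
    if missing:
        raise ValueError(f"gene(s) without a category label: {missing}")

    def one(sub: pd.DataFrame, label: str) -> CategoryComparison | None:
        a = sub.loc[sub.category == "carbohydrate", value_column].tolist()
        b = sub.loc[sub.category != "carbohydrate", value_column].tolist()
        if not a or not b:
            return None
        r = mann_whitney_u(a, b)
        return CategoryComparison(
            "carbohydrate", "non-carbohydrate", len(a), len(b), a, b,
            r.u, r.p, significance_band(r.p), subset=label,
        )

    out = [c for c in [one(merged, "all")] if c]
    if "mode" in merged.columns:
        for mode in sorted(merged["mode"].dropna().unique()):
            c = one(merged[merged["mode"] == mode], str(mode))
            if c:
                out.append(c)
    return out


def comparison_table(comparisons: list[CategoryComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subset=c.subset,
                n_carbohydrate=c.n_a,
                n_other=c.n_b,
                median_carbohydrate=float(np.median(c.values_a)),
                median_other=float(np.median(c.values_b)),
                U=c.u,
                p=c.p,
                band=c.band,
            )
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# trees: Fitch parsimony and monophyly

def _load_tree(tree: "str | dendropy.Tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        t = tree.clone(depth=1)
    else:
        t = dendropy.Tree.get(data=tree, schema="newick")
    if len(t.seed_node.child_nodes()) > 2:
        # unrooted newick: midpoint-root before any clade-based reasoning
        t.reroot_at_midpoint(update_bipartitions=False)
    t.resolve_polytomies()
    t.is_rooted = True
    return t


def fitch_parsimony(tree, tip_states: dict[str, str]) -> int:
    """Minimum number of state changes on the rooted tree (Fitch small
    parsimony).  Zero when all tips share a state."""
    t = _load_tree(tree)
    changes = 0
    sets: dict[dendropy.Node, frozenset] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in tip_states:
                raise ValueError(f"tip {label!r} has no state label")
            sets[node] = frozenset([tip_states[label]])
        else:
            children = [sets[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*children)
            if inter:
                sets[node] = inter
            else:
                sets[node] = frozenset.union(*children)
                changes += len(children) - 1
    return changes


def is_state_monophyletic(tree, tip_states: dict[str, str], state: str) -> bool:
    """True iff the tips carrying ``state`` form exactly one clade of the
    rooted tree."""
    t = _load_tree(tree)
    carriers = {tip for tip, s in tip_states.items() if s == state}
    if not carriers:
        raise ValueError(f"state {state!r} absent from tip_states")
    taxa = [
        leaf.taxon for leaf in t.leaf_node_iter()
        if leaf.taxon and leaf.taxon.label in carriers
    ]
    if len(taxa) != len(carriers):
        missing = carriers - {x.label for x in taxa}
        raise ValueError(f"tip(s) not in tree: {sorted(missing)}")
    if len(taxa) == 1:
        return True
    mrca = t.mrca(taxa=taxa)
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == carriers
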