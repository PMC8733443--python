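"""Gene-level enrichment machinery around TRD regions.

Three independent operations:

* a permutation test asking whether genes inside TRD regions carry more
  nonsynonymous SNPs (nsSNPs) than equally sized random draws of
  non-predicted protein-coding genes;
* a generic hypergeometric overrepresentation test with Benjamini-Hochberg
  correction over user-supplied gene sets;
* an overlay of protein-protein interaction (PPI) edges on region pairs
  with significant incompatibility evidence, keeping only edges whose two
  genes both carry nsSNPs and lie in different regions on different
  chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneAnnotation, PpiEdge
from .trd_scan import TrdRegion


@dataclass
class PermutationResult:
    observed_nssnps: int
    observed_genes_with_nssnp: int
    n_permutations: int
    null_mean: float
    null_sd: float
    null_max: float
    empirical_p: float
    seed: int
    draw_size: int

    def __post_init__(self):
        if not 0 < self.empirical_p <= 1:
            raise ValueError("empirical_p must be in (0,1]")


@dataclass
class EnrichmentRow:
    set_id: str
    k_in_set_and_query: int
    set_size: int
    query_size: int
    universe_size: int
    p_raw: float
    p_bh: float


def permutation_universe(annotation: list[GeneAnnotation]) -> list[GeneAnnotation]:
    """Non-predicted protein-coding genes eligible for random draws."""
    return [
        g for g in annotation if g.biotype == "protein_coding" and not g.predicted_flag
    ]


def nssnp_permutation_test(
    annotation: list[GeneAnnotation],
    observed_genes: list[str],
    n_permutations: int = 50_000,
    seed: int = 0,
    draw_size: int | None = None,
) -> PermutationResult:
    """Permutation test for nsSNP overrepresentation in the observed genes.

    Each permutation draws ``draw_size`` distinct non-predicted
    protein-coding genes uniformly from the annotation (default draw size =
    number of observed genes) and records the summed nsSNP count.  The
    empirical p-value uses the (r+1)/(n+1) estimator so it can never be
    exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    by_id = {g.gene_id: g for g in annotation}
    missing = [g for g in observed_genes if g not in by_id]
    if missing:
        raise ValueError(f"observed genes absent from annotation: {missing[:5]}")
    observed_total = sum(by_id[g].nssnp_count for g in observed_genes)
    observed_with = sum(1 for g in observed_genes if by_id[g].nssnp_count > 0)
    universe = permutation_universe(annotation)
    counts = np.array([g.nssnp_count for g in universe], dtype=np.int64)
    draw = draw_size if draw_size is not None else len(observed_genes)
    if draw > len(universe):
        raise ValueError(f"draw size {draw} exceeds universe of {len(universe)} genes")
    rng = np.random.default_rng(seed)
    totals = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        totals[i] = counts[rng.choice(len(counts), size=draw, replace=False)].sum()
    exceed = int((totals >= observed_total).sum())
    return PermutationResult(
        observed_nssnps=int(observed_total),
        observed_genes_with_nssnp=int(observed_with),
        n_permutations=n_permutations,
        null_mean=float(totals.mean()),
        null_sd=float(totals.std(ddof=1)) if n_permutations > 1 else 0.0,
        null_max=float(totals.max()),
        empirical_p=(exceed + 1) / (n_permutations + 1),
        seed=seed,
        draw_size=draw,
    )


def excess_percent(observed: float, null_mean: float) -> float:
    """Percent excess of the observation over the permutation null mean."""
    if null_mean <= 0:
        raise ValueError("null_mean must be positive")
    return 100.0 * (observed - null_mean) / null_mean


def hypergeom_overrep(
    query: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric overrepresentation with BH correction.

    Every gene set is intersected with the universe first; p-values are
    Benjamini-Hochberg adjusted across all tested sets and rows are sorted
    by adjusted then raw p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows: list[EnrichmentRow] = []
    for set_id, members in sets.items():
        in_universe = members & universe
        k = len(in_universe & query)
        # P(X >= k) for X ~ Hypergeom(M=|universe|, n=|set|, N=|query|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_universe), len(query)))
        rows.append(
            EnrichmentRow(
                set_id=set_id,
                k_in_set_and_query=k,
                set_size=len(in_universe),
                query_size=len(query),
                universe_size=len(universe),
                p_raw=min(p, 1.0),
                p_bh=np.nan,
            )
        )
    if rows:
        _, p_bh, _, _ = multipletests([r.p_raw for r in rows], method="fdr_bh")
        for r, adj in zip(rows, p_bh):
            r.p_bh = float(adj)
    rows.sort(key=lambda r: (r.p_bh, r.p_raw, r.set_id))
    return rows


def assign_genes_to_regions(
    annotation: list[GeneAnnotation], regions: list[TrdRegion]
) -> dict[str, list[str]]:
    """Map gene id -> region ids whose interval it overlaps by >= 1 bp."""
    out: dict[str, list[str]] = {}
    for g in annotation:
        hits = [
            r.region_id
            for r in regions
            if r.chromosome == g.chromosome
            and g.start_bp <= r.distal_bp
            and g.end_bp >= r.proximal_bp
        ]
        if hits:
            out[g.gene_id] = hits
    return out


def ppi_overlay(
    edges: list[PpiEdge],
    gene_regions: dict[str, list[str]],
    significant_pairs: set[frozenset[str]],
    nssnp_counts: dict[str, int],
    region_chromosomes: dict[str, str],
) -> list[PpiEdge]:
    """PPI edges compatible with a detected two-locus incompatibility.

    An edge is kept iff both genes carry at least one nsSNP, lie in regions
    on different chromosomes, and some pair of their regions is among the
    significant incompatibility pairs.  Same-chromosome edges are dropped:
    the incompatibility test is undefined for linked loci.
    """
    kept: list[PpiEdge] = []
    for edge in edges:
        a, b = edge.genes()
        if nssnp_counts.get(a, 0) < 1 or nssnp_counts.get(b, 0) < 1:
            continue
        regions_a = gene_regions.get(a, [])
        regions_b = gene_regions.get(b, [])
        qualifies = False
        for ra in regions_a:
            for rb in regions_b:
                if ra == rb:
                    continue
                if region_chromosomes[ra] == region_chromosomes[rb]:
                    continue
                if frozenset((ra, rb)) in significant_pairs:
                    qualifies = True
        if qualifies:
            kept.append(edge)
    return kept
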