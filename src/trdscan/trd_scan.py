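"""Transmission-ratio-distortion (TRD) scan.

For every eligible marker, transmissions from heterozygous parents of one
sex are counted across trios and tested against the Mendelian 50:50
expectation with the one-degree-of-freedom statistic

    chi2 = (n_A - n_B)^2 / (n_A + n_B)

where n_A / n_B count transmissions of the founder-1 / founder-2 allele.
P-values are expressed as LOD = -log10(p).  Eligibility requires founder
informativeness, a minimum number of heterozygous parents of the focal sex,
and Hardy-Weinberg equilibrium in the offspring generation (the test
statistic is only calibrated under HWE; strong HWE departures indicate
viability selection or genotyping artefacts).  Runs of significant markers
with a common preferred allele are merged into regions summarised the way
region tables in intercross studies are usually printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    GenotypeMatrix,
    MOUSE_AUTOSOMES,
    chrom_sort_key,
)
from .pedigree_qc import Trio

#: smallest p-value reported; smaller underflows double precision
P_FLOOR = 5e-324
#: LOD corresponding to P_FLOOR
LOD_CAP = -math.log10(P_FLOOR)


@dataclass
class ScanConfig:
    """Tunable thresholds of the TRD scan.

    The default LOD thresholds 6.75 (5%) and 7.45 (1%) are the published
    genome-wide Bonferroni constants for this family of mouse AIL scans;
    ``bonferroni_lod_threshold`` derives thresholds for other designs.
    """

    min_het_parents: int = 10
    hwe_alpha: float = 0.01
    lod_threshold_5pct: float = 6.75
    lod_threshold_1pct: float = 7.45
    merge_gap_bp: int = 5_000_000
    max_nonsig_run: int = 3
    min_call_rate: float = 0.9
    autosomes: tuple[str, ...] = MOUSE_AUTOSOMES

    def __post_init__(self):
        if self.min_het_parents < 1:
            raise ValueError("min_het_parents must be >= 1")
        if not 0 < self.hwe_alpha < 1:
            raise ValueError("hwe_alpha must be in (0,1)")
        if self.lod_threshold_5pct <= 0 or self.lod_threshold_1pct <= 0:
            raise ValueError("LOD thresholds must be positive")
        if self.merge_gap_bp < 0 or self.max_nonsig_run < 0:
            raise ValueError("merge_gap_bp and max_nonsig_run must be >= 0")


@dataclass
class TransmissionCounts:
    """Allele transmissions from heterozygous parents of one sex at a marker."""

    marker_id: str
    parent_sex: str  # {"paternal", "maternal"}
    n_A: int = 0
    n_B: int = 0
    n_het_parents: int = 0
    n_skipped_double_het: int = 0

    def __post_init__(self):
        if min(self.n_A, self.n_B, self.n_het_parents, self.n_skipped_double_het) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_resolved(self) -> int:
        return self.n_A + self.n_B


@dataclass
class TrdTestResult:
    counts: TransmissionCounts
    chromosome: str
    position_bp: int
    chi2: float
    p_value: float
    lod: float
    preferred_allele: str  # {"A", "B", "none"}
    lod_capped: bool = False

    @property
    def marker_id(self) -> str:
        return self.counts.marker_id


@dataclass
class TrdRegion:
    """A chromosome interval of contiguous significant markers."""

    region_id: str
    chromosome: str
    proximal_bp: int
    top_bp: int
    distal_bp: int
    n_snps: int
    preferred_allele: str
    mean_n_A: float
    sd_n_A: float
    mean_n_B: float
    sd_n_B: float
    top_marker_id: str
    top_n_A: int
    top_n_B: int
    distortion_percent: float
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.proximal_bp <= self.top_bp <= self.distal_bp:
            raise ValueError("region bounds must satisfy proximal <= top <= distal")
        if self.n_snps < 1:
            raise ValueError("region needs at least one marker")

    @property
    def size_bp(self) -> int:
        return self.distal_bp - self.proximal_bp


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, every feasible heterozygote
    count is enumerated and the p-value is the summed probability of all
    configurations no more probable than the observed one.  Probabilities
    are built by the standard two-sided recurrence on the heterozygote
    count, which avoids factorial overflow.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_AA + n_AB
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0  # monomorphic: single configuration
    # heterozygote counts share the parity of the rare-allele count
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    hets = list(range(rare % 2, rare + 1, 2))
    probs = np.zeros(len(hets))
    index = {h: i for i, h in enumerate(hets)}
    probs[index[mid]] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (homR+1)(homC+1))
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[index[h - 2]] = probs[index[h]] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    # upward recurrence: P(h+2)/P(h) = 4 homR homC / ((h+1)(h+2))
    h = mid
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[index[h + 2]] = probs[index[h]] * 4.0 * hom_r * hom_c / ((h + 1.0) * (h + 2.0))
        h += 2
    probs /= probs.sum()
    observed_het = n_AB
    p_obs = probs[index[observed_het]]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# transmission counting
# ---------------------------------------------------------------------------

def count_transmissions(
    genotypes: GenotypeMatrix,
    trios: list[Trio],
    marker_id: str,
    parent_sex: str,
) -> TransmissionCounts:
    """Count founder-allele transmissions from heterozygous focal parents.

    A transmission is resolvable only when the focal parent is heterozygous,
    the co-parent is homozygous and the child call pins down which allele the
    focal parent passed.  Double-heterozygous matings are tallied separately
    and excluded (the transmitted allele cannot be determined); trios with a
    missing call or a Mendelian-impossible configuration are skipped.
    """
    if parent_sex not in ("paternal", "maternal"):
        raise ValueError("parent_sex must be 'paternal' or 'maternal'")
    j = genotypes.marker_index(marker_id)
    focal_ids = [t.sire_id if parent_sex == "paternal" else t.dam_id for t in trios]
    other_ids = [t.dam_id if parent_sex == "paternal" else t.sire_id for t in trios]
    child_ids = [t.child_id for t in trios]
    focal = genotypes.calls[[genotypes.individual_index(i) for i in focal_ids], j]
    other = genotypes.calls[[genotypes.individual_index(i) for i in other_ids], j]
    child = genotypes.calls[[genotypes.individual_index(i) for i in child_ids], j]

    het_focal = focal == HET
    double_het = het_focal & (other == HET)
    resolvable = het_focal & np.isin(other, (HOM_A, HOM_B)) & (child != MISSING)
    # co-parent HOM_A: child HOM_A => focal gave A, child HET => focal gave B
    a_from_homA = resolvable & (other == HOM_A) & (child == HOM_A)
    b_from_homA = resolvable & (other == HOM_A) & (child == HET)
    # co-parent HOM_B: child HET => focal gave A, child HOM_B => focal gave B
    a_from_homB = resolvable & (other == HOM_B) & (child == HET)
    b_from_homB = resolvable & (other == HOM_B) & (child == HOM_B)

    het_parent_ids = {f for f, is_het in zip(focal_ids, het_focal) if is_het}
    return TransmissionCounts(
        marker_id=marker_id,
        parent_sex=parent_sex,
        n_A=int(a_from_homA.sum() + a_from_homB.sum()),
        n_B=int(b_from_homA.sum() + b_from_homB.sum()),
        n_het_parents=len(het_parent_ids),
        n_skipped_double_het=int(double_het.sum()),
    )


def transmission_chi2(
    counts: TransmissionCounts,
    chromosome: str = "",
    position_bp: int = 1,
) -> TrdTestResult:
    """One-df chi-square test of transmission symmetry, chi2 = (nA-nB)^2/(nA+nB)."""
    n_A, n_B = counts.n_A, counts.n_B
    total = n_A + n_B
    if total < 1:
        raise ValueError("no resolved transmissions")
    chi2 = (n_A - n_B) ** 2 / total
    p = float(stats.chi2.sf(chi2, df=1))
    capped = p < P_FLOOR
    p = max(p, P_FLOOR)
    lod = -math.log10(p)
    preferred = "A" if n_A > n_B else ("B" if n_B > n_A else "none")
    return TrdTestResult(
        counts=counts,
        chromosome=chromosome,
        position_bp=position_bp,
        chi2=chi2,
        p_value=p,
        lod=lod,
        preferred_allele=preferred,
        lod_capped=capped,
    )


def bonferroni_lod_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide LOD threshold -log10(alpha / n_tests)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return -math.log10(alpha / n_tests)


def distortion_percent(n_A: int, n_B: int) -> float:
    """Signed percent excess of founder-A transmissions over the Mendelian half.

    100 * (n_A - (n_A+n_B)/2) / ((n_A+n_B)/2); positive = founder-A excess.
    """
    total = n_A + n_B
    if total < 1:
        raise ValueError("no transmissions")
    expected = total / 2.0
    return 100.0 * (n_A - expected) / expected


# ---------------------------------------------------------------------------
# eligibility and the scan itself
# ---------------------------------------------------------------------------

def eligible_markers(
    genotypes: GenotypeMatrix,
    trios: list[Trio],
    parent_sex: str,
    config: ScanConfig | None = None,
) -> list[str]:
    """Markers passing all preconditions of the transmission test.

    A marker is eligible when it is founder-informative, reaches the
    call-rate threshold, has at least ``min_het_parents`` heterozygous
    parents of the focal sex among the trios, and its offspring genotypes
    are consistent with HWE at ``hwe_alpha``.
    """
    config = config or ScanConfig()
    if parent_sex not in ("paternal", "maternal"):
        raise ValueError("parent_sex must be 'paternal' or 'maternal'")
    parents = sorted({t.sire_id if parent_sex == "paternal" else t.dam_id for t in trios})
    children = sorted({t.child_id for t in trios})
    parent_rows = [genotypes.individual_index(i) for i in parents]
    child_rows = [genotypes.individual_index(i) for i in children]
    rates = genotypes.call_rates()
    eligible: list[str] = []
    for j, m in enumerate(genotypes.markers):
        if not m.informative or m.chromosome not in config.autosomes:
            continue
        if rates[j] < config.min_call_rate:
            continue
        n_het = int((genotypes.calls[parent_rows, j] == HET).sum())
        if n_het < config.min_het_parents:
            continue
        col = genotypes.calls[child_rows, j]
        n_aa = int((col == HOM_A).sum())
        n_ab = int((col == HET).sum())
        n_bb = int((col == HOM_B).sum())
        if n_aa + n_ab + n_bb == 0:
            continue
        if hwe_exact_test(n_aa, n_ab, n_bb) < config.hwe_alpha:
            continue
        eligible.append(m.marker_id)
    return eligible


def scan_transmissions(
    genotypes: GenotypeMatrix,
    trios: list[Trio],
    parent_sex: str,
    config: ScanConfig | None = None,
) -> list[TrdTestResult]:
    """Run the full per-marker transmission scan, map-ordered."""
    config = config or ScanConfig()
    marker_by_id = {m.marker_id: m for m in genotypes.markers}
    ids = eligible_markers(genotypes, trios, parent_sex, config)
    ids.sort(key=lambda mid: (chrom_sort_key(marker_by_id[mid].chromosome), marker_by_id[mid].position_bp))
    results: list[TrdTestResult] = []
    for mid in ids:
        counts = count_transmissions(genotypes, trios, mid, parent_sex)
        if counts.n_resolved == 0:
            continue
        m = marker_by_id[mid]
        results.append(transmission_chi2(counts, m.chromosome, m.position_bp))
    return results


def call_regions(
    results: list[TrdTestResult],
    config: ScanConfig | None = None,
    prefix: str = "Pat",
) -> list[TrdRegion]:
    """Merge map-ordered significant markers into TRD regions.

    A region is a maximal run of markers with LOD >= the 1% threshold on one
    chromosome sharing a preferred allele.  A run survives an intervening
    sub-threshold stretch of at most ``max_nonsig_run`` markers, provided
    consecutive significant markers lie within ``merge_gap_bp``.  The top
    marker is the maximum-LOD member; near-identical LODs tie-break toward
    the proximal marker.
    """
    config = config or ScanConfig()
    regions: list[TrdRegion] = []
    current: list[TrdTestResult] = []
    nonsig_since = 0

    def close_run():
        nonlocal current
        if current:
            regions.append(_summarize_region(current, f"{prefix}_R{len(regions) + 1}"))
            current = []

    ordered = sorted(results, key=lambda r: (chrom_sort_key(r.chromosome), r.position_bp))
    for r in ordered:
        significant = r.lod >= config.lod_threshold_1pct and r.preferred_allele != "none"
        if not significant:
            if current and (r.chromosome != current[-1].chromosome):
                close_run()
            nonsig_since += 1
            if nonsig_since > config.max_nonsig_run:
                close_run()
            continue
        if current:
            same_run = (
                r.chromosome == current[-1].chromosome
                and r.preferred_allele == current[-1].preferred_allele
                and r.position_bp - current[-1].position_bp <= config.merge_gap_bp
                and nonsig_since <= config.max_nonsig_run
            )
            if not same_run:
                close_run()
        current.append(r)
        nonsig_since = 0
    close_run()
    return regions


def _summarize_region(members: list[TrdTestResult], region_id: str) -> TrdRegion:
    lods = np.array([m.lod for m in members])
    # tie-break toward the proximal marker: first index within tolerance of max
    top_idx = int(np.nonzero(lods >= lods.max() - 1e-9)[0][0])
    top = members[top_idx]
    n_a = np.array([m.counts.n_A for m in members], dtype=float)
    n_b = np.array([m.counts.n_B for m in members], dtype=float)
    ddof = 1 if len(members) > 1 else 0
    return TrdRegion(
        region_id=region_id,
        chromosome=top.chromosome,
        proximal_bp=members[0].position_bp,
        top_bp=top.position_bp,
        distal_bp=members[-1].position_bp,
        n_snps=len(members),
        preferred_allele=top.preferred_allele,
        mean_n_A=float(n_a.mean()),
        sd_n_A=float(n_a.std(ddof=ddof)),
        mean_n_B=float(n_b.mean()),
        sd_n_B=float(n_b.std(ddof=ddof)),
        top_marker_id=top.marker_id,
        top_n_A=top.counts.n_A,
        top_n_B=top.counts.n_B,
        distortion_percent=distortion_percent(top.counts.n_A, top.counts.n_B),
        marker_ids=[m.marker_id for m in members],
    )
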