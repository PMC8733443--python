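"""Pairwise Bateson-Dobzhansky-Muller (BDM) incompatibility scan.

For each pair of TRD regions on different chromosomes, a 3x3 contingency
table of joint genotype classes at the two regions' top markers is compared
with the expectation under independent segregation (outer product of the
marginals).  A deficit of one joint class relative to that expectation is
the signature of a two-locus incompatibility.  Multiple testing across the
pair scan is controlled with genome-wide thresholds based on the effective
number of independent tests estimated from the eigenvalue spectrum of the
marker correlation matrix (the simpleM approach), with the pair count
written as n_eff * n_eff * 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix, chrom_sort_key
from .trd_scan import LOD_CAP, P_FLOOR, TrdRegion

GENOTYPE_CLASSES = ("HOM_A", "HET", "HOM_B")


@dataclass
class EffectiveTests:
    """Effective number of independent marker tests."""

    n_effective: int
    fix_length: int
    variance_fraction: float

    def __post_init__(self):
        if self.n_effective < 1:
            raise ValueError("n_effective must be >= 1")


@dataclass
class PairTable:
    """Observed and independence-expected 3x3 joint genotype counts."""

    marker_1: str
    marker_2: str
    observed: np.ndarray  # 3x3 counts, rows = classes at marker_1
    expected: np.ndarray
    n: int

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.observed.shape != (3, 3) or self.expected.shape != (3, 3):
            raise ValueError("tables must be 3x3")
        if abs(self.observed.sum() - self.n) > 1e-6:
            raise ValueError("observed counts do not sum to n")
        if abs(self.expected.sum() - self.n) > 1e-6:
            raise ValueError("expected counts do not sum to n")

    def transposed(self) -> "PairTable":
        return PairTable(self.marker_2, self.marker_1, self.observed.T, self.expected.T, self.n)


@dataclass
class IncompatResult:
    region_1: str
    region_2: str
    chromosome_1: str
    chromosome_2: str
    marker_1: str
    marker_2: str
    table: PairTable | None
    chi2: float | None
    p_value: float | None
    lod: float | None
    status: str  # {"not_tested", "not_significant", "significant", "highly_significant"}
    most_reduced_combo: tuple[str, str, float] | None


def simple_m(
    genotypes: GenotypeMatrix,
    fix_length: int = 1200,
    variance_fraction: float = 0.995,
) -> EffectiveTests:
    """Effective number of independent tests from blockwise eigen-spectra.

    Per chromosome, markers are split into consecutive blocks of at most
    ``fix_length``.  For each block the eigenvalues of the genotype-dosage
    correlation matrix (0/1/2 coding, pairwise-complete over missing calls)
    are computed, and the block contributes the smallest k whose top-k
    eigenvalues explain at least ``variance_fraction`` of the total
    variance.  The genome-wide estimate is the sum over blocks.
    """
    if fix_length < 1:
        raise ValueError("fix_length must be >= 1")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0,1]")
    by_chrom: dict[str, list[int]] = {}
    for j, m in enumerate(genotypes.markers):
        by_chrom.setdefault(m.chromosome, []).append(j)
    n_effective = 0
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        idx = sorted(by_chrom[chrom], key=lambda j: genotypes.markers[j].position_bp)
        for start in range(0, len(idx), fix_length):
            block = idx[start : start + fix_length]
            dosage = genotypes.calls[:, block].astype(float)
            dosage[dosage == MISSING] = np.nan
            keep = np.nanstd(dosage, axis=0) > 0
            if not keep.all():
                warnings.warn(
                    f"dropping {int((~keep).sum())} zero-variance markers on {chrom}"
                )
            dosage = dosage[:, keep]
            if dosage.shape[1] == 0:
                continue
            if np.isnan(dosage).any():
                corr = pd.DataFrame(dosage).corr(min_periods=1).to_numpy()
                corr = np.nan_to_num(corr, nan=0.0)
                np.fill_diagonal(corr, 1.0)
            else:
                corr = np.corrcoef(dosage, rowvar=False)
                corr = np.atleast_2d(corr)
            eigvals = np.linalg.eigvalsh(corr)[::-1]
            eigvals = np.clip(eigvals, 0.0, None)
            total = eigvals.sum()
            frac = np.cumsum(eigvals) / total
            n_effective += int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)
    if n_effective < 1:
        raise ValueError("no variable markers: cannot estimate effective tests")
    return EffectiveTests(n_effective, fix_length, variance_fraction)


def pair_contingency(
    genotypes: GenotypeMatrix,
    marker_1: str,
    marker_2: str,
    individuals: list[str],
) -> PairTable:
    """Observed vs independence-expected joint genotype table at two markers.

    The markers must lie on different chromosomes (linked loci segregate
    jointly and the independence expectation would be meaningless).
    Individuals missing at either marker are excluded.
    """
    m1 = genotypes.markers[genotypes.marker_index(marker_1)]
    m2 = genotypes.markers[genotypes.marker_index(marker_2)]
    if m1.chromosome == m2.chromosome:
        raise ValueError(
            f"{marker_1} and {marker_2} are both on chromosome {m1.chromosome}; "
            "incompatibility tests need unlinked markers"
        )
    rows = [genotypes.individual_index(i) for i in individuals]
    g1 = genotypes.calls[rows, genotypes.marker_index(marker_1)]
    g2 = genotypes.calls[rows, genotypes.marker_index(marker_2)]
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok], g2[ok]
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no individuals genotyped at both markers")
    observed = np.zeros((3, 3))
    for a in (HOM_A, HET, HOM_B):
        for b in (HOM_A, HET, HOM_B):
            observed[a, b] = int(((g1 == a) & (g2 == b)).sum())
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    return PairTable(marker_1, marker_2, observed, expected, n)


def bdm_chi2(table: PairTable, min_expected_warn: float = 5.0) -> IncompatResult:
    """Chi-square test of the joint table against independent segregation.

    chi2 sums (O-E)^2/E over cells with E > 0; degrees of freedom are
    (r-1)(c-1) over rows/columns with non-zero marginals (4 for a full 3x3).
    ``most_reduced_combo`` reports the cell with the largest percent deficit
    100*(E-O)/E, the natural candidate for the disadvantaged genotype
    combination.
    """
    obs, exp = table.observed, table.expected
    nonzero_rows = int((obs.sum(axis=1) > 0).sum())
    nonzero_cols = int((obs.sum(axis=0) > 0).sum())
    df = (nonzero_rows - 1) * (nonzero_cols - 1)
    if df <= 0:
        raise ValueError("degenerate table: a marker is monomorphic among counted individuals")
    mask = exp > 0
    if not mask.any():
        raise ValueError("no expected cell > 0")
    if exp[mask].min() < min_expected_warn:
        warnings.warn(
            f"expected count below {min_expected_warn} in pair "
            f"({table.marker_1}, {table.marker_2}); chi-square approximation is rough"
        )
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    p = float(stats.chi2.sf(chi2, df=df))
    p = max(p, P_FLOOR)
    lod = -math.log10(p)
    reductions = np.full((3, 3), -np.inf)
    reductions[mask] = 100.0 * (exp[mask] - obs[mask]) / exp[mask]
    # most reduced cell; ties broken toward the larger expected count
    best = np.unravel_index(
        np.lexsort((exp.ravel(), reductions.ravel()))[-1], reductions.shape
    )
    combo = (
        GENOTYPE_CLASSES[best[0]],
        GENOTYPE_CLASSES[best[1]],
        float(reductions[best]),
    )
    return IncompatResult(
        region_1="",
        region_2="",
        chromosome_1="",
        chromosome_2="",
        marker_1=table.marker_1,
        marker_2=table.marker_2,
        table=table,
        chi2=chi2,
        p_value=p,
        lod=lod,
        status="",
        most_reduced_combo=combo,
    )


def pairwise_lod_threshold(alpha: float, n_effective: int) -> float:
    """Genome-wide LOD threshold for the pair scan: -log10(alpha/(n_eff^2 * 0.5)).

    The pair count is written as n_eff * n_eff * 0.5, the published form for
    this correction; ``strict_pairs=True`` in :func:`pairwise_scan` swaps in
    n_eff*(n_eff-1)/2 instead.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    return -math.log10(alpha / (n_effective * n_effective * 0.5))


def _strict_pairs_lod_threshold(alpha: float, n_effective: int) -> float:
    n_pairs = max(n_effective * (n_effective - 1) // 2, 1)
    return -math.log10(alpha / n_pairs)


def pairwise_scan(
    regions: list[TrdRegion],
    genotypes: GenotypeMatrix,
    effective: EffectiveTests | int,
    individuals: list[str],
    alpha_significant: float = 0.05,
    alpha_highly: float = 0.01,
    strict_pairs: bool = False,
) -> list[IncompatResult]:
    """BDM test for every unordered pair of TRD regions.

    Each region is represented by its top marker (the proximal flanking
    marker when the region had no unique LOD maximum, which is how the top
    marker is already resolved at region-calling time).  Pairs on the same
    chromosome are emitted with status ``not_tested``.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    n_eff = effective.n_effective if isinstance(effective, EffectiveTests) else int(effective)
    thr_fn = _strict_pairs_lod_threshold if strict_pairs else pairwise_lod_threshold
    thr_sig = thr_fn(alpha_significant, n_eff)
    thr_high = thr_fn(alpha_highly, n_eff)
    results: list[IncompatResult] = []
    for r1, r2 in combinations(regions, 2):
        if r1.chromosome == r2.chromosome:
            results.append(
                IncompatResult(
                    region_1=r1.region_id,
                    region_2=r2.region_id,
                    chromosome_1=r1.chromosome,
                    chromosome_2=r2.chromosome,
                    marker_1=r1.top_marker_id,
                    marker_2=r2.top_marker_id,
                    table=None,
                    chi2=None,
                    p_value=None,
                    lod=None,
                    status="not_tested",
                    most_reduced_combo=None,
                )
            )
            continue
        table = pair_contingency(genotypes, r1.top_marker_id, r2.top_marker_id, individuals)
        res = bdm_chi2(table)
        res.region_1, res.region_2 = r1.region_id, r2.region_id
        res.chromosome_1, res.chromosome_2 = r1.chromosome, r2.chromosome
        if res.lod > thr_high:
            res.status = "highly_significant"
        elif res.lod > thr_sig:
            res.status = "significant"
        else:
            res.status = "not_significant"
        results.append(res)
    return results
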