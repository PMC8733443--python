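import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trdscan import (
    GenotypeMatrix,
    MarkerInfo,
    ScanConfig,
    TransmissionCounts,
    Trio,
    bonferroni_lod_threshold,
    build_trios,
    call_regions,
    count_transmissions,
    distortion_percent,
    eligible_markers,
    hwe_exact_test,
    scan_transmissions,
    transmission_chi2,
)
from trdscan.io_formats import HET, HOM_A, HOM_B, MISSING
from trdscan.trd_scan import TrdTestResult


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test vs full enumeration
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact p by enumerating every heterozygote count with fixed allele counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def prob(h):
        # P(n_AB = h | n, n_a) = n! 2^h n_a! n_b! / (hom_r! h! hom_c! (2n)!)
        hom_r = (min(n_a, 2 * n - n_a) - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 0 or hom_c < 0:
            return Fraction(0)
        f = math.factorial
        return (
            Fraction(f(n) * 2**h * f(n_a) * f(2 * n - n_a))
            / Fraction(f(hom_r) * f(h) * f(hom_c) * f(2 * n))
        )

    rare = min(n_a, 2 * n - n_a)
    feasible = range(rare % 2, rare + 1, 2)
    p_obs = prob(n_ab)
    return float(sum(prob(h) for h in feasible if prob(h) <= p_obs))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 100) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(3, 5, 2), (50, 0, 50), (10, 5, 10), (2, 9, 3), (1, 1, 1), (0, 21, 4)],
    )
    def test_matches_enumeration(self, counts):
        expected = hwe_enumeration_oracle(*counts)
        assert hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-9)

    def test_extreme_het_deficit_is_tiny(self):
        assert hwe_exact_test(50, 0, 50) < 1e-3

    def test_random_small_tables_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            c = tuple(int(x) for x in rng.integers(0, 18, size=3))
            if sum(c) == 0:
                continue
            assert hwe_exact_test(*c) == pytest.approx(
                hwe_enumeration_oracle(*c), rel=1e-9
            ), c

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# transmission resolution and chi-square
# ---------------------------------------------------------------------------

def _single_marker_trio(sire, dam, child):
    gm = GenotypeMatrix(
        ["s", "d", "c"],
        [MarkerInfo("m", "1", 100)],
        np.array([[sire], [dam], [child]], dtype=np.int8),
    )
    return gm, [Trio("c", "s", "d")]


@pytest.mark.parametrize(
    "sire,dam,child,expect",
    [
        (HET, HOM_A, HET, dict(n_A=0, n_B=1)),  # father forced to have given B
        (HET, HOM_A, HOM_A, dict(n_A=1, n_B=0)),
        (HET, HOM_B, HET, dict(n_A=1, n_B=0)),
        (HET, HOM_B, HOM_B, dict(n_A=0, n_B=1)),
        (HET, HET, HOM_A, dict(n_A=0, n_B=0, n_skipped_double_het=1)),
        (HET, HET, HET, dict(n_A=0, n_B=0, n_skipped_double_het=1)),
        (HOM_A, HOM_A, HOM_A, dict(n_A=0, n_B=0, n_het_parents=0)),  # focal not het
        (HET, HOM_A, MISSING, dict(n_A=0, n_B=0)),  # unresolvable, skipped
        (HET, MISSING, HET, dict(n_A=0, n_B=0)),  # co-parent missing, skipped
        (HET, HOM_A, HOM_B, dict(n_A=0, n_B=0)),  # Mendelian-impossible, skipped
    ],
)
def test_paternal_transmission_resolution(sire, dam, child, expect):
    gm, trios = _single_marker_trio(sire, dam, child)
    counts = count_transmissions(gm, trios, "m", "paternal")
    assert counts.n_A == expect.get("n_A", 0)
    assert counts.n_B == expect.get("n_B", 0)
    assert counts.n_skipped_double_het == expect.get("n_skipped_double_het", 0)
    assert counts.n_het_parents == expect.get("n_het_parents", 1)


def test_maternal_counting_mirrors_paternal():
    gm, trios = _single_marker_trio(HOM_A, HET, HET)
    counts = count_transmissions(gm, trios, "m", "maternal")
    assert (counts.n_A, counts.n_B) == (0, 1)


class TestTransmissionChi2:
    def test_published_top_marker_counts(self):
        res = transmission_chi2(TransmissionCounts("m", "paternal", 169, 48))
        assert res.chi2 == pytest.approx(121**2 / 217, rel=1e-12)
        assert res.p_value < 1e-14
        assert res.preferred_allele == "A"

    def test_table_row_counts(self):
        res = transmission_chi2(TransmissionCounts("m", "paternal", 207, 47))
        assert res.chi2 == pytest.approx(160**2 / 254, rel=1e-12)

    def test_perfect_symmetry(self):
        res = transmission_chi2(TransmissionCounts("m", "paternal", 100, 100))
        assert res.chi2 == 0
        assert res.p_value == 1
        assert res.lod == 0
        assert res.preferred_allele == "none"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            transmission_chi2(TransmissionCounts("m", "paternal", 0, 0))

    def test_extreme_counts_floor_p_and_flag(self):
        res = transmission_chi2(TransmissionCounts("m", "paternal", 10_000, 0))
        assert res.lod_capped
        assert res.p_value > 0
        assert np.isfinite(res.lod)

    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    @settings(deadline=None, max_examples=60)
    def test_symmetry_flips_preference(self, a, b):
        if a + b == 0:
            return
        fwd = transmission_chi2(TransmissionCounts("m", "paternal", a, b))
        rev = transmission_chi2(TransmissionCounts("m", "paternal", b, a))
        assert fwd.chi2 == rev.chi2
        assert fwd.p_value == rev.p_value
        flip = {"A": "B", "B": "A", "none": "none"}
        assert rev.preferred_allele == flip[fwd.preferred_allele]

    @given(total=st.integers(2, 400), data=st.data())
    @settings(deadline=None, max_examples=60)
    def test_chi2_monotone_in_imbalance(self, total, data):
        """For fixed n_A + n_B, chi2 strictly increases with |n_A - n_B|."""
        a1 = data.draw(st.integers(0, total))
        a2 = data.draw(st.integers(0, total))
        if abs(2 * a1 - total) == abs(2 * a2 - total):
            return
        if abs(2 * a1 - total) > abs(2 * a2 - total):
            a1, a2 = a2, a1
        lo = transmission_chi2(TransmissionCounts("m", "paternal", a1, total - a1))
        hi = transmission_chi2(TransmissionCounts("m", "paternal", a2, total - a2))
        assert hi.chi2 > lo.chi2


def test_bonferroni_lod_threshold():
    assert bonferroni_lod_threshold(0.05, 1) == pytest.approx(1.3010, abs=1e-4)
    assert bonferroni_lod_threshold(0.01, 1) == pytest.approx(2.0)
    assert bonferroni_lod_threshold(0.05, 1000) == pytest.approx(4.3010, abs=1e-4)
    with pytest.raises(ValueError):
        bonferroni_lod_threshold(1.5, 10)


@pytest.mark.parametrize(
    "n_a,n_b,expected",
    [(169, 48, 55.8), (152, 30, 67.0), (10, 130, -85.7), (77, 77, 0.0)],
)
def test_distortion_percent(n_a, n_b, expected):
    assert distortion_percent(n_a, n_b) == pytest.approx(expected, abs=0.05)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def _cohort(n_fathers_het, n_total=30):
    """Trios with a configurable number of heterozygous fathers, offspring in HWE."""
    rng = np.random.default_rng(1)
    markers = [MarkerInfo("m", "1", 100)]
    individuals, rows, trios = [], [], []
    child_calls = rng.choice([HOM_A, HET, HET, HOM_B], size=n_total)
    for i in range(n_total):
        sire = HET if i < n_fathers_het else HOM_A
        for name, g in ((f"s{i}", sire), (f"d{i}", HOM_A), (f"c{i}", child_calls[i])):
            individuals.append(name)
            rows.append([g])
        trios.append(Trio(f"c{i}", f"s{i}", f"d{i}"))
    gm = GenotypeMatrix(individuals, markers, np.array(rows, dtype=np.int8))
    return gm, trios


class TestEligibility:
    def test_nine_het_fathers_ineligible(self):
        gm, trios = _cohort(9)
        assert eligible_markers(gm, trios, "paternal") == []

    def test_ten_het_fathers_eligible(self):
        gm, trios = _cohort(10)
        assert eligible_markers(gm, trios, "paternal") == ["m"]

    def test_hwe_violation_excluded(self):
        gm, trios = _cohort(15)
        # force a gross heterozygote deficit among the offspring
        child_rows = [gm.individual_index(t.child_id) for t in trios]
        gm.calls[child_rows[: len(child_rows) // 2], 0] = HOM_A
        gm.calls[child_rows[len(child_rows) // 2 :], 0] = HOM_B
        assert eligible_markers(gm, trios, "paternal") == []

    def test_uninformative_excluded(self):
        gm, trios = _cohort(15)
        gm.markers[0] = MarkerInfo("m", "1", 100, informative=False)
        assert eligible_markers(gm, trios, "paternal") == []


def test_conservation_of_transmissions(null_ail):
    """n_A + n_B never exceeds the trios whose focal parent is heterozygous."""
    cfg, genotypes, pedigree = null_ail
    trios = build_trios(pedigree, cfg.generations, genotypes)
    for mid in [m.marker_id for m in genotypes.markers[:10]]:
        counts = count_transmissions(genotypes, trios, mid, "paternal")
        j = genotypes.marker_index(mid)
        sire_rows = [genotypes.individual_index(t.sire_id) for t in trios]
        n_het_trios = int((genotypes.calls[sire_rows, j] == HET).sum())
        assert counts.n_resolved <= n_het_trios


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def _result(mid, chrom, bp, lod, allele="A", n_a=150, n_b=50):
    counts = TransmissionCounts(mid, "paternal", n_a, n_b)
    if allele == "B":
        counts = TransmissionCounts(mid, "paternal", n_b, n_a)
    p = 10.0**-lod
    return TrdTestResult(
        counts=counts,
        chromosome=chrom,
        position_bp=bp,
        chi2=0.0,
        p_value=p,
        lod=lod,
        preferred_allele=allele if lod > 0 else "none",
    )


class TestCallRegions:
    cfg = ScanConfig(lod_threshold_1pct=7.45, merge_gap_bp=5_000_000, max_nonsig_run=3)

    def test_contiguous_run_single_region(self):
        results = [
            _result("a", "1", 1_000_000, 8.0),
            _result("b", "1", 1_200_000, 9.0),
            _result("c", "1", 1_400_000, 8.0),
        ]
        regions = call_regions(results, self.cfg)
        assert len(regions) == 1
        r = regions[0]
        assert (r.n_snps, r.top_marker_id) == (3, "b")
        assert (r.proximal_bp, r.top_bp, r.distal_bp) == (1_000_000, 1_200_000, 1_400_000)

    def test_short_subthreshold_dip_does_not_split(self):
        results = [
            _result("a", "1", 1_000_000, 8.0),
            _result("b", "1", 1_200_000, 2.0),
            _result("c", "1", 1_400_000, 9.0),
        ]
        regions = call_regions(results, self.cfg)
        assert len(regions) == 1 and regions[0].n_snps == 2

    def test_long_subthreshold_stretch_splits(self):
        results = [_result("a", "1", 1_000_000, 8.0)]
        results += [
            _result(f"n{k}", "1", 1_000_000 + 50_000 * (k + 1), 1.0) for k in range(4)
        ]
        results += [_result("b", "1", 1_300_000, 9.0)]
        regions = call_regions(results, self.cfg)
        assert [r.top_marker_id for r in regions] == ["a", "b"]

    def test_bp_gap_splits(self):
        results = [
            _result("a", "1", 1_000_000, 8.0),
            _result("b", "1", 20_000_000, 9.0),
        ]
        assert len(call_regions(results, self.cfg)) == 2

    def test_allele_switch_splits(self):
        results = [
            _result("a", "1", 1_000_000, 8.0, "A"),
            _result("b", "1", 1_100_000, 9.0, "B"),
        ]
        regions = call_regions(results, self.cfg)
        assert [r.preferred_allele for r in regions] == ["A", "B"]

    def test_chromosome_change_splits(self):
        results = [
            _result("a", "1", 1_000_000, 8.0),
            _result("b", "2", 1_100_000, 9.0),
        ]
        assert len(call_regions(results, self.cfg)) == 2

    def test_lod_tie_resolves_to_proximal_marker(self):
        results = [
            _result("a", "1", 1_000_000, 8.0),
            _result("b", "1", 1_100_000, 8.0),
            _result("c", "1", 1_200_000, 8.0),
        ]
        regions = call_regions(results, self.cfg)
        assert regions[0].top_marker_id == "a"
        assert regions[0].top_bp == 1_000_000

    def test_region_members_share_preferred_allele(self, null_ail):
        cfg, genotypes, pedigree = null_ail
        trios = build_trios(pedigree, cfg.generations, genotypes)
        scan_cfg = ScanConfig(lod_threshold_1pct=0.5)  # low bar to force regions
        results = scan_transmissions(genotypes, trios, "paternal", scan_cfg)
        by_id = {r.marker_id: r for r in results}
        for region in call_regions(results, scan_cfg):
            alleles = {by_id[m].preferred_allele for m in region.marker_ids}
            assert alleles == {region.preferred_allele}

    def test_empty_input(self):
        assert call_regions([], self.cfg) == []
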