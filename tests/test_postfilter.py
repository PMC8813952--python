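"""Pileup counting, beta-binomial allele-balance test, control filters."""

from __future__ import annotations

import math

import numpy as np
import pysam
import pytest
from scipy import stats

from mosaicbench.mix_design import TruthRecord
from mosaicbench.postfilter import (
    ALLELE_BALANCE,
    ALT_EVIDENCE,
    BetaBinomParams,
    DataCompletenessError,
    FilterDecision,
    FitError,
    GermlineRecord,
    LOW_COVERAGE,
    LOW_HOM_VAF,
    LOW_VARIANT_COVERAGE,
    MISSING,
    PileupBoundsError,
    PileupCounts,
    alt_allele_key,
    betabinom_two_tailed_p,
    filter_germline_setB,
    filter_negative_setA,
    filter_positive,
    fit_betabinom,
    pileup_positions,
    retained_sites,
)
from mosaicbench.variants import Genotype, VariantSite

HET, HOM = Genotype.HET, Genotype.HOM_ALT


# ---------------------------------------------------------------------------
# independent beta-binomial oracle (lgamma arithmetic, explicit summation)
# ---------------------------------------------------------------------------


def _oracle_pmf(k: int, n: int, a: float, b: float) -> float:
    def lbeta(x, y):
        return math.lgamma(x) + math.lgamma(y) - math.lgamma(x + y)

    logc = (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )
    return math.exp(logc + lbeta(k + a, n - k + b) - lbeta(a, b))


def _oracle_two_tailed(k: int, n: int, a: float, b: float) -> float:
    pmf = [_oracle_pmf(j, n, a, b) for j in range(n + 1)]
    pk = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= pk * (1 + 1e-9)))


class TestBetaBinomP:
    def test_matches_oracle_at_reference_point(self):
        params = BetaBinomParams(74, 76)
        got = betabinom_two_tailed_p(20, 100, params)
        assert got == pytest.approx(_oracle_two_tailed(20, 100, 74, 76), abs=1e-10)

    @pytest.mark.parametrize("n", [1, 7, 40, 113, 200])
    def test_matches_oracle_for_all_k(self, n):
        params = BetaBinomParams(74, 76)
        for k in range(n + 1):
            assert betabinom_two_tailed_p(k, n, params) == pytest.approx(
                _oracle_two_tailed(k, n, 74, 76), abs=1e-10
            )

    def test_mode_has_p_one(self):
        params = BetaBinomParams(74, 76)
        n = 60
        pmf = stats.betabinom.pmf(np.arange(n + 1), n, 74, 76)
        assert betabinom_two_tailed_p(int(pmf.argmax()), n, params) == pytest.approx(1.0)

    def test_symmetry_when_alpha_equals_beta(self):
        params = BetaBinomParams(30, 30)
        for n in (10, 55):
            for k in range(n + 1):
                assert betabinom_two_tailed_p(k, n, params) == pytest.approx(
                    betabinom_two_tailed_p(n - k, n, params), abs=1e-12
                )

    def test_monotone_away_from_mode(self):
        params = BetaBinomParams(74, 76)
        n = 120
        pvals = [betabinom_two_tailed_p(k, n, params) for k in range(n + 1)]
        mode = int(np.argmax(stats.betabinom.pmf(np.arange(n + 1), n, 74, 76)))
        for k in range(mode, n):
            assert pvals[k] >= pvals[k + 1] - 1e-12
        for k in range(mode, 0, -1):
            assert pvals[k] >= pvals[k - 1] - 1e-12

    def test_domain_validation(self):
        params = BetaBinomParams()
        with pytest.raises(ValueError):
            betabinom_two_tailed_p(5, 0, params)
        with pytest.raises(ValueError):
            betabinom_two_tailed_p(11, 10, params)

    def test_per_site_rejection_rate_near_nominal(self):
        """Simulated from the model at n=1100, the two-tailed test at
        p<0.01 rejects just under the nominal rate (discrete test); the
        exact rejection probability is ~0.0098."""
        rng = np.random.default_rng(42)
        n, sites = 1100, 4000
        ps = rng.beta(74, 76, sites)
        ks = rng.binomial(n, ps)
        params = BetaBinomParams(74, 76)
        rejected = sum(
            betabinom_two_tailed_p(int(k), n, params) < 0.01 for k in ks
        )
        rate = rejected / sites
        assert 0.004 <= rate <= 0.016


class TestFitBetaBinom:
    def test_parameter_recovery(self):
        """10,000 sites at n=1,100 from beta-binomial(74, 76): the fitted
        mean alpha/(alpha+beta) lands within 0.005 of 74/150."""
        rng = np.random.default_rng(11)
        n = 1100
        ps = rng.beta(74, 76, 10_000)
        ks = rng.binomial(n, ps)
        fitted = fit_betabinom([(int(k), n) for k in ks])
        mean = fitted.alpha / (fitted.alpha + fitted.beta)
        assert mean == pytest.approx(74 / 150, abs=0.005)
        assert fitted.alpha + fitted.beta == pytest.approx(150, rel=0.2)

    def test_symmetric_data_gives_symmetric_fit(self):
        rng = np.random.default_rng(5)
        n = 400
        ps = rng.beta(50, 50, 5000)
        ks = rng.binomial(n, ps)
        fitted = fit_betabinom([(int(k), n) for k in ks])
        assert abs(fitted.alpha - fitted.beta) / fitted.alpha < 0.05

    def test_pure_binomial_pushes_concentration_up(self):
        rng = np.random.default_rng(3)
        ks = rng.binomial(300, 0.5, 3000)
        fitted = fit_betabinom([(int(k), 300) for k in ks])
        assert fitted.alpha + fitted.beta > 1e4

    def test_degenerate_data_rejected(self):
        with pytest.raises(FitError):
            fit_betabinom([(0, 100)] * 50)
        with pytest.raises(FitError):
            fit_betabinom([])


# ---------------------------------------------------------------------------
# pileup counting on a hand-built BAM
# ---------------------------------------------------------------------------


@pytest.fixture()
def tiny_bam(tmp_path):
    """Hand-built alignments over a 60 bp contig around position 21-30.

    Read layout (1-based positions):
      r1 10M at 16..25: ref-matching, BQ 35
      r2 10M at 16..25: alt C at pos 21, BQ 35
      r3 10M at 16..25: alt C at pos 21, BQ 20 (below the BQ30 bar)
      r4 5S5M at 21..25: soft-clipped first 5 bases; aligned part starts pos 21
      r5 4M3D4M at 18..28: deletion spanning 22-24
      r6 5M2I5M at 17..26: insertion of 'TT' after pos 21
    """
    ref_seq = "A" * 60
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "c", "LN": 60}]}
    )
    fasta = tmp_path / "ref.fa"
    fasta.write_text(">c\n" + ref_seq + "\n")
    pysam.faidx(str(fasta))

    def read(name, start0, cigar, seq, bq):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = 0
        a.reference_id = 0
        a.reference_start = start0
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array(chr(bq + 33) * len(seq))
        return a

    reads = [
        read("r1", 15, "10M", "A" * 10, 35),
        read("r2", 15, "10M", "A" * 5 + "C" + "A" * 4, 35),
        read("r3", 15, "10M", "A" * 5 + "C" + "A" * 4, 20),
        read("r4", 20, "5S5M", "G" * 5 + "A" * 5, 35),
        read("r5", 17, "4M3D4M", "A" * 8, 35),
        read("r6", 16, "5M2I5M", "A" * 5 + "TT" + "A" * 5, 35),
    ]
    path = str(tmp_path / "tiny.bam")
    with pysam.AlignmentFile(path + ".u", "wb", header=header) as fh:
        for r in reads:
            fh.write(r)
    pysam.sort("-o", path, path + ".u")
    pysam.index(path)
    return path, str(fasta)


class TestPileup:
    def test_snv_counts_and_bq_stratification(self, tiny_bam):
        path, fasta = tiny_bam
        ref = pysam.FastaFile(fasta)
        (pc,) = pileup_positions(path, [("c", 21)], reference=ref)
        # r1..r6 all cover pos 21 through their aligned spans
        assert pc.depth == 6
        assert pc.ref == "A"
        assert pc.count_of("C") == (2, 1)  # r2 high-BQ, r3 low-BQ
        # r6 carries the insertion allele at the anchor
        assert pc.count_of("A+TT") == (1, 1)
        # non-ref alleles at 21: C (2,1), deletion A-3 (1,1), insertion A+TT (1,1)
        assert pc.alt_totals() == (4, 3)

    def test_soft_clip_invisible(self, tiny_bam):
        path, fasta = tiny_bam
        ref = pysam.FastaFile(fasta)
        # position 20: r4's clipped bases would sit here if clips counted
        (pc,) = pileup_positions(path, [("c", 20)], reference=ref)
        assert pc.depth == 5  # r1 r2 r3 r5 r6; r4's soft clip is invisible
        assert "G" not in pc.allele_counts

    def test_spanning_deletion_counts_depth_only(self, tiny_bam):
        path, fasta = tiny_bam
        ref = pysam.FastaFile(fasta)
        (pc,) = pileup_positions(path, [("c", 23)], reference=ref)
        # r5's deletion spans 22-24: depth includes it, alleles do not
        assert pc.depth == 6
        assert sum(t for t, _ in pc.allele_counts.values()) == 5

    def test_deletion_allele_at_anchor(self, tiny_bam):
        path, fasta = tiny_bam
        ref = pysam.FastaFile(fasta)
        (pc,) = pileup_positions(path, [("c", 21)], reference=ref)
        assert pc.count_of("A-3") == (1, 1)  # r5 anchors its deletion at 21

    def test_bounds_error(self, tiny_bam):
        path, _ = tiny_bam
        with pytest.raises(PileupBoundsError):
            pileup_positions(path, [("c", 500)])

    def test_alt_allele_key_forms(self):
        assert alt_allele_key(VariantSite("c", 5, "A", "G")) == "G"
        assert alt_allele_key(VariantSite("c", 5, "A", "ATT")) == "A+TT"
        assert alt_allele_key(VariantSite("c", 5, "ATTT", "A")) == "A-3"


# ---------------------------------------------------------------------------
# filters on synthesized PileupCounts
# ---------------------------------------------------------------------------


def _pc(chrom, pos, depth, alt_key=None, alt=0, alt_hq=None, ref="A"):
    counts = {}
    ref_reads = depth - alt
    if ref_reads > 0:
        counts[ref] = (ref_reads, ref_reads)
    if alt_key and alt > 0:
        counts[alt_key] = (alt, alt if alt_hq is None else alt_hq)
    return PileupCounts(chrom, pos, depth, counts, ref=ref)


SITE = VariantSite("chr1", 50, "A", "G")


def _records(product_ids, site=SITE, zyg=HET):
    from fractions import Fraction

    return [
        TruthRecord(site, "V1", zyg, Fraction(1, 25), pid) for pid in product_ids
    ]


class TestFilterPositive:
    def test_low_variant_coverage_removed(self):
        products = [f"P{i}" for i in range(10)]
        pileups = {
            pid: {("chr1", 50): _pc("chr1", 50, 100, "G", alt=(5 if i == 0 else 0))}
            for i, pid in enumerate(products)
        }
        (dec,) = filter_positive(_records(products), pileups)
        assert dec.verdict == "REMOVED"
        assert LOW_VARIANT_COVERAGE in dec.reason_codes

    @pytest.mark.parametrize("depth,verdict", [(39, "REMOVED"), (40, "RETAINED")])
    def test_mean_coverage_boundary_strict(self, depth, verdict):
        pileups = {"P0": {("chr1", 50): _pc("chr1", 50, depth, "G", alt=5)}}
        (dec,) = filter_positive(_records(["P0"]), pileups)
        assert dec.verdict == verdict

    def test_fractional_mean_just_below_threshold(self):
        pileups = {
            "P0": {("chr1", 50): _pc("chr1", 50, 39, "G", alt=4)},
            "P1": {("chr1", 50): _pc("chr1", 50, 40, "G", alt=4)},
        }
        (dec,) = filter_positive(_records(["P0", "P1"]), pileups)
        assert dec.verdict == "REMOVED" and LOW_COVERAGE in dec.reason_codes

    def test_fully_observed_deep_variant_retained(self):
        products = [f"P{i}" for i in range(5)]
        pileups = {
            pid: {("chr1", 50): _pc("chr1", 50, 1000, "G", alt=40)}
            for pid in products
        }
        (dec,) = filter_positive(_records(products), pileups)
        assert dec.verdict == "RETAINED" and dec.reason_codes == []

    def test_low_bq_alt_does_not_count_as_harbored(self):
        """Variant coverage requires high-BQ alt reads, not just any."""
        products = ["P0", "P1", "P2", "P3", "P4", "P5"]
        pileups = {
            pid: {("chr1", 50): _pc("chr1", 50, 100, "G", alt=5, alt_hq=0)}
            for pid in products
        }
        (dec,) = filter_positive(_records(products), pileups)
        assert LOW_VARIANT_COVERAGE in dec.reason_codes

    def test_missing_designed_pileup_is_error(self):
        with pytest.raises(DataCompletenessError):
            filter_positive(_records(["P0", "P1"]), {"P0": {("chr1", 50): _pc("chr1", 50, 100)}})

    def test_idempotent_on_retained(self):
        products = ["P0", "P1"]
        pileups = {
            pid: {("chr1", 50): _pc("chr1", 50, 200, "G", alt=10)} for pid in products
        }
        first = filter_positive(_records(products), pileups)
        survivors = retained_sites(first)
        again = filter_positive(
            [r for r in _records(products) if r.site in survivors], pileups
        )
        assert [d.verdict for d in again] == ["RETAINED"] * len(survivors)


class TestFilterNegativeSetA:
    POS = [("chr1", 10)]

    @pytest.mark.parametrize(
        "hq_alt,verdict", [(3, "RETAINED"), (4, "REMOVED")]
    )
    def test_more_than_three_hq_alt_boundary(self, hq_alt, verdict):
        pileups = {
            "P0": {("chr1", 10): _pc("chr1", 10, 100, "T", alt=hq_alt)},
            "P1": {("chr1", 10): _pc("chr1", 10, 100)},
        }
        (dec,) = filter_negative_setA(self.POS, pileups)
        assert dec.verdict == verdict
        if verdict == "REMOVED":
            assert dec.reason_codes == [ALT_EVIDENCE]

    def test_low_bq_alt_reads_tolerated(self):
        pileups = {"P0": {("chr1", 10): _pc("chr1", 10, 100, "T", alt=10, alt_hq=2)}}
        (dec,) = filter_negative_setA(self.POS, pileups)
        assert dec.verdict == "RETAINED"

    @pytest.mark.parametrize("depth,verdict", [(19, "REMOVED"), (20, "RETAINED")])
    def test_coverage_boundary(self, depth, verdict):
        pileups = {"P0": {("chr1", 10): _pc("chr1", 10, depth)}}
        (dec,) = filter_negative_setA(self.POS, pileups)
        assert dec.verdict == verdict


class TestFilterGermlineSetB:
    def _pileups(self, alt, depth, products=("P0", "P1")):
        return {
            pid: {("chr1", 50): _pc("chr1", 50, depth, "G", alt=alt)}
            for pid in products
        }

    def test_hom_below_09_removed(self):
        rec = GermlineRecord(SITE, HOM)
        (dec,) = filter_germline_setB([rec], self._pileups(alt=85, depth=100))
        assert LOW_HOM_VAF in dec.reason_codes

    def test_hom_at_09_retained(self):
        rec = GermlineRecord(SITE, HOM)
        (dec,) = filter_germline_setB([rec], self._pileups(alt=90, depth=100))
        assert dec.verdict == "RETAINED"

    def test_het_missing_in_one_product_removed(self):
        rec = GermlineRecord(SITE, HET)
        pileups = self._pileups(alt=50, depth=100)
        pileups["P1"] = {("chr1", 50): _pc("chr1", 50, 100)}  # zero alt reads
        (dec,) = filter_germline_setB([rec], pileups)
        assert MISSING in dec.reason_codes

    def test_het_at_model_center_retained(self):
        """Alt fraction ~ alpha/(alpha+beta) = 0.493 at depth 1,000 sits at
        the center of the allele-balance model and must survive."""
        rec = GermlineRecord(SITE, HET)
        (dec,) = filter_germline_setB([rec], self._pileups(alt=493, depth=1000))
        assert dec.verdict == "RETAINED"

    def test_het_extreme_imbalance_removed(self):
        rec = GermlineRecord(SITE, HET)
        (dec,) = filter_germline_setB([rec], self._pileups(alt=300, depth=1000))
        assert ALLELE_BALANCE in dec.reason_codes

    def test_any_product_failure_removes(self):
        rec = GermlineRecord(SITE, HET)
        pileups = self._pileups(alt=493, depth=1000)
        pileups["P1"] = {("chr1", 50): _pc("chr1", 50, 1000, "G", alt=300)}
        (dec,) = filter_germline_setB([rec], pileups)
        assert dec.verdict == "REMOVED"


def test_filter_decision_requires_reason_when_removed():
    with pytest.raises(ValueError):
        FilterDecision(("chr1", 1), "REMOVED", [])
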