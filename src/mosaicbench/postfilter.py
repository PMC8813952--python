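"""Post-filtration of candidate controls from per-site pileup counts.

Theoretically pre-fixed truth sets still have to survive contact with
the sequencing data: positions may be under-covered by the capture, a donor
variant may fail to show up in a given mixture, and the internal
reference's heterozygous sites wobble around VAF 0.5 with WES-typical
overdispersion.  This module finalizes the three control catalogues:

* positive controls — dropped when mean coverage across products falls
  below 40x or when the variant materializes (>= 1 high-quality alt
  read) in fewer than 20% of the products designed to carry it;
* non-variant negatives (set A) — dropped below 20x mean coverage or
  when any product shows more than three high-quality (BQ >= 30)
  alternate alleles, which flags a real subclone rather than sequencing
  noise;
* germline negatives (set B) — heterozygous sites must stay consistent
  with a beta-binomial allele-balance model (alpha=74, beta=76 fitted on
  internal-reference het SNPs; two-tailed p >= 0.01), homozygous sites
  must keep VAF >= 0.9, and a site missing from any product is dropped.

All boundary comparisons follow the printed inequalities literally:
strictly-below thresholds remove, exact-threshold values survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from scipy import optimize, stats

from .mix_design import TruthRecord
from .variants import Genotype, VariantSite


class PileupBoundsError(ValueError):
    """Requested position beyond the contig length."""


class DataCompletenessError(ValueError):
    """A product designed to harbor a variant has no pileup there."""


class FitError(ValueError):
    """Degenerate data for beta-binomial fitting."""


# ---------------------------------------------------------------------------
# Pileup counting
# ---------------------------------------------------------------------------


@dataclass
class PileupCounts:
    """Per-position depth and per-allele (total, high-BQ) counts.

    Allele keys: a plain base for SNVs, ``A+TT`` for an insertion after
    an ``A`` anchor, ``A-2`` for a two-base deletion after the anchor.
    Reads whose deletion spans the position count toward depth but carry
    no allele.  Soft/hard-clipped bases never contribute.
    """

    chrom: str
    pos: int  # 1-based
    depth: int
    allele_counts: dict[str, tuple[int, int]]
    ref: str | None = None

    def count_of(self, allele: str) -> tuple[int, int]:
        return self.allele_counts.get(allele, (0, 0))

    def alt_totals(self, ref: str | None = None) -> tuple[int, int]:
        """(total, high-BQ) reads carrying any non-reference allele."""
        ref_allele = ref or self.ref
        if ref_allele is None:
            raise ValueError(f"{self.chrom}:{self.pos}: reference allele unknown")
        total = hq = 0
        for allele, (t, h) in self.allele_counts.items():
            if allele != ref_allele:
                total += t
                hq += h
        return total, hq

    def vaf(self, allele: str) -> float:
        if self.depth == 0:
            return 0.0
        return self.count_of(allele)[0] / self.depth


def alt_allele_key(site: VariantSite) -> str:
    """Pileup allele key corresponding to a normalized variant site."""
    if site.is_snv:
        return site.alt
    if len(site.alt) > len(site.ref):  # insertion: anchor + inserted sequence
        return site.alt[0] + "+" + site.alt[1:]
    return site.ref[0] + "-" + str(len(site.ref) - len(site.alt))


def pileup_positions(
    alignment_path: str,
    positions: Sequence[tuple[str, int]],
    bq_threshold: int = 30,
    reference=None,
    max_depth: int = 1_000_000,
) -> list[PileupCounts]:
    """Count alleles at 1-based ``positions``, stratified by base quality.

    ``reference`` (a :class:`pysam.FastaFile`) annotates each position's
    reference base, which downstream negative-control filters need to
    tell alternate alleles apart.  Mirrors the samtools pileup
    convention: clipped bases are invisible, spanning deletions add depth
    but no allele; mate-overlap correction is left enabled.
    """
    results: list[PileupCounts] = []
    with pysam.AlignmentFile(alignment_path, "rb") as bam:
        lengths = dict(zip(bam.references, bam.lengths))
        for chrom, pos in positions:
            if chrom not in lengths or pos < 1 or pos > lengths[chrom]:
                raise PileupBoundsError(f"{chrom}:{pos} outside contig bounds")
            ref_base = None
            if reference is not None:
                ref_base = reference.fetch(chrom, pos - 1, pos).upper()
            depth = 0
            counts: dict[str, list[int]] = {}
            for col in bam.pileup(
                chrom,
                pos - 1,
                pos,
                truncate=True,
                min_base_quality=0,
                max_depth=max_depth,
            ):
                for pr in col.pileups:
                    if pr.is_refskip:
                        continue
                    depth += 1
                    if pr.is_del:
                        continue
                    read = pr.alignment
                    qpos = pr.query_position
                    base = read.query_sequence[qpos].upper()
                    bq = read.query_qualities[qpos]
                    if pr.indel > 0:
                        inserted = read.query_sequence[qpos + 1 : qpos + 1 + pr.indel]
                        allele = base + "+" + inserted.upper()
                    elif pr.indel < 0:
                        allele = base + "-" + str(-pr.indel)
                    else:
                        allele = base
                    entry = counts.setdefault(allele, [0, 0])
                    entry[0] += 1
                    if bq >= bq_threshold:
                        entry[1] += 1
            results.append(
                PileupCounts(
                    chrom=chrom,
                    pos=pos,
                    depth=depth,
                    allele_counts={k: (t, h) for k, (t, h) in counts.items()},
                    ref=ref_base,
                )
            )
    return results


def index_pileups(pileups: Iterable[PileupCounts]) -> dict[tuple[str, int], PileupCounts]:
    return {(p.chrom, p.pos): p for p in pileups}


# ---------------------------------------------------------------------------
# Beta-binomial allele-balance model
# ---------------------------------------------------------------------------


@dataclass
class BetaBinomParams:
    """Beta-binomial allele-balance model for heterozygous sites."""

    alpha: float = 74.0
    beta: float = 76.0
    p_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


def betabinom_two_tailed_p(k: int, n: int, params: BetaBinomParams) -> float:
    """Exact two-tailed beta-binomial p-value (minimum-likelihood sum).

    p = sum of P(j | n, alpha, beta) over all outcomes j whose pmf does
    not exceed the observed outcome's pmf — the standard two-tailed
    convention for a discrete exact test.
    """
    if n <= 0 or not 0 <= k <= n:
        raise ValueError(f"invalid k={k}, n={n}")
    j = np.arange(n + 1)
    pmf = stats.betabinom.pmf(j, n, params.alpha, params.beta)
    p = float(pmf[pmf <= pmf[k] * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


def fit_betabinom(
    het_observations: Sequence[tuple[int, int]],
    p_threshold: float = 0.01,
) -> BetaBinomParams:
    """Maximum-likelihood beta-binomial fit to het (alt count, depth) pairs.

    The fit is run on log-parameters with L-BFGS-B from a method-of-
    moments-flavoured start; pure-binomial data drives alpha+beta toward
    the optimizer's upper bound, which callers can treat as a
    no-overdispersion signal.
    """
    ks = np.array([k for k, _ in het_observations], dtype=float)
    ns = np.array([n for _, n in het_observations], dtype=float)
    if len(ks) == 0 or np.any(ks < 0) or np.any(ks > ns) or np.any(ns <= 0):
        raise FitError("invalid observations")
    if np.all(ks == 0) or np.all(ks == ns):
        raise FitError("degenerate data: all counts at a boundary")

    def nll(logab: np.ndarray) -> float:
        a, b = np.exp(logab)
        return -float(stats.betabinom.logpmf(ks, ns, a, b).sum())

    mean_p = float(np.sum(ks) / np.sum(ns))
    mean_p = min(max(mean_p, 1e-6), 1 - 1e-6)
    x0 = np.log([50.0 * mean_p, 50.0 * (1 - mean_p)])
    bound = (math.log(1e-3), math.log(1e7))
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=[bound, bound])
    alpha, beta = np.exp(res.x)
    return BetaBinomParams(float(alpha), float(beta), p_threshold)


# ---------------------------------------------------------------------------
# Filter decisions
# ---------------------------------------------------------------------------

RETAINED = "RETAINED"
REMOVED = "REMOVED"

LOW_COVERAGE = "LOW_COVERAGE"
LOW_VARIANT_COVERAGE = "LOW_VARIANT_COVERAGE"
ALT_EVIDENCE = "ALT_EVIDENCE"
ALLELE_BALANCE = "ALLELE_BALANCE"
LOW_HOM_VAF = "LOW_HOM_VAF"
MISSING = "MISSING"


@dataclass
class FilterDecision:
    site: tuple[str, int] | VariantSite
    verdict: str
    reason_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict == REMOVED and not self.reason_codes:
            raise ValueError("REMOVED requires at least one reason code")

    @property
    def retained(self) -> bool:
        return self.verdict == RETAINED


ProductPileups = Mapping[str, Mapping[tuple[str, int], PileupCounts]]


def _mean_depth_across_products(
    pileups: ProductPileups, key: tuple[str, int]
) -> float:
    depths = [prod[key].depth for prod in pileups.values() if key in prod]
    if not depths:
        return 0.0
    return sum(depths) / len(pileups)


def filter_positive(
    records: Sequence[TruthRecord],
    pileups: ProductPileups,
    min_mean_cov: float = 40.0,
    min_variant_cov: float = 0.2,
    min_alt_reads_present: int = 1,
) -> list[FilterDecision]:
    """Finalize positive controls by coverage and variant coverage.

    One decision per distinct site.  Mean depth is taken across *all*
    products; variant coverage is the fraction of products designed to
    harbor the variant in which it actually materializes (at least
    ``min_alt_reads_present`` high-BQ alt reads).
    """
    designed: dict[VariantSite, set[str]] = {}
    for rec in records:
        designed.setdefault(rec.site, set()).add(rec.product_id)

    decisions = []
    for site in sorted(designed):
        key = (site.chrom, site.pos)
        products = designed[site]
        missing = [p for p in products if key not in pileups.get(p, {})]
        if missing:
            raise DataCompletenessError(
                f"{site.key()}: no pileup for designed products {sorted(missing)}"
            )
        reasons = []
        if _mean_depth_across_products(pileups, key) < min_mean_cov:
            reasons.append(LOW_COVERAGE)
        allele = alt_allele_key(site)
        harbored = sum(
            1
            for p in products
            if pileups[p][key].count_of(allele)[1] >= min_alt_reads_present
        )
        if harbored / len(products) < min_variant_cov:
            reasons.append(LOW_VARIANT_COVERAGE)
        decisions.append(
            FilterDecision(site, REMOVED if reasons else RETAINED, reasons)
        )
    return decisions


def filter_negative_setA(
    candidates: Sequence[tuple[str, int]],
    pileups: ProductPileups,
    min_mean_cov: float = 20.0,
    max_hq_alt: int = 3,
) -> list[FilterDecision]:
    """Finalize set-A non-variant negatives.

    A candidate position is removed below ``min_mean_cov`` mean depth or
    when more than ``max_hq_alt`` high-BQ alternate alleles appear in any
    single product (the shared catalogue must be clean in all mixtures).
    """
    decisions = []
    for key in candidates:
        reasons = []
        if _mean_depth_across_products(pileups, key) < min_mean_cov:
            reasons.append(LOW_COVERAGE)
        for prod in pileups.values():
            pc = prod.get(key)
            if pc is not None and pc.alt_totals()[1] > max_hq_alt:
                reasons.append(ALT_EVIDENCE)
                break
        decisions.append(
            FilterDecision(key, REMOVED if reasons else RETAINED, reasons)
        )
    return decisions


@dataclass(frozen=True)
class GermlineRecord:
    """An internal-reference germline variant carried into every set-B file."""

    site: VariantSite
    zygosity: Genotype


def filter_germline_setB(
    germline_records: Sequence[GermlineRecord],
    pileups: ProductPileups,
    params: BetaBinomParams | None = None,
    hom_min_vaf: float = 0.9,
    min_mean_cov: float = 40.0,
) -> list[FilterDecision]:
    """Finalize set-B germline negatives.

    Heterozygous sites must pass the beta-binomial allele-balance test in
    every product (total alt reads vs depth, two-tailed p >= threshold);
    homozygous sites must keep VAF >= ``hom_min_vaf`` everywhere; any
    product with zero alt reads (variant coverage < 1) removes the site.
    """
    params = params or BetaBinomParams()
    decisions = []
    for rec in sorted(germline_records, key=lambda r: r.site):
        site = rec.site
        key = (site.chrom, site.pos)
        allele = alt_allele_key(site)
        reasons = []
        if _mean_depth_across_products(pileups, key) < min_mean_cov:
            reasons.append(LOW_COVERAGE)
        balance_fail = hom_fail = missing = False
        for prod in pileups.values():
            pc = prod.get(key)
            if pc is None or pc.count_of(allele)[0] == 0:
                missing = True
                continue
            alt_total = pc.count_of(allele)[0]
            if rec.zygosity is Genotype.HET and pc.depth > 0:
                if betabinom_two_tailed_p(alt_total, pc.depth, params) < params.p_threshold:
                    balance_fail = True
            if rec.zygosity is Genotype.HOM_ALT and pc.vaf(allele) < hom_min_vaf:
                hom_fail = True
        if balance_fail:
            reasons.append(ALLELE_BALANCE)
        if hom_fail:
            reasons.append(LOW_HOM_VAF)
        if missing:
            reasons.append(MISSING)
        decisions.append(
            FilterDecision(site, REMOVED if reasons else RETAINED, reasons)
        )
    return decisions


def retained_sites(decisions: Iterable[FilterDecision]) -> list:
    return [d.site for d in decisions if d.retained]


def write_decisions_tsv(path: str, decisions: Sequence[FilterDecision]) -> None:
    """Write a decision ledger: chrom, pos, (ref, alt,) verdict, reasons."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tverdict\treasons\n")
        for d in decisions:
            if isinstance(d.site, VariantSite):
                chrom, pos, ref, alt = d.site.key()
            else:
                chrom, pos = d.site
                ref = alt = "."
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{d.verdict}\t"
                f"{','.join(d.reason_codes) or '.'}\n"
            )
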