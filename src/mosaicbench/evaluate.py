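"""Scoring of mosaic-variant caller output against a finalized truth set.

Mosaic calling fails in two qualitatively different ways, and the dual
negative controls let us separate them: a call at a catalogued
non-variant site (set A) is an *artifact* false positive, while a call at
an internal-reference germline site (set B) is a *germline* false
positive — the caller mistook an inherited variant for a mosaic one.
Calls matching neither catalogue are tallied as FP_UNKNOWN and excluded
from rates, since the negative catalogues are explicit.

Concordance between designed and observed VAFs is measured the same way
the design is validated: positives are grouped by (variant type,
expected VAF), the median observed VAF per group is taken, and Pearson's
r is computed between log10(expected) and log10(median observed),
separately for SNVs and INDELs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .mix_design import TruthRecord
from .postfilter import PileupCounts, alt_allele_key
from .variants import VariantSite, VariantType

TP = "TP"
FN = "FN"
FP_ARTIFACT = "FP_ARTIFACT"
FP_GERMLINE = "FP_GERMLINE"
FP_UNKNOWN = "FP_UNKNOWN"

DEFAULT_VAF_BINS = (0.0, 0.01, 0.05, 0.10, 0.30, 1.0)


@dataclass(frozen=True)
class TruthSet:
    """The benchmark contract for one product.

    ``positives`` carry expected VAFs; ``negatives_setA`` are non-variant
    positions (artifact sentinels); ``negatives_setB`` are the internal
    reference's germline variants (germline-FP sentinels).
    """

    positives: tuple[TruthRecord, ...]
    negatives_setA: frozenset = frozenset()  # of (chrom, pos)
    negatives_setB: frozenset = frozenset()  # of VariantSite

    @classmethod
    def build(cls, positives, negatives_setA=(), negatives_setB=()):
        return cls(tuple(positives), frozenset(negatives_setA), frozenset(negatives_setB))


@dataclass
class CallMatch:
    call: VariantSite
    reported_vaf: float | None
    matched_truth: TruthRecord | None
    category: str


@dataclass
class EvalReport:
    counts: dict[str, int]
    matches: list[CallMatch]
    missed: list[TruthRecord]
    sensitivity_by_bin: dict[tuple[float, float], float | None] = field(
        default_factory=dict
    )
    warnings: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float | None:
        denom = self.counts[TP] + self.counts[FN]
        return self.counts[TP] / denom if denom else None


def score_calls(
    calls: Sequence[tuple[VariantSite, float | None]],
    truth: TruthSet,
    mode: str,
    bin_edges: Sequence[float] = DEFAULT_VAF_BINS,
) -> EvalReport:
    """Match caller output against the truth contract.

    ``calls`` are normalized (left-aligned, bi-allelic) sites with an
    optional reported VAF.  Matching is exact on (chrom, pos, ref, alt).
    ``mode`` selects which negative catalogue is in force: ``"setA"``
    (artifact sentinels at non-variant positions) or ``"setB"`` (germline
    sentinel variants).
    """
    if mode not in ("setA", "setB"):
        raise ValueError(f"mode must be setA or setB, got {mode!r}")
    by_site: dict[VariantSite, TruthRecord] = {r.site: r for r in truth.positives}
    truth_contigs = (
        {r.site.chrom for r in truth.positives}
        | {c for c, _ in truth.negatives_setA}
        | {s.chrom for s in truth.negatives_setB}
    )

    counts = {TP: 0, FN: 0, FP_ARTIFACT: 0, FP_GERMLINE: 0, FP_UNKNOWN: 0}
    matches: list[CallMatch] = []
    warnings: list[str] = []
    seen_positive: set[VariantSite] = set()
    for site, vaf in calls:
        rec = by_site.get(site)
        if rec is not None:
            category = TP
            seen_positive.add(site)
        elif mode == "setA" and (site.chrom, site.pos) in truth.negatives_setA:
            category = FP_ARTIFACT
        elif mode == "setB" and site in truth.negatives_setB:
            category = FP_GERMLINE
        else:
            category = FP_UNKNOWN
            if truth_contigs and site.chrom not in truth_contigs:
                warnings.append(f"call on contig {site.chrom} absent from truth")
        counts[category] += 1
        matches.append(CallMatch(site, vaf, rec, category))

    missed = [r for r in truth.positives if r.site not in seen_positive]
    counts[FN] = len(missed)
    report = EvalReport(counts=counts, matches=matches, missed=missed, warnings=warnings)
    report.sensitivity_by_bin = stratify_by_vaf(report, bin_edges)
    return report


def stratify_by_vaf(
    report: EvalReport, bin_edges: Sequence[float]
) -> dict[tuple[float, float], float | None]:
    """Per-bin sensitivity over half-open expected-VAF bins [lo, hi).

    Records with expected VAF outside every bin land in an overflow bin.
    Bins with no records report ``None``.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    bins = list(zip(edges, edges[1:]))
    tally: dict[tuple[float, float], list[int]] = {b: [0, 0] for b in bins}
    overflow = (float("nan"), float("nan"))

    def bin_of(vaf: float) -> tuple[float, float]:
        for lo, hi in bins:
            if lo <= vaf < hi:
                return (lo, hi)
        return overflow

    for match in report.matches:
        if match.category == TP and match.matched_truth is not None:
            b = bin_of(float(match.matched_truth.expected_vaf))
            tally.setdefault(b, [0, 0])[0] += 1
    for rec in report.missed:
        b = bin_of(float(rec.expected_vaf))
        tally.setdefault(b, [0, 0])[1] += 1
    return {
        b: (tp / (tp + fn) if tp + fn else None) for b, (tp, fn) in tally.items()
    }


# ---------------------------------------------------------------------------
# Expected-vs-observed VAF concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    pearson_r_snv: float | None
    pearson_r_indel: float | None
    p_snv: float | None
    p_indel: float | None
    medians: dict  # (vtype, expected_vaf) -> median observed VAF
    excluded_zero_median: list  # groups dropped from the log-scale fit


def _pearson_log10(groups: dict) -> tuple[float | None, float | None, list]:
    expected, observed, excluded = [], [], []
    for (evaf, median) in groups:
        if median <= 0:
            excluded.append(evaf)
            continue
        expected.append(math.log10(float(evaf)))
        observed.append(math.log10(median))
    if len(set(expected)) < 2:
        return None, None, excluded
    r, p = stats.pearsonr(expected, observed)
    return float(r), float(p), excluded


def vaf_concordance_from_observations(
    observations: Mapping[tuple[VariantType, object], Sequence[float]],
) -> ConcordanceReport:
    """Concordance from pre-grouped observed VAFs.

    ``observations`` maps (variant type, expected VAF) to the observed
    VAFs of all records/products at that design level.  The median per
    level enters a log10-log10 Pearson correlation, separately for SNVs
    and INDELs; levels whose median is zero cannot enter the log fit and
    are reported in ``excluded_zero_median``.
    """
    medians = {
        key: float(np.median(vals)) for key, vals in observations.items() if len(vals)
    }
    per_type: dict[VariantType, list] = {VariantType.SNV: [], VariantType.INDEL: []}
    for (vtype, evaf), med in medians.items():
        per_type[VariantType(vtype)].append((evaf, med))
    r_snv, p_snv, excl_snv = _pearson_log10(per_type[VariantType.SNV])
    r_indel, p_indel, excl_indel = _pearson_log10(per_type[VariantType.INDEL])
    return ConcordanceReport(
        pearson_r_snv=r_snv,
        pearson_r_indel=r_indel,
        p_snv=p_snv,
        p_indel=p_indel,
        medians=medians,
        excluded_zero_median=[(VariantType.SNV, e) for e in excl_snv]
        + [(VariantType.INDEL, e) for e in excl_indel],
    )


def vaf_concordance(
    truth: Sequence[TruthRecord],
    pileups: Mapping[str, Mapping[tuple[str, int], "PileupCounts"]],
) -> ConcordanceReport:
    """Concordance of designed vs observed VAFs from per-product pileups.

    Each positive record contributes one observed VAF (alt reads / depth)
    per product designed to carry it; groups pool all products.
    """
    observations: dict[tuple[VariantType, object], list[float]] = {}
    for rec in truth:
        prod = pileups.get(rec.product_id)
        if prod is None:
            continue
        pc = prod.get((rec.site.chrom, rec.site.pos))
        if pc is None or pc.depth == 0:
            continue
        obs = pc.count_of(alt_allele_key(rec.site))[0] / pc.depth
        observations.setdefault((rec.site.vtype, rec.expected_vaf), []).append(obs)
    if len({evaf for _, evaf in observations}) < 2:
        raise ValueError("need at least two distinct expected-VAF levels")
    return vaf_concordance_from_observations(observations)


def report_to_dict(report: EvalReport) -> dict:
    """JSON-ready summary of an evaluation report."""
    return {
        "counts": dict(report.counts),
        "sensitivity": report.sensitivity,
        "sensitivity_by_bin": {
            f"[{lo},{hi})": s for (lo, hi), s in report.sensitivity_by_bin.items()
        },
        "warnings": list(report.warnings),
    }
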