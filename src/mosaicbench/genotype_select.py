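"""Selection of mutually exclusive variant sets and negative-control candidates.

The benchmark construction rests on germline variants that are private to
one constituent sample: when that sample is diluted into an internal
reference, its private variants appear at sub-germline allele frequencies
and behave exactly like mosaic mutations.  This module derives those
private sets (one ``ExclusiveVariantSet`` per sample, V1..Vn) from
dual-caller genotype data under three criteria:

1. the variant is called by *both* callers with passing filters and
   concordant zygosity in its owner sample;
2. every other sample is explicitly genotyped reference homozygous there
   (a no-call is not good enough — absence of evidence would poison the
   truth set);
3. the site shows no sign of copy-number alteration in *any* sample
   (|log2 ratio| below a threshold everywhere), so the diploid VAF
   arithmetic holds.

It also collects the complementary catalogue: targeted positions that are
explicitly reference homozygous in *all* samples, which become candidates
for the non-variant negative controls.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variants import (
    Genotype,
    GenotypeCall,
    VariantSite,
    VariantType,
    bed_to_positions,
)


class CallsetFormatError(ValueError):
    """Malformed callset input (e.g. duplicate site keys)."""


class ConfigurationError(ValueError):
    """Inconsistent multi-sample configuration."""


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------


@dataclass
class CNSegmentSet:
    """Copy-number segments as (chrom, start, end, log2_ratio), 1-based inclusive."""

    segments: list[tuple[str, int, int, float]]
    _index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, log2 in self.segments:
            by_chrom.setdefault(chrom, []).append((start, end, float(log2)))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ConfigurationError(
                        f"overlapping CN segments on {chrom} near {s2}"
                    )
            self._index[chrom] = ([s for s, _, _ in segs], segs)

    def log2_at(self, chrom: str, pos: int) -> float | None:
        """log2 ratio of the segment covering ``pos``, or None if uncovered."""
        entry = self._index.get(chrom)
        if entry is None:
            return None
        starts, segs = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        start, end, log2 = segs[i]
        return log2 if start <= pos <= end else None

    @classmethod
    def read_tsv(cls, path: str) -> "CNSegmentSet":
        """Read a cnvkit-style segment table: chrom, start, end, log2."""
        segs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("chrom", "chromosome"):
                    continue
                segs.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        return cls(segs)


# ---------------------------------------------------------------------------
# Dual-caller consensus
# ---------------------------------------------------------------------------


class ConsensusGenotypes:
    """Consensus genotype map for one sample.

    Holds HET/HOM_ALT calls keyed by normalized site plus the set of
    positions with explicit dual-caller REF_HOM assertions.  A position
    carrying any variant call is never REF_HOM, even for a different alt
    allele at the same coordinate.
    """

    def __init__(
        self,
        variant_calls: Mapping[VariantSite, Genotype],
        ref_hom_positions: Iterable[tuple[str, int]],
    ) -> None:
        self.variant_calls = dict(variant_calls)
        self.ref_hom_positions = set(ref_hom_positions)
        self._variant_positions = {(s.chrom, s.pos) for s in self.variant_calls}

    def genotype_of(self, site: VariantSite) -> Genotype:
        """Consensus genotype of the sample with respect to ``site``."""
        got = self.variant_calls.get(site)
        if got is not None:
            return got
        if (site.chrom, site.pos) in self._variant_positions:
            return Genotype.NO_CALL  # different alt at same position: not REF_HOM
        if (site.chrom, site.pos) in self.ref_hom_positions:
            return Genotype.REF_HOM
        return Genotype.NO_CALL

    def genotype_at(self, chrom: str, pos: int) -> Genotype:
        """Positional consensus: REF_HOM only for clean explicit assertions."""
        if (chrom, pos) in self._variant_positions:
            return Genotype.NO_CALL
        if (chrom, pos) in self.ref_hom_positions:
            return Genotype.REF_HOM
        return Genotype.NO_CALL

    def variant_sites(self) -> list[VariantSite]:
        return sorted(self.variant_calls)


def _index_calls(calls: Sequence[GenotypeCall]):
    variants: dict[VariantSite, GenotypeCall] = {}
    ref_hom: set[tuple[str, int]] = set()
    for call in calls:
        if call.site is not None:
            if call.site in variants:
                raise CallsetFormatError(
                    f"duplicate site {call.site.key()} in callset {call.caller_id}"
                )
            variants[call.site] = call
        elif call.genotype is Genotype.REF_HOM:
            ref_hom.add((call.chrom, call.pos))
    return variants, ref_hom


def consensus_genotype(
    calls_a: Sequence[GenotypeCall], calls_b: Sequence[GenotypeCall]
) -> ConsensusGenotypes:
    """Merge two callers' calls for one sample into consensus genotypes.

    A site is HET or HOM_ALT only when both callers report it with
    passing filters and identical zygosity; zygosity disagreement, a
    failing filter, or single-caller support all collapse to NO_CALL.
    A position is REF_HOM only when both callers explicitly assert it
    and neither reports a variant there.
    """
    var_a, ref_a = _index_calls(calls_a)
    var_b, ref_b = _index_calls(calls_b)

    consensus: dict[VariantSite, Genotype] = {}
    disputed_positions: set[tuple[str, int]] = set()
    for site in set(var_a) | set(var_b):
        ca, cb = var_a.get(site), var_b.get(site)
        disputed_positions.add((site.chrom, site.pos))
        if ca is None or cb is None:
            continue
        if not (ca.passed_filter and cb.passed_filter):
            continue
        if ca.genotype is not cb.genotype:
            continue
        consensus[site] = ca.genotype

    ref_hom = {
        p for p in ref_a & ref_b if p not in disputed_positions
    }
    return ConsensusGenotypes(consensus, ref_hom)


# ---------------------------------------------------------------------------
# Mutually exclusive variant sets
# ---------------------------------------------------------------------------

SEX_CHROMOSOMES = ("chrX", "chrY", "X", "Y")


@dataclass
class ExclusiveVariantSet:
    """Variants private to ``owner_sample``: PASS in the owner, REF_HOM elsewhere."""

    owner_sample: str
    records: list[tuple[VariantSite, Genotype]]

    def sites(self) -> set[VariantSite]:
        return {site for site, _ in self.records}

    def __len__(self) -> int:
        return len(self.records)


def select_exclusive_variants(
    samples: Mapping[str, ConsensusGenotypes],
    cn: Mapping[str, CNSegmentSet],
    excluded_chroms: Sequence[str] = SEX_CHROMOSOMES,
    cn_threshold: float = 0.3,
) -> dict[str, ExclusiveVariantSet]:
    """Derive one mutually exclusive variant set per sample.

    A site enters sample *s*'s set iff it is consensus HET/HOM_ALT in *s*,
    explicitly REF_HOM in every other sample, lies in a copy-number
    segment with |log2| < ``cn_threshold`` in *every* sample (positions
    not covered by any segment are conservatively excluded), and its
    chromosome is not excluded.  The resulting sets are disjoint by
    construction.
    """
    if len(samples) < 2:
        raise ConfigurationError("need at least two samples")
    missing = set(samples) - set(cn)
    if missing:
        raise ConfigurationError(f"samples missing CN segments: {sorted(missing)}")
    excluded = set(excluded_chroms)

    result = {
        sid: ExclusiveVariantSet(owner_sample=sid, records=[])
        for sid in samples
    }
    for sid, geno in samples.items():
        others = [(oid, samples[oid]) for oid in samples if oid != sid]
        for site, zyg in sorted(geno.variant_calls.items()):
            if site.chrom in excluded:
                continue
            if any(
                other.genotype_of(site) is not Genotype.REF_HOM for _, other in others
            ):
                continue
            cn_ok = True
            for oid in samples:
                log2 = cn[oid].log2_at(site.chrom, site.pos)
                if log2 is None or abs(log2) >= cn_threshold:
                    cn_ok = False
                    break
            if cn_ok:
                result[sid].records.append((site, zyg))
    return result


def rescue_single_caller_indels(
    raw_calls: Mapping[str, Mapping[str, Sequence[GenotypeCall]]],
    accept_list: Iterable[tuple[str, VariantSite]] = (),
) -> tuple[list[tuple[str, VariantSite]], list[tuple[str, VariantSite]]]:
    """Flag single-caller INDELs for manual review; promote accepted ones.

    INDEL concordance between callers is low, so INDELs called PASS by
    exactly one of the two callers in exactly one sample — with both
    callers asserting REF_HOM in every other sample — are emitted with a
    NEEDS_REVIEW flag.  They are never auto-promoted: only entries on the
    caller-supplied ``accept_list`` are returned as promotable.

    Returns ``(needs_review, promoted)``.
    """
    indexed: dict[str, list[tuple[dict, set]]] = {}
    for sid, per_caller in raw_calls.items():
        indexed[sid] = [_index_calls(calls) for calls in per_caller.values()]

    flagged: list[tuple[str, VariantSite]] = []
    for sid, callsets in indexed.items():
        if len(callsets) != 2:
            raise ConfigurationError(f"sample {sid}: expected exactly two callsets")
        (var_a, _), (var_b, _) = callsets
        for site in set(var_a) | set(var_b):
            if site.vtype is not VariantType.INDEL:
                continue
            ca, cb = var_a.get(site), var_b.get(site)
            single = (ca is None) != (cb is None)
            if not single:
                continue
            call = ca or cb
            if not call.passed_filter:
                continue
            ok = True
            for oid, other_sets in indexed.items():
                if oid == sid:
                    continue
                for o_var, o_ref in other_sets:
                    if site in o_var or (site.chrom, site.pos) not in o_ref:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                flagged.append((sid, site))
    flagged.sort()
    accepted = set(accept_list)
    promoted = [entry for entry in flagged if entry in accepted]
    return flagged, promoted


def select_negative_candidates(
    samples: Mapping[str, ConsensusGenotypes],
    target_regions: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int]]:
    """Collect targeted positions explicitly REF_HOM in every sample.

    ``target_regions`` follow the BED convention (0-based half-open);
    returned positions are 1-based.  Any NO_CALL or variant evidence in
    any sample excludes the position.
    """
    out = []
    genos = list(samples.values())
    for chrom, pos in bed_to_positions(target_regions):
        if all(g.genotype_at(chrom, pos) is Genotype.REF_HOM for g in genos):
            out.append((chrom, pos))
    return out
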