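"""Normalized variant sites, genotype calls, and VCF I/O helpers.

A :class:`VariantSite` is the atomic unit shared by every stage of the
toolkit: selection of mutually exclusive germline variants, truth-set
assembly, post-filtration and caller scoring all key on the normalized
``(chrom, pos, ref, alt)`` tuple.  INDELs are parsimony-trimmed and
(when a reference sequence is available) left-aligned before any
comparison, so that the same mutation is always spelled the same way
regardless of which caller emitted it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping, Sequence

SequenceLookup = Callable[[str, int, int], str]
"""Maps ``(chrom, start0, end0)`` half-open 0-based slices to sequence."""


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Genotype(str, enum.Enum):
    """Diploid genotype states.

    ``REF_HOM`` is an explicit assertion that the sample is reference
    homozygous at a position — deliberately distinct from ``NO_CALL``
    (absence of evidence), because truth-set construction requires
    positive confirmation of the reference state in non-carrier samples.
    """

    REF_HOM = "REF_HOM"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    NO_CALL = "NO_CALL"


class NormalizationError(ValueError):
    """Raised for alleles that cannot be normalized (empty, non-ACGTN...)."""


_VALID_BASES = frozenset("ACGTNacgtn")


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim a ref/alt allele pair.

    Removes shared trailing bases, then shared leading bases (advancing
    ``pos``), always keeping at least one base in each allele so INDELs
    retain their anchor base.
    """
    if not ref or not alt:
        raise NormalizationError("empty allele")
    if not (_VALID_BASES.issuperset(ref) and _VALID_BASES.issuperset(alt)):
        raise NormalizationError(f"non-nucleotide allele {ref!r}/{alt!r}")
    ref, alt = ref.upper(), alt.upper()
    # shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix (keep one anchor base)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(
    chrom: str, pos: int, ref: str, alt: str, reference: SequenceLookup
) -> tuple[int, str, str]:
    """Shift a trimmed INDEL to its leftmost equivalent representation.

    Uses the standard normalization loop (chop a shared trailing base;
    when an allele empties, extend both alleles leftward with the
    preceding reference base), then re-applies the anchor convention.
    SNVs and complex substitutions are returned trim-normalized only.
    """
    pos, ref, alt = trim_alleles(pos, ref, alt)
    if len(ref) == len(alt):
        return pos, ref, alt
    r, a = ref, alt
    while True:
        if r and a and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        elif (not r or not a) and pos > 1:
            prev = reference(chrom, pos - 2, pos - 1)
            if not prev:
                break
            prev = prev.upper()
            r, a = prev + r, prev + a
            pos -= 1
        else:
            break
    if not r or not a:
        # event abuts the contig start: anchor on the following base
        nxt = reference(chrom, pos - 1 + max(len(r), len(a)), pos + max(len(r), len(a)))
        r, a = r + nxt.upper(), a + nxt.upper()
    return trim_alleles(pos, r, a)


def fasta_lookup(fasta) -> SequenceLookup:
    """Adapt a :class:`pysam.FastaFile` to the slice-lookup protocol."""

    def lookup(chrom: str, start: int, end: int) -> str:
        if start < 0:
            return ""
        return fasta.fetch(chrom, start, end)

    return lookup


@dataclass(frozen=True, order=True)
class VariantSite:
    """A normalized bi-allelic variant: 1-based position, trimmed alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        pos, ref, alt = trim_alleles(self.pos, self.ref, self.alt)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)

    @property
    def vtype(self) -> VariantType:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantType.SNV
        return VariantType.INDEL

    @property
    def is_snv(self) -> bool:
        return self.vtype is VariantType.SNV

    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive span of the reference allele."""
        return self.pos, self.pos + len(self.ref) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    """One caller's genotype assertion.

    ``site`` is ``None`` for positional REF_HOM assertions (reference
    homozygosity is a property of the position, not of a specific alt
    allele); variant calls (HET / HOM_ALT) always carry a site.
    """

    chrom: str
    pos: int
    genotype: Genotype
    passed_filter: bool
    caller_id: str
    site: VariantSite | None = None

    def __post_init__(self) -> None:
        if self.genotype in (Genotype.HET, Genotype.HOM_ALT) and self.site is None:
            raise ValueError("variant genotype requires a site")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_PASS_FILTERS = (None, "PASS", ".")


def read_vcf_calls(
    path: str,
    caller_id: str,
    reference=None,
) -> list[GenotypeCall]:
    """Read a single-sample VCF into genotype calls.

    Multi-allelic records are split into bi-allelic sites; each alt's
    genotype is derived from the sample GT.  ``0/0`` records are kept as
    explicit positional REF_HOM assertions.  FILTER of PASS or '.' counts
    as passed.  If ``reference`` (a pysam.FastaFile) is given, INDELs are
    left-aligned on read.
    """
    import cyvcf2

    lookup = fasta_lookup(reference) if reference is not None else None
    calls: list[GenotypeCall] = []
    vcf = cyvcf2.VCF(path)
    try:
        sites_only = len(vcf.samples) == 0
        for rec in vcf:
            passed = rec.FILTER in _PASS_FILTERS
            if sites_only:
                # catalogue VCF (no sample columns): every ALT is a variant,
                # zygosity from INFO ZYG when annotated
                zyg = (
                    Genotype.HOM_ALT
                    if (rec.INFO.get("ZYG") or "HET") == "HOM"
                    else Genotype.HET
                )
                for alt in rec.ALT:
                    pos, ref_a, alt_a = rec.POS, rec.REF, alt
                    if lookup is not None:
                        pos, ref_a, alt_a = left_align(rec.CHROM, pos, ref_a, alt_a, lookup)
                    site = VariantSite(rec.CHROM, pos, ref_a, alt_a)
                    calls.append(
                        GenotypeCall(site.chrom, site.pos, zyg, passed, caller_id, site)
                    )
                continue
            gt = rec.genotypes[0] if rec.genotypes else [-1, -1, False]
            alleles = [a for a in gt[:-1] if a is not None]
            if not alleles or all(a < 0 for a in alleles):
                continue  # no-call: absence, never an assertion
            if all(a == 0 for a in alleles):
                calls.append(
                    GenotypeCall(rec.CHROM, rec.POS, Genotype.REF_HOM, passed, caller_id)
                )
                continue
            for alt_index, alt in enumerate(rec.ALT, start=1):
                n_alt = sum(1 for a in alleles if a == alt_index)
                if n_alt == 0:
                    continue
                genotype = Genotype.HOM_ALT if n_alt == len(alleles) else Genotype.HET
                pos, ref_a, alt_a = rec.POS, rec.REF, alt
                if lookup is not None:
                    pos, ref_a, alt_a = left_align(rec.CHROM, pos, ref_a, alt_a, lookup)
                site = VariantSite(rec.CHROM, pos, ref_a, alt_a)
                calls.append(
                    GenotypeCall(site.chrom, site.pos, genotype, passed, caller_id, site)
                )
    finally:
        vcf.close()
    return calls


def write_vcf(
    path: str,
    records: Iterable[tuple[VariantSite, Mapping[str, object]]],
    contigs: Mapping[str, int],
    info_fields: Sequence[tuple[str, str, str, str]] = (),
) -> None:
    """Write sites with INFO annotations to an (uncompressed) VCF.

    ``info_fields`` are (id, number, type, description) tuples declared in
    the header; ``records`` yields (site, {info_id: value}).
    """
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for fid, number, ftype, desc in info_fields:
        header.info.add(fid, number, ftype, desc)
    with pysam.VariantFile(path, "w", header=header) as out:
        for site, info in sorted(records, key=lambda r: r[0]):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
            )
            for k, v in info.items():
                rec.info[k] = v
            out.write(rec)


def write_genotyped_vcf(
    path: str,
    calls: Sequence[GenotypeCall],
    contigs: Mapping[str, int],
    sample_name: str,
    reference_bases: Mapping[tuple[str, int], str] | None = None,
) -> None:
    """Write a single-sample VCF with GT, including explicit 0/0 records.

    REF_HOM assertions need a REF allele; ``reference_bases`` supplies it
    per position (defaulting to N when absent).
    """
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", "1", "String", "Genotype")
    header.add_sample(sample_name)
    _GT = {
        Genotype.REF_HOM: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
    }

    def sort_key(call: GenotypeCall):
        return (call.chrom, call.pos, call.site.alt if call.site else "")

    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(calls, key=sort_key):
            if call.genotype is Genotype.NO_CALL:
                continue
            if call.site is not None:
                alleles = (call.site.ref, call.site.alt)
                stop = call.pos - 1 + len(call.site.ref)
            else:
                base = None
                if reference_bases is not None:
                    base = reference_bases.get((call.chrom, call.pos))
                alleles = (base or "N", "<NON_REF>")
                stop = call.pos
            rec = out.new_record(
                contig=call.chrom, start=call.pos - 1, stop=stop, alleles=alleles
            )
            rec.samples[sample_name]["GT"] = _GT[call.genotype]
            rec.samples[sample_name].phased = False
            out.write(rec)


def read_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    """Read BED (0-based half-open) intervals as (chrom, start, end)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_bed(path: str, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def bed_to_positions(intervals: Iterable[tuple[str, int, int]]) -> Iterator[tuple[str, int]]:
    """Expand half-open 0-based intervals to 1-based positions."""
    for chrom, start, end in intervals:
        for pos0 in range(start, end):
            yield chrom, pos0 + 1
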