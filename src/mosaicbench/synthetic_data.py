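"""Fully synthetic inputs: reference, genotypes, callsets, CN tables, reads.

Everything the toolkit consumes can be generated here at desk scale, so
the whole pipeline — exclusive-variant selection, mixture design,
in-silico mixing, post-filtration and scoring — runs without any
downloads.  The generator emulates the study design: several diploid
samples carrying mutually exclusive private variants plus a common
germline background, genotyped by two simulated callers, sequenced as
paired-end reads at known depth.

Reads are written pre-aligned (coordinates are known by construction, so
no aligner is involved): correct CIGARs including INDEL-spanning reads,
per-base errors at a configurable rate, and base qualities drawn so that
roughly 93% of bases are at or above BQ 30.  Heterozygous variants are
emitted on a per-fragment coin flip (unphased), which is adequate because
planted variants are spaced beyond fragment length.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pysam

from .genotype_select import CNSegmentSet, ExclusiveVariantSet
from .mix_design import REFERENCE_GERMLINE_COUNTS, REFERENCE_VSET_COUNTS
from .variants import Genotype, GenotypeCall, VariantSite, left_align

_BASES = np.array(list("ACGT"))
BQ_HIGH = 37
BQ_LOW = 20
LOW_BQ_RATE = 0.07  # leaves ~93% of bases at BQ >= 30


class CapacityError(ValueError):
    """More variants requested than the spacing constraint can place."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults describe the desk-scale analogue of the design this toolkit
    models: six diploid samples on a 100 kb single-contig genome, each
    with 50 private variants and a shared germline background, het:hom
    5:1, 10% INDELs, 100 bp paired reads at ~300 bp inserts.
    """

    genome_length: int = 100_000
    n_samples: int = 6
    unique_per_sample: int = 50
    shared_germline: int = 40
    indel_fraction: float = 0.1
    depth: float = 100.0
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    base_error_rate: float = 0.001
    gc_target: float = 0.5
    seed: int = 0
    chrom: str = "chr1"
    het_hom_ratio: float = 5.0
    caller_dropout: float = 0.0
    caller_zygosity_error: float = 0.0

    def __post_init__(self) -> None:
        for name in ("indel_fraction", "base_error_rate", "gc_target",
                     "caller_dropout", "caller_zygosity_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def min_spacing(self) -> int:
        return 2 * self.read_length


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config_seed & 0x7FFFFFFF, stream])


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------


def make_reference(config: SimConfig) -> str:
    """Random single-contig sequence with GC fraction ~ ``gc_target``."""
    if config.genome_length < 10 * config.read_length:
        raise ValueError(
            f"genome_length {config.genome_length} < 10x read_length"
        )
    rng = _rng(config.seed, 1)
    gc = config.gc_target
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=config.genome_length, p=probs)
    return "".join(seq)


def write_fasta(path: str, name: str, sequence: str) -> str:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
    pysam.faidx(path)
    return path


# ---------------------------------------------------------------------------
# Genotypes, callsets and CN segments
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """Planted truth plus the derived noisy inputs for one synthetic study."""

    config: SimConfig
    reference: str
    truth: dict[str, dict[VariantSite, Genotype]]  # per-sample genotypes
    unique_sites: dict[str, dict[VariantSite, Genotype]]  # private subsets
    shared_sites: dict[VariantSite, Genotype]
    callsets: dict[str, dict[str, list[GenotypeCall]]]
    cn: dict[str, CNSegmentSet]
    targets: list[tuple[str, int, int]]

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.truth)


def _make_variant(
    rng: np.random.Generator,
    reference: str,
    chrom: str,
    pos: int,
    is_indel: bool,
) -> VariantSite:
    """Plant one variant at a 1-based anchor position, left-aligned."""
    anchor = reference[pos - 1]
    if not is_indel:
        alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
        return VariantSite(chrom, pos, anchor, alt)
    size = int(rng.integers(1, 4))
    lookup = lambda c, s, e: reference[max(s, 0) : e]  # noqa: E731
    if rng.random() < 0.5:  # insertion
        inserted = "".join(rng.choice(_BASES, size=size))
        p, r, a = left_align(chrom, pos, anchor, anchor + inserted, lookup)
    else:  # deletion
        deleted = reference[pos : pos + size]
        p, r, a = left_align(chrom, pos, anchor + deleted, anchor, lookup)
    return VariantSite(chrom, p, r, a)


def _zygosity(rng: np.random.Generator, het_hom_ratio: float) -> Genotype:
    p_het = het_hom_ratio / (het_hom_ratio + 1.0)
    return Genotype.HET if rng.random() < p_het else Genotype.HOM_ALT


def make_sample_genotypes(
    config: SimConfig,
    reference: str,
    aberrant_segments: Mapping[str, Sequence[tuple[int, int, float]]] | None = None,
) -> SimulatedCohort:
    """Plant per-sample private variants, shared germline, and derive inputs.

    Every sample gets ``unique_per_sample`` private variants plus the
    common ``shared_germline`` background (het:hom ~ 5:1, INDELs at
    ``indel_fraction``).  Two pseudo-callers are derived from the truth
    with the configured dropout and zygosity-error rates; both emit
    explicit REF_HOM assertions at all planted positions where the
    sample carries no variant and across the target regions.  CN tables
    are flat (log2 = 0) except for explicitly planted aberrant segments.
    """
    rng = _rng(config.seed, 2)
    chrom = config.chrom
    spacing = config.min_spacing + 12  # head room for indel spans
    margin = config.read_length
    slots = np.arange(margin + 1, config.genome_length - margin - 12, spacing)
    n_needed = config.n_samples * config.unique_per_sample + config.shared_germline
    if n_needed > len(slots):
        raise CapacityError(
            f"{n_needed} variants do not fit {len(slots)} spaced slots"
        )
    chosen = rng.permutation(slots)[:n_needed]

    sample_ids = [f"S{i}" for i in range(config.n_samples)]
    shared_sites: dict[VariantSite, Genotype] = {}
    unique_sites = {sid: {} for sid in sample_ids}
    cursor = 0
    for _ in range(config.shared_germline):
        site = _make_variant(
            rng, reference, chrom, int(chosen[cursor]),
            rng.random() < config.indel_fraction,
        )
        shared_sites[site] = _zygosity(rng, config.het_hom_ratio)
        cursor += 1
    for sid in sample_ids:
        for _ in range(config.unique_per_sample):
            site = _make_variant(
                rng, reference, chrom, int(chosen[cursor]),
                rng.random() < config.indel_fraction,
            )
            unique_sites[sid][site] = _zygosity(rng, config.het_hom_ratio)
            cursor += 1

    truth = {
        sid: {**shared_sites, **unique_sites[sid]} for sid in sample_ids
    }

    # target regions: windows over the planted loci plus clean windows
    all_positions = sorted(p for s in truth.values() for p in {v.pos for v in s})
    targets = [(chrom, max(0, p - 3), p + 3) for p in all_positions[:: max(1, len(all_positions) // 40)]]
    clean_start = int(slots[-1]) + spacing
    if clean_start + 60 < config.genome_length:
        targets.append((chrom, clean_start, clean_start + 50))

    all_sites = sorted({s for t in truth.values() for s in t})
    callsets: dict[str, dict[str, list[GenotypeCall]]] = {}
    for sid in sample_ids:
        callsets[sid] = {}
        for caller in ("callerA", "callerB"):
            calls: list[GenotypeCall] = []
            sample_truth = truth[sid]
            variant_positions = {s.pos for s in sample_truth}
            for site in all_sites:
                zyg = sample_truth.get(site)
                if zyg is not None:
                    if rng.random() < config.caller_dropout:
                        continue
                    if rng.random() < config.caller_zygosity_error:
                        zyg = (
                            Genotype.HOM_ALT
                            if zyg is Genotype.HET
                            else Genotype.HET
                        )
                    calls.append(
                        GenotypeCall(chrom, site.pos, zyg, True, caller, site)
                    )
                elif site.pos not in variant_positions:
                    calls.append(
                        GenotypeCall(chrom, site.pos, Genotype.REF_HOM, True, caller)
                    )
            for tchrom, start, end in targets:
                for pos in range(start + 1, end + 1):
                    if pos not in variant_positions:
                        calls.append(
                            GenotypeCall(tchrom, pos, Genotype.REF_HOM, True, caller)
                        )
            callsets[sid][caller] = calls

    aberrant = aberrant_segments or {}
    cn: dict[str, CNSegmentSet] = {}
    for sid in sample_ids:
        segs = []
        planted = sorted(aberrant.get(sid, ()))
        cursor_pos = 1
        for start, end, log2 in planted:
            if start > cursor_pos:
                segs.append((chrom, cursor_pos, start - 1, 0.0))
            segs.append((chrom, start, end, float(log2)))
            cursor_pos = end + 1
        if cursor_pos <= config.genome_length:
            segs.append((chrom, cursor_pos, config.genome_length, 0.0))
        cn[sid] = CNSegmentSet(segs)

    return SimulatedCohort(
        config=config,
        reference=reference,
        truth=truth,
        unique_sites=unique_sites,
        shared_sites=shared_sites,
        callsets=callsets,
        cn=cn,
        targets=targets,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

# fragment alignment segments: ("M", ref_len, alt_seq) | ("I", 0, seq) | ("D", n, "")


def _fragment_segments(
    reference: str,
    frag_start0: int,
    frag_ref_end0: int,
    variants: Sequence[tuple[VariantSite, bool]],
) -> list[tuple[str, int, str]]:
    """Piecewise alignment of the fragment's alt sequence to the reference."""
    segments: list[tuple[str, int, str]] = []
    cursor = frag_start0
    for site, apply in sorted(variants, key=lambda v: v[0].pos):
        if not apply:
            continue
        anchor0 = site.pos - 1
        if anchor0 < cursor:
            continue  # variant truncated by fragment start: skip
        if anchor0 >= frag_ref_end0:
            break
        if anchor0 > cursor:
            segments.append(("M", anchor0 - cursor, reference[cursor:anchor0]))
            cursor = anchor0
        if site.is_snv:
            segments.append(("M", 1, site.alt))
            cursor += 1
        elif len(site.alt) > len(site.ref):  # insertion after anchor
            segments.append(("M", 1, site.alt[0]))
            segments.append(("I", 0, site.alt[1:]))
            cursor += 1
        else:  # deletion after anchor
            del_len = len(site.ref) - len(site.alt)
            segments.append(("M", 1, site.alt[0]))
            end = min(cursor + 1 + del_len, frag_ref_end0)
            segments.append(("D", end - (cursor + 1), ""))
            cursor = end
    if cursor < frag_ref_end0:
        segments.append(("M", frag_ref_end0 - cursor, reference[cursor:frag_ref_end0]))
    return segments


def _slice_read(
    segments: Sequence[tuple[str, int, str]],
    frag_start0: int,
    alt_a: int,
    alt_b: int,
) -> tuple[int, list[tuple[int, int]], str]:
    """Extract one read covering alt-coordinates [alt_a, alt_b).

    Returns (reference_start0, cigartuples, sequence).  Leading/trailing
    deletions are trimmed; adjacent same-op runs are merged.
    """
    ref_off = frag_start0
    alt_off = 0
    ops: list[list[int]] = []  # [op_code, length]
    seq_parts: list[str] = []
    read_ref_start = None
    OP = {"M": 0, "I": 1, "D": 2}
    for kind, ref_len, alt_seq in segments:
        alt_len = len(alt_seq)
        if kind in ("M", "I"):
            lo = max(alt_a, alt_off)
            hi = min(alt_b, alt_off + alt_len)
            if lo < hi:
                within = lo - alt_off
                take = hi - lo
                if read_ref_start is None:
                    read_ref_start = ref_off + (within if kind == "M" else 0)
                code = OP[kind]
                if ops and ops[-1][0] == code:
                    ops[-1][1] += take
                else:
                    ops.append([code, take])
                seq_parts.append(alt_seq[within : within + take])
        else:  # D: no alt length; include only when strictly inside the read
            if read_ref_start is not None and alt_off < alt_b and alt_off > alt_a:
                if ops and ops[-1][0] == OP["D"]:
                    ops[-1][1] += ref_len
                else:
                    ops.append([OP["D"], ref_len])
        alt_off += alt_len
        ref_off += ref_len
        if alt_off >= alt_b:
            break
    while ops and ops[-1][0] == 2:  # trailing deletion carries no bases
        ops.pop()
    while ops and ops[0][0] == 2:
        read_ref_start += ops[0][1]
        ops.pop(0)
    return read_ref_start, [(c, l) for c, l in ops], "".join(seq_parts)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    reference: str,
    genotypes: Mapping[VariantSite, Genotype],
    config: SimConfig,
    out_path: str,
    sample_id: str = "sample",
    seed: int | None = None,
    depth: float | None = None,
) -> str:
    """Write coordinate-sorted, indexed paired-end reads for one sample.

    Fragments are placed uniformly; heterozygous variants land on a
    random haplotype per fragment, homozygous on both.  Per-base errors
    occur at ``base_error_rate``; qualities are BQ 37 with a 7% BQ 20
    admixture.  Deterministic under (config.seed, seed).
    """
    depth = config.depth if depth is None else depth
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])
    L = config.genome_length
    rl = config.read_length
    n_frags = int(round(depth * L / (2 * rl)))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": config.chrom, "LN": L}],
            "RG": [{"ID": sample_id, "SM": sample_id}],
        }
    )
    var_list = sorted(genotypes, key=lambda s: s.pos)
    var_pos = np.array([s.pos - 1 for s in var_list], dtype=int)
    var_end = np.array([s.pos - 1 + len(s.ref) for s in var_list], dtype=int)
    var_zyg = [genotypes[s] for s in var_list]

    tmp = out_path + ".unsorted.bam"
    if n_frags == 0:
        with pysam.AlignmentFile(tmp, "wb", header=header):
            pass
        pysam.sort("-o", out_path, tmp)
        os.unlink(tmp)
        pysam.index(out_path)
        return out_path

    inserts = np.clip(
        rng.normal(config.insert_mean, config.insert_sd, n_frags).round().astype(int),
        rl + 10,
        L,
    )
    starts = (rng.random(n_frags) * (L - inserts)).astype(int)
    n_err = rng.binomial(2 * rl, config.base_error_rate, n_frags)
    n_lowq = rng.binomial(2 * rl, LOW_BQ_RATE, n_frags)
    hq = np.full(rl, BQ_HIGH, dtype=np.uint8)

    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i in range(n_frags):
            fstart, fins = int(starts[i]), int(inserts[i])
            fend = fstart + fins
            lo = int(np.searchsorted(var_end, fstart, side="right"))
            hi = int(np.searchsorted(var_pos, fend, side="left"))
            chosen = []
            for vi in range(lo, hi):
                zyg = var_zyg[vi]
                apply = zyg is Genotype.HOM_ALT or rng.random() < 0.5
                chosen.append((var_list[vi], apply))
            if any(a for _, a in chosen):
                segments = _fragment_segments(reference, fstart, fend, chosen)
                alt_len = sum(len(s) for _, _, s in segments)
                if alt_len < rl:
                    continue  # large net deletion shrank the fragment too far
                r1_start, cig1, seq1 = _slice_read(segments, fstart, 0, rl)
                r2_start, cig2, seq2 = _slice_read(
                    segments, fstart, alt_len - rl, alt_len
                )
            else:
                r1_start, cig1, seq1 = fstart, [(0, rl)], reference[fstart : fstart + rl]
                r2_start, cig2, seq2 = (
                    fend - rl,
                    [(0, rl)],
                    reference[fend - rl : fend],
                )

            seqs = [list(seq1), list(seq2)]
            quals = [hq.copy(), hq.copy()]
            for _ in range(int(n_err[i])):
                which, posn = int(rng.integers(2)), int(rng.integers(rl))
                old = seqs[which][posn]
                seqs[which][posn] = str(rng.choice([b for b in "ACGT" if b != old]))
            for _ in range(int(n_lowq[i])):
                which, posn = int(rng.integers(2)), int(rng.integers(rl))
                quals[which][posn] = BQ_LOW

            name = f"{sample_id}.f{i:08d}"
            ref_end2 = r2_start + sum(l for c, l in cig2 if c in (0, 2))
            tlen = ref_end2 - r1_start
            for mate, (rstart, cig, seq, flag, mstart, tl) in enumerate(
                (
                    (r1_start, cig1, seqs[0], 99, r2_start, tlen),
                    (r2_start, cig2, seqs[1], 147, r1_start, -tlen),
                )
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.flag = flag
                a.reference_id = 0
                a.reference_start = rstart
                a.mapping_quality = 60
                a.cigartuples = cig
                a.query_sequence = "".join(seq)
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals[mate])
                )
                a.next_reference_id = 0
                a.next_reference_start = mstart
                a.template_length = tl
                a.set_tag("RG", sample_id, "Z")
                out.write(a)
    pysam.sort("-o", out_path, tmp)
    os.unlink(tmp)
    pysam.index(out_path)
    return out_path


# ---------------------------------------------------------------------------
# Published-shape variant sets for truth arithmetic
# ---------------------------------------------------------------------------


def planted_vsets(
    counts: Mapping[str, Mapping[tuple[str, Genotype], int]] = REFERENCE_VSET_COUNTS,
    chrom: str = "chr1",
) -> dict[str, ExclusiveVariantSet]:
    """Synthesize disjoint exclusive variant sets with given cardinalities.

    Produces one ``ExclusiveVariantSet`` per named set whose per-type and
    per-zygosity record counts match ``counts`` (defaulting to the
    published design's cardinalities), with schematic sites at distinct
    positions.  This lets truth-set arithmetic run at full scale without
    sequencing data.
    """
    vsets: dict[str, ExclusiveVariantSet] = {}
    pos = 100
    for owner in sorted(counts):
        records = []
        for (vtype, zyg), n in sorted(
            counts[owner].items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            for _ in range(n):
                if vtype == "SNV":
                    site = VariantSite(chrom, pos, "A", "G")
                else:
                    site = VariantSite(chrom, pos, "AT", "A")
                records.append((site, zyg))
                pos += 10
        vsets[owner] = ExclusiveVariantSet(owner_sample=owner, records=records)
    return vsets


def planted_germline(
    counts: Mapping[tuple[str, Genotype], int] = REFERENCE_GERMLINE_COUNTS,
    chrom: str = "chr2",
):
    """Schematic internal-reference germline records at given cardinalities.

    Mirrors :func:`planted_vsets` for the set-B germline negative
    catalogue; defaults to the published per-type/zygosity counts.
    """
    from .postfilter import GermlineRecord

    records = []
    pos = 100
    for (vtype, zyg), n in sorted(counts.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        for _ in range(n):
            if vtype == "SNV":
                site = VariantSite(chrom, pos, "C", "T")
            else:
                site = VariantSite(chrom, pos, "CA", "C")
            records.append(GermlineRecord(site, zyg))
            pos += 10
    return records
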