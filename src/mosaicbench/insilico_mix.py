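"""In-silico construction of mixture (set A) and germline-replaced (set B) BAMs.

Physical DNA mixing is emulated at the read level: each source BAM is
independently downsampled so that its expected contribution to the output
equals its mass fraction of the target depth, then the survivors are
merged, coordinate-sorted and indexed.  Downsampling decisions are made
per read *pair* from a keyed hash of the read name, so both mates share
one fate and the selection is deterministic under a fixed seed and stable
under re-sorting.

The germline-negative companion file (set B) is built by downsampling the
internal reference to the mixture depth, deleting every reference read
whose aligned span touches a positive-control position, and splicing in
all mixture reads that overlap those positions.  Away from the positives
the file is pure internal reference — its germline variants intact as
negative controls — while at every positive position the pileup is pure
mixture.
"""

from __future__ import annotations

import bisect
import hashlib
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

from .mix_design import MixtureProduct

_HASH_DENOM = float(2**64)


class DepthError(ValueError):
    """A source cannot supply its required share of the target depth."""


class AlignmentFormatError(ValueError):
    """Unsorted/unindexed input or mismatched reference dictionaries."""


@dataclass
class ReadSource:
    """A coordinate-sorted, indexed alignment file with a known mean depth."""

    sample_id: str
    alignment_path: str
    mean_depth: float | None = None

    def __post_init__(self) -> None:
        if self.mean_depth is None:
            self.mean_depth = estimate_mean_depth(self.alignment_path)
        if self.mean_depth <= 0:
            raise DepthError(f"{self.sample_id}: non-positive mean depth")


@dataclass
class MixRecipe:
    product_id: str
    sources: list[tuple[ReadSource, float]]
    target_depth: float
    seed: int

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.sources)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.product_id}: fractions sum to {total}, not 1")


def recipe_from_product(
    product: MixtureProduct,
    read_sources: Mapping[str, ReadSource],
    internal_ref_id: str,
    target_depth: float,
    seed: int,
) -> MixRecipe:
    """Turn a design product into a mixing recipe.

    Donor fractions come from the product; the internal reference takes
    the remainder so the recipe fractions sum to one.
    """
    sources = [
        (read_sources[sid], float(f)) for sid, f in product.components if f > 0
    ]
    sources.append((read_sources[internal_ref_id], float(product.internal_fraction)))
    return MixRecipe(product.product_id, sources, target_depth, seed)


def estimate_mean_depth(path: str) -> float:
    """Mean depth = total aligned reference bases / total reference length."""
    with pysam.AlignmentFile(path, "rb") as bam:
        ref_len = sum(bam.lengths)
        aligned = 0
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            aligned += read.reference_length or 0
    if ref_len == 0:
        raise AlignmentFormatError(f"{path}: empty reference dictionary")
    return aligned / ref_len


def _pair_uniform(seed: int, sample_id: str, read_name: str) -> float:
    """Deterministic uniform in [0, 1) keyed by (seed, sample, read name)."""
    h = hashlib.blake2b(
        read_name.encode(),
        digest_size=8,
        key=f"{seed}:{sample_id}".encode()[:64],
    )
    return int.from_bytes(h.digest(), "big") / _HASH_DENOM


def _check_indexed(path: str) -> None:
    with pysam.AlignmentFile(path, "rb") as bam:
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise AlignmentFormatError(f"{path}: not coordinate-sorted/indexed") from exc


def _same_reference(header_a, header_b) -> bool:
    sq_a = [(sq["SN"], sq["LN"]) for sq in header_a.to_dict().get("SQ", [])]
    sq_b = [(sq["SN"], sq["LN"]) for sq in header_b.to_dict().get("SQ", [])]
    return sq_a == sq_b


def _sort_and_index(unsorted_path: str, out_path: str) -> None:
    pysam.sort("-o", out_path, unsorted_path)
    pysam.index(out_path)
    os.unlink(unsorted_path)


def _merged_header(template_header, sample_ids: Iterable[str]) -> dict:
    header = template_header.to_dict()
    header["RG"] = [{"ID": sid, "SM": sid} for sid in sample_ids]
    header.pop("PG", None)
    return header


def mix_bams(recipe: MixRecipe, out_path: str) -> str:
    """Synthesize a mixture BAM from fraction-weighted downsampled sources.

    Each source is thinned to keep-probability
    ``fraction * target_depth / mean_depth`` per read pair; survivors are
    tagged with a read group named after their source sample, merged and
    coordinate-sorted.  Raises :class:`DepthError` when a source is too
    shallow to supply its share.
    """
    keep_probs = []
    for src, frac in recipe.sources:
        _check_indexed(src.alignment_path)
        required = frac * recipe.target_depth
        if required > src.mean_depth * (1 + 1e-9):
            raise DepthError(
                f"{src.sample_id}: needs {required:.1f}x but has {src.mean_depth:.1f}x"
            )
        keep_probs.append(min(1.0, required / src.mean_depth))

    with pysam.AlignmentFile(recipe.sources[0][0].alignment_path, "rb") as first:
        template = first.header
        header = _merged_header(template, [s.sample_id for s, _ in recipe.sources])

    tmp = out_path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for (src, _frac), p_keep in zip(recipe.sources, keep_probs):
            with pysam.AlignmentFile(src.alignment_path, "rb") as bam:
                if not _same_reference(template, bam.header):
                    raise AlignmentFormatError(
                        f"{src.sample_id}: reference dictionary mismatch"
                    )
                for read in bam.fetch(until_eof=True):
                    if read.is_secondary or read.is_supplementary:
                        continue
                    if _pair_uniform(recipe.seed, src.sample_id, read.query_name) >= p_keep:
                        continue
                    read.set_tag("RG", src.sample_id, "Z")
                    out.write(read)
    _sort_and_index(tmp, out_path)
    return out_path


# ---------------------------------------------------------------------------
# Interval machinery for set-B read replacement
# ---------------------------------------------------------------------------


class _IntervalIndex:
    """Merged half-open intervals per chromosome with overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        self._merged: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[chrom] = ([s for s, _ in merged], [e for _, e in merged])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        entry = self._merged.get(chrom)
        if entry is None or start >= end:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, start) - 1
        if i >= 0 and ends[i] > start:
            return True
        i += 1
        return i < len(starts) and starts[i] < end

    def __bool__(self) -> bool:
        return bool(self._merged)


def _read_overlaps(read, index: _IntervalIndex) -> bool:
    """Overlap by aligned span (deletions included, soft clips excluded)."""
    if read.is_unmapped:
        return False
    return index.overlaps(
        read.reference_name, read.reference_start, read.reference_end
    )


ORIGIN_TAG = "XO"  # provenance tag on set-B reads: "mixture" or "reference"


def make_setB(
    mixture_path: str,
    internal_ref: ReadSource,
    positive_intervals: Sequence[tuple[str, int, int]],
    target_depth: float,
    seed: int,
    out_path: str,
) -> str:
    """Build the germline-negative companion of a mixture BAM.

    ``positive_intervals`` are half-open 0-based (BED) spans of the
    positive-control sites (ref-allele span for INDELs).  The output is
    the internal reference downsampled to ``target_depth`` with every
    read overlapping a positive interval removed, plus every mixture read
    overlapping those intervals.  Reads carry an origin tag
    (``XO:mixture`` / ``XO:reference``) for provenance audits.
    """
    if not positive_intervals:
        raise ValueError("positive_intervals must be nonempty")
    _check_indexed(mixture_path)
    _check_indexed(internal_ref.alignment_path)
    index = _IntervalIndex(positive_intervals)
    p_keep = min(1.0, target_depth / internal_ref.mean_depth)
    if target_depth > internal_ref.mean_depth * (1 + 1e-9):
        raise DepthError(
            f"internal reference has {internal_ref.mean_depth:.1f}x "
            f"< target {target_depth:.1f}x"
        )

    with pysam.AlignmentFile(internal_ref.alignment_path, "rb") as ref_bam, \
            pysam.AlignmentFile(mixture_path, "rb") as mix_bam:
        if not _same_reference(ref_bam.header, mix_bam.header):
            raise AlignmentFormatError("reference dictionary mismatch")
        header = _merged_header(ref_bam.header, [internal_ref.sample_id, "mixture"])
        tmp = out_path + ".unsorted.bam"
        with pysam.AlignmentFile(tmp, "wb", header=header) as out:
            for read in ref_bam.fetch(until_eof=True):
                if read.is_secondary or read.is_supplementary:
                    continue
                u = _pair_uniform(seed, internal_ref.sample_id, read.query_name)
                if u >= p_keep:
                    continue
                if _read_overlaps(read, index):
                    continue
                read.set_tag("RG", internal_ref.sample_id, "Z")
                read.set_tag(ORIGIN_TAG, "reference", "Z")
                out.write(read)
            for read in mix_bam.fetch(until_eof=True):
                if read.is_secondary or read.is_supplementary:
                    continue
                if not _read_overlaps(read, index):
                    continue
                read.set_tag("RG", "mixture", "Z")
                read.set_tag(ORIGIN_TAG, "mixture", "Z")
                out.write(read)
    _sort_and_index(tmp, out_path)
    return out_path


# ---------------------------------------------------------------------------
# Read-profile comparison
# ---------------------------------------------------------------------------


@dataclass
class ReadProfile:
    """Library-level summary of one alignment file."""

    insert_size_peak: int
    read1_length_mode: int
    read2_length_mode: int
    duplicate_rate: float
    gc_fraction: float
    bq30_fraction: float


def _profile(path: str) -> ReadProfile:
    from collections import Counter

    inserts: Counter = Counter()
    len1: Counter = Counter()
    len2: Counter = Counter()
    n_reads = dup_reads = 0
    gc = total_bases = hq_bases = 0
    with pysam.AlignmentFile(path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            n_reads += 1
            if read.is_duplicate:
                dup_reads += 1
            if read.is_proper_pair and read.template_length > 0:
                inserts[read.template_length] += 1
            target = len1 if read.is_read1 or not read.is_paired else len2
            target[read.query_length] += 1
            seq = read.query_sequence or ""
            total_bases += len(seq)
            gc += seq.count("G") + seq.count("C")
            quals = read.query_qualities
            if quals is not None:
                hq_bases += sum(1 for q in quals if q >= 30)
    return ReadProfile(
        insert_size_peak=inserts.most_common(1)[0][0] if inserts else 0,
        read1_length_mode=len1.most_common(1)[0][0] if len1 else 0,
        read2_length_mode=len2.most_common(1)[0][0] if len2 else 0,
        duplicate_rate=dup_reads / n_reads if n_reads else 0.0,
        gc_fraction=gc / total_bases if total_bases else 0.0,
        bq30_fraction=hq_bases / total_bases if total_bases else 0.0,
    )


def compare_read_profiles(path_a: str, path_b: str) -> dict:
    """Five library summary statistics per file plus absolute differences."""
    pa, pb = _profile(path_a), _profile(path_b)
    diffs = {
        name: abs(getattr(pa, name) - getattr(pb, name))
        for name in (
            "insert_size_peak",
            "read1_length_mode",
            "read2_length_mode",
            "duplicate_rate",
            "gc_fraction",
            "bq30_fraction",
        )
    }
    return {"a": pa, "b": pb, "abs_diff": diffs}
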