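"""Hierarchical mixture design: products, expected VAFs, truth assembly.

A mixture *product* dilutes one or more donor samples into an internal
reference at known mass fractions.  Under copy-number-neutral diploidy,
a donor present at mass fraction *f* presents its heterozygous variants
at VAF *f*/2 and its homozygous variants at VAF *f* — so every variant
private to a donor becomes a positive control with an exactly known
expected VAF.  Products fall into classes (M1/M2/M3-style) according to
which donors they contain; two products sharing a donor share that
donor's variant set at a known VAF pair, which is what makes the design
useful for shared-versus-private mosaic variant analysis.

Fractions are kept as exact rationals (:class:`fractions.Fraction`) so
that designed-VAF tallies and distinctness counts never suffer float
collisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from numbers import Rational
from typing import Iterable, Mapping, Sequence

from .genotype_select import ConfigurationError, ExclusiveVariantSet
from .variants import Genotype, VariantSite

_SUM_TOL = Fraction(1, 10**9)


def _as_fraction(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(str(x))


def expected_vaf(zygosity: Genotype, fraction) -> Fraction:
    """Expected VAF of a donor variant at mass fraction ``fraction``.

    HET -> f/2, HOM_ALT -> f (diploid, copy-number neutral).
    """
    f = _as_fraction(fraction)
    if not 0 <= f <= 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if zygosity is Genotype.HET:
        return f / 2
    if zygosity is Genotype.HOM_ALT:
        return f
    raise ValueError(f"zygosity must be HET or HOM_ALT, got {zygosity}")


@dataclass(frozen=True)
class MixtureProduct:
    """One mixture: donor components at mass fractions, remainder = internal reference."""

    product_id: str
    class_label: str
    components: tuple[tuple[str, Fraction], ...]

    def __post_init__(self) -> None:
        comps = tuple((sid, _as_fraction(f)) for sid, f in self.components)
        object.__setattr__(self, "components", comps)
        seen = set()
        total = Fraction(0)
        for sid, f in comps:
            if sid in seen:
                raise ConfigurationError(
                    f"{self.product_id}: component {sid} listed twice"
                )
            seen.add(sid)
            if not 0 <= f <= 1:
                raise ConfigurationError(f"{self.product_id}: fraction {f} outside [0,1]")
            total += f
        if total > 1 + _SUM_TOL:
            raise ConfigurationError(
                f"{self.product_id}: component fractions sum to {float(total):.6f} > 1"
            )

    @property
    def internal_fraction(self) -> Fraction:
        return 1 - sum((f for _, f in self.components), Fraction(0))

    @property
    def donor_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, f in self.components if f > 0)

    def fraction_of(self, sample_id: str) -> Fraction:
        for sid, f in self.components:
            if sid == sample_id:
                return f
        return Fraction(0)


@dataclass(frozen=True)
class TruthRecord:
    """A positive control: one donor variant in one product at a known VAF."""

    site: VariantSite
    source_sample: str
    zygosity: Genotype
    expected_vaf: Fraction
    product_id: str


def build_truth_set(
    product: MixtureProduct,
    vsets: Mapping[str, ExclusiveVariantSet],
) -> list[TruthRecord]:
    """Assemble the positive-control truth records of one product.

    Every variant in every donor component's exclusive set yields one
    record; the internal reference contributes none.  The record count is
    therefore the sum of the component set cardinalities.
    """
    records: list[TruthRecord] = []
    pid = product.product_id
    for sid, f in product.components:
        if f == 0:
            continue
        if sid not in vsets:
            raise ConfigurationError(
                f"{pid}: component {sid} has no variant set"
            )
        evaf = {z: expected_vaf(z, f) for z in (Genotype.HET, Genotype.HOM_ALT)}
        records.extend(
            TruthRecord(site, sid, zyg, evaf[zyg], pid)
            for site, zyg in vsets[sid].records
        )
    return records


@dataclass(frozen=True)
class PairRelationship:
    """Variant-sharing structure between two products.

    ``shared`` maps each donor present in both products to its
    (het VAF in first, het VAF in second) pair; homozygous VAFs are twice
    these.  ``unique_first``/``unique_second`` list donors private to one
    side.  Together they cover every donor of both products exactly once.
    """

    product_pair: tuple[str, str]
    shared: tuple[tuple[str, tuple[Fraction, Fraction]], ...]
    unique_first: tuple[str, ...]
    unique_second: tuple[str, ...]


def enumerate_pair_relationships(
    products: Sequence[MixtureProduct],
) -> list[PairRelationship]:
    """All C(n, 2) pairwise variant-sharing relationships."""
    if len(products) < 2:
        raise ConfigurationError("need at least two products")
    out = []
    for p, q in combinations(products, 2):
        dp, dq = set(p.donor_ids), set(q.donor_ids)
        shared = tuple(
            (sid, (expected_vaf(Genotype.HET, p.fraction_of(sid)),
                   expected_vaf(Genotype.HET, q.fraction_of(sid))))
            for sid in sorted(dp & dq)
        )
        out.append(
            PairRelationship(
                product_pair=(p.product_id, q.product_id),
                shared=shared,
                unique_first=tuple(sorted(dp - dq)),
                unique_second=tuple(sorted(dq - dp)),
            )
        )
    return out


def designed_vaf_summary(
    products: Sequence[MixtureProduct],
    threshold,
    owners: Iterable[str] | None = None,
) -> dict[str, Fraction]:
    """Per-donor proportion of designed VAFs exceeding ``threshold``.

    Counts one (zygosity-class, product) combination per product the
    donor appears in — two designed VAFs (het and hom) per appearance,
    unweighted by variant counts — and reports the fraction strictly
    above the threshold.  Donors appearing in no product are omitted.
    """
    thr = _as_fraction(threshold)
    if not 0 < thr < 1:
        raise ValueError("threshold must be in (0, 1)")
    totals: dict[str, int] = {}
    above: dict[str, int] = {}
    for product in products:
        for sid, f in product.components:
            if f == 0:
                continue
            for zyg in (Genotype.HET, Genotype.HOM_ALT):
                totals[sid] = totals.get(sid, 0) + 1
                if expected_vaf(zyg, f) > thr:
                    above[sid] = above.get(sid, 0) + 1
    result = {
        sid: Fraction(above.get(sid, 0), totals[sid]) for sid in totals
    }
    if owners is not None:
        result = {sid: v for sid, v in result.items() if sid in set(owners)}
    return result


def distinct_designed_vafs(fractions: Sequence) -> int:
    """Number of distinct VAF levels a set of mass fractions can present.

    Each fraction f yields f/2 (het) and f (hom); collisions between the
    two zygosity ladders are counted once (exact rational arithmetic).
    """
    if not fractions:
        raise ValueError("fractions must be nonempty")
    fr = [_as_fraction(f) for f in fractions]
    return len({f / 2 for f in fr} | set(fr))


def minimum_detectable_vaf(depth: float) -> float:
    """Smallest VAF presentable by a single alternate read at ``depth``.

    At 40x one alt read corresponds to VAF 2.5%, which is why the
    coverage floor of the positive-control filter is paired with the
    2.5%-designed-VAF audit of :func:`designed_vaf_summary`.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    return 1.0 / depth


# ---------------------------------------------------------------------------
# The published 39-product reference design
# ---------------------------------------------------------------------------

# Donor mass fractions per product, given as the homozygous VAF percentages
# of the printed design (het% is always half).  Donors: V1..V5 ladders;
# classes: M1 = {V1, V2}, M2 = {V1, V3, V4}, M3 = {V1, V3, V5}.
_M1 = [  # (V1 hom%, V2 hom%)
    ("M1-1", "8", "2"), ("M1-2", "8", "6"), ("M1-3", "8", "50"),
    ("M1-4", "19.2", "2"), ("M1-5", "19.2", "6"), ("M1-6", "19.2", "50"),
    ("M1-7", "56", "2"), ("M1-8", "56", "6"), ("M1-9", "8", "1"),
]
_M2 = [  # (V1 hom%, V3 hom%, V4 hom%)
    ("M2-1", "8", "10", "1"), ("M2-2", "8", "10", "6"),
    ("M2-3", "8", "16", "1"), ("M2-4", "8", "16", "6"),
    ("M2-5", "19.2", "10", "1"), ("M2-6", "19.2", "10", "6"),
    ("M2-7", "19.2", "16", "1"), ("M2-8", "19.2", "16", "6"),
    ("M2-9", "56", "10", "1"), ("M2-10", "56", "10", "6"),
    ("M2-11", "56", "16", "1"), ("M2-12", "56", "16", "6"),
]
_M3 = [  # (V1 hom%, V3 hom%, V5 hom%)
    ("M3-1", "8", "15", "2"), ("M3-2", "8", "15", "4"), ("M3-3", "8", "15", "8"),
    ("M3-4", "8", "24", "2"), ("M3-5", "8", "24", "4"), ("M3-6", "8", "24", "8"),
    ("M3-7", "19.2", "15", "2"), ("M3-8", "19.2", "15", "4"), ("M3-9", "19.2", "15", "8"),
    ("M3-10", "19.2", "32", "2"), ("M3-11", "19.2", "32", "4"), ("M3-12", "19.2", "32", "8"),
    ("M3-13", "56", "20", "2"), ("M3-14", "56", "20", "4"), ("M3-15", "56", "20", "8"),
    ("M3-16", "56", "32", "2"), ("M3-17", "56", "32", "4"), ("M3-18", "56", "32", "8"),
]


def _pct(p: str) -> Fraction:
    return Fraction(p) / 100


def reference_design() -> list[MixtureProduct]:
    """The published 39-product design (9 M1, 12 M2, 18 M3)."""
    products = [
        MixtureProduct(pid, "M1", (("V1", _pct(v1)), ("V2", _pct(v2))))
        for pid, v1, v2 in _M1
    ]
    products += [
        MixtureProduct(pid, "M2", (("V1", _pct(v1)), ("V3", _pct(v3)), ("V4", _pct(v4))))
        for pid, v1, v3, v4 in _M2
    ]
    products += [
        MixtureProduct(pid, "M3", (("V1", _pct(v1)), ("V3", _pct(v3)), ("V5", _pct(v5))))
        for pid, v1, v3, v5 in _M3
    ]
    return products


# Published variant-set cardinalities: {set: {(vtype, zygosity): count}}.
REFERENCE_VSET_COUNTS: dict[str, dict[tuple[str, Genotype], int]] = {
    "V1": {("SNV", Genotype.HET): 2698, ("SNV", Genotype.HOM_ALT): 133,
           ("INDEL", Genotype.HET): 89, ("INDEL", Genotype.HOM_ALT): 5},
    "V2": {("SNV", Genotype.HET): 6158, ("SNV", Genotype.HOM_ALT): 350,
           ("INDEL", Genotype.HET): 212, ("INDEL", Genotype.HOM_ALT): 12},
    "V3": {("SNV", Genotype.HET): 2058, ("SNV", Genotype.HOM_ALT): 188,
           ("INDEL", Genotype.HET): 65, ("INDEL", Genotype.HOM_ALT): 7},
    "V4": {("SNV", Genotype.HET): 2127, ("SNV", Genotype.HOM_ALT): 129,
           ("INDEL", Genotype.HET): 60, ("INDEL", Genotype.HOM_ALT): 7},
    "V5": {("SNV", Genotype.HET): 5825, ("SNV", Genotype.HOM_ALT): 349,
           ("INDEL", Genotype.HET): 173, ("INDEL", Genotype.HOM_ALT): 16},
}


# Published germline negative-control cardinalities of the internal
# reference (set B): {(vtype, zygosity): count}.
REFERENCE_GERMLINE_COUNTS: dict[tuple[str, Genotype], int] = {
    ("SNV", Genotype.HET): 11734,
    ("SNV", Genotype.HOM_ALT): 7763,
    ("INDEL", Genotype.HET): 296,
    ("INDEL", Genotype.HOM_ALT): 143,
}


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


def load_design(path: str) -> list[MixtureProduct]:
    """Load products from a YAML design config.

    Expected layout::

        products:
          - id: M1-1
            class: M1
            components: {V1: 0.08, V2: 0.02}
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    products = []
    for entry in doc["products"]:
        comps = tuple(
            (sid, _as_fraction(f)) for sid, f in entry["components"].items()
        )
        products.append(
            MixtureProduct(str(entry["id"]), str(entry.get("class", "")), comps)
        )
    return products


def save_design(path: str, products: Sequence[MixtureProduct]) -> None:
    import yaml

    doc = {
        "products": [
            {
                "id": p.product_id,
                "class": p.class_label,
                "components": {sid: float(f) for sid, f in p.components},
            }
            for p in products
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
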