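# mosaicbench

Reference-standard construction and evaluation for **mosaic variant
calling**, built around cell-line-mixture designs.

Mosaic (postzygotic) variants sit at allele frequencies far below the
germline 50%/100%, where callers are hardest to validate: there is no
natural ground truth. A practical way to manufacture one is to take
several samples with *mutually exclusive* germline variants — each
variant private to exactly one sample, explicitly reference-homozygous in
all the others — and dilute those samples into a common internal
reference at known mass fractions. Under copy-number-neutral diploidy a
donor at mass fraction *f* presents its heterozygous variants at

```
VAF_het = f / 2        VAF_hom = f
```

so every private variant becomes a positive control with an exactly known
expected VAF, and the caller can be scored against two distinct negative
catalogues: positions confirmed reference-homozygous in every constituent
sample (any call there is an **artifact** false positive — "set A"), and
the internal reference's own germline variants, preserved by replacing
reads at positive positions in a reference-only alignment (calling one of
those as mosaic is a **germline** false positive — "set B").

`mosaicbench` implements this construction fully in silico:

- **genotype_select** — dual-caller consensus genotyping, mutually
  exclusive variant sets (V1..Vn) under a copy-number-neutrality gate
  (|log2 ratio| < 0.3), and negative-candidate collection;
- **mix_design** — mixture products with exact-rational mass fractions,
  expected-VAF arithmetic, truth-set assembly, pairwise variant-sharing
  relationships, and the encoded 39-product reference design;
- **insilico_mix** — deterministic read-pair downsampling and merging of
  BAMs to a designed depth, and set-B construction by read replacement;
- **postfilter** — pileup-based finalization: coverage (≥40×ᵖᵒˢ/≥20×ⁿᵉᵍ),
  variant coverage (≥20%), >3 high-BQ alt alleles, a beta-binomial
  allele-balance test for heterozygous germline sites (α=74, β=76,
  two-tailed p < 0.01) and a VAF ≥ 0.9 rule for homozygous ones;
- **evaluate** — caller scoring with TP/FN/FP_artifact/FP_germline
  accounting, per-VAF-bin sensitivity, and log10-scale Pearson
  concordance between expected and median observed VAFs;
- **synthetic_data** — a seeded generator for reference sequence, diploid
  genotypes with planted private variants, dual pseudo-caller callsets,
  CN tables, and directly written aligned paired-end reads, so the whole
  pipeline runs without any external data.

## Worked example

```python
from mosaicbench import (
    reference_design, planted_vsets, build_truth_set,
    enumerate_pair_relationships, designed_vaf_summary,
)

products = reference_design()        # the 39-product design (9 M1, 12 M2, 18 M3)
vsets = planted_vsets()              # V1..V5 at their published cardinalities

m1_1 = products[0]
truth = build_truth_set(m1_1, vsets)
print(f"{m1_1.product_id}: {len(truth)} positive controls")
levels = sorted({float(r.expected_vaf) for r in truth})
print("designed VAF levels:", [f"{v:.3g}" for v in levels])

total = sum(len(build_truth_set(p, vsets)) for p in products)
print(f"full design: {total} positive controls across {len(products)} products")
print(f"pairwise relationships: {len(enumerate_pair_relationships(products))}")

summary = designed_vaf_summary(products, "0.025")
print("fraction of designed VAFs above 2.5%:",
      {k: f"{float(v):.0%}" for k, v in sorted(summary.items())})
```

prints

```
M1-1: 9657 positive controls
designed VAF levels: ['0.01', '0.02', '0.04', '0.08']
full design: 386613 positive controls across 39 products
pairwise relationships: 741
fraction of designed VAFs above 2.5%: {'V1': '100%', 'V2': '56%', 'V3': '100%', 'V4': '50%', 'V5': '50%'}
```

The first product mixes donor V1 at 8% and V2 at 1% mass fraction, so its
positives sit at the four designed VAFs 1/2/4/8%; the 2.5% threshold is
the smallest VAF a single alternate read can present at the 40× coverage
floor, and the summary shows every variant set keeps at least half of its
designed (zygosity, product) combinations above it.

The same pipeline is scriptable from the shell — `mosaicbench simulate`,
`select`, `design`, `mix`, `make-setb`, `filter-positives`,
`filter-neg-a`, `filter-neg-b`, `score` — each a thin wrapper over the
functions above; see `mosaicbench --help`.

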