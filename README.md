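# hapnetrec

Haplotype median networks and quartet-based recombinant detection for
phased, biallelic SNP data — built around the evolutionary analysis of the
human ABO blood-group gene region, where the modern A-type haplogroup looks
like the product of an ancient crossover between B-type and O-type lineages.

## The problem

Phased SNP haplotypes over a gene region record, site by site, which allele
each chromosome carries. When a lineage arises by recombination, it agrees
with one parental lineage at the 5′ end and with the other at the 3′ end.
Two consequences are exploited here:

1. **Network signature.** In a median phylogenetic network (the closure of
   binary haplotypes under coordinate-wise majority of triples, pruned to
   shortest paths between observed haplotypes), a single crossover between
   two diverged parents creates a *rectangle*: the parents occupy opposing
   vertices with long external branches of post-event private substitutions,
   while the recombinant opposes the path to the outgroup with a short
   external branch. The two parallel edge classes of the rectangle carry the
   sites the recombinant shares with each parent, so the crossover is
   bracketed by `(max(5′ class), min(3′ class))`.

2. **Quartet signature.** For a quartet {x, y, z, outgroup}, a site is
   phylogenetically informative when exactly two members share each allele;
   every informative site supports one of the three splits. A simple
   recombinant z of parents x and y empties the split {x, y | z, outgroup}
   and fills the other two with positionally disjoint site classes. The
   five-step scan (count singletons; classify sites per quartet; keep
   quartets with exactly one empty split; require disjoint class ranges;
   pick the quartet whose candidate has fewest singletons, ties broken by
   the largest parental singleton sum) turns this into a detector that also
   *vetoes* lineages carrying parallel changes with the outgroup — mosaics
   shaped by gene conversion rather than one crossover.

Because SNP panels cannot see indels, a non-SNP landmark such as the ABO
exon-6 single-base deletion (Δ261, which frameshifts the
glycosyltransferase and defines the major O alleles) is tracked as a
*marker* pinned between two SNP ordinals, with an explicit carrier set.
When a marker falls inside a breakpoint interval and the two parents differ
in carrier state, the recombinant's own state tells which side of the marker
the crossover lies on, narrowing the interval to a marker endpoint such as
`(15, Δ261)`.

## What's in the box

| module | contents |
| --- | --- |
| `hapnetrec.hapio` | TSV / FASTA-like readers and writers, outgroup-polarised 0/1 encoding, JSON/TSV call reports |
| `hapnetrec.filters` | phase-confidence filtering (≤ 1 heterozygous site per individual), recurrence filtering, collapse to unique haplotypes |
| `hapnetrec.haplogroups` | diagnostic-SNP panel classification (config-driven, fallback label `X`), modal representatives |
| `hapnetrec.mednet` | binary median-network construction, external branches, rectangle enumeration, GraphML/DOT export |
| `hapnetrec.netrec` | rectangle-signature recombinant calls, breakpoint intervals, marker refinement, parallel-substitution costs |
| `hapnetrec.pnarec` | the five-step quartet scan with a full per-quartet audit trail |
| `hapnetrec.simdata` | infinite-sites simulator (recombination + gene conversion + markers), the 15-site worked model, a synthetic 54-site ABO reconstruction, recovery experiments |
| `hapnetrec.pipeline` / CLI `hapnetrec` | end-to-end runs with byte-stable report bundles |

## Worked example

The 15-site model: parents p1 and p2 diverge from a common ancestor,
recombine between sites 6 and 7, and the surviving product r1 adds one
substitution (site 7); the outgroup accumulates three private changes.

```sh
python examples/01_worked_model.py
```

```
external branches (site labels from each haplotype to the rectangle):
  p1: [9, 13, 15]  (length 3)
  p2: [1, 6, 12]  (length 3)
  r1: [7]  (length 1)

singleton counts: {'p1': 3, 'p2': 3, 'r1': 1, 'o_prime': 0}
 network: recombinant r1, parents p1 (5') / p2 (3'), crossover within sites (5, 8)
  pnarec: recombinant r1, parents p1 (5') / p2 (3'), crossover within sites (5, 8)
true crossover: between sites 6 and 7
```

Both detectors name r1 as the recombinant because it shares sites 2, 4, 5
with p1 and sites 8, 11 with p2; the interval (5, 8) is the tightest bracket
those classes allow and contains the true crossover. r1's external branch
(one site) is shorter than either parent's (three sites each) — the
hallmark that distinguishes the recombinant corner of the rectangle.

On the synthetic 54-site ABO reconstruction
(`examples/02_abo_reconstruction.py`), the network detector calls two
recombinants — O01 (parents B101 × O02, crossover in (32, 42), i.e. between
intron 1 and intron 3; explaining the data without recombination would need
4 or 11 parallel substitutions) and A101-A201-O09 (parents O01 × B101,
crossover in (15, 36), narrowed to (15, Δ261) because the A haplogroup
lacks the deletion; 7 or 3 parallel substitutions otherwise). The quartet
scan confirms the A haplogroup but never considers O01, which shares the
outgroup allele at sites where both would-be parents are derived — the
empty-split veto that separates clean crossovers from conversion-like
mosaics. Note this matrix is a constructed stand-in exhibiting the
published site classes, not population data (see `docs/methods.md`).

`examples/03_simulate_and_recover.py` validates both detectors on fresh
infinite-sites simulations (detection and interval coverage 1.00 with one
crossover and ≥ 2 informative sites per segment; false positives 0.00 on
null histories), and `examples/04_pipeline_run.py` runs the whole pipeline
on a 95-haplotype synthetic population, from frequency filtering to the
report bundle.

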