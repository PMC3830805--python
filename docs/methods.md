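# Methods

## Data model

The unit of analysis is a phased haplotype matrix: named rows of
single-character allele states over ordered biallelic SNP sites, numbered
1..L. Genomic positions and gene-feature labels (exon/intron names) are
optional annotations; all reasoning happens in site ordinals. Indel
landmarks (the exon-6 deletion Δ261 of the ABO gene is the motivating case)
cannot be columns of a SNP matrix, so they are *markers*: a name, a
placement between two adjacent ordinals, and an explicit carrier set.
Allele states are polarised against an outgroup row (chimpanzee in the ABO
setting): 0 is the outgroup allele, 1 the derived allele. Sites where the
outgroup state is missing take the ingroup major allele as the ancestral
stand-in and are flagged polarity-uncertain; flagged sites are excluded
from the quartet scan's empty-split test, since a mis-polarised site could
fabricate or hide the diagnostic empty class. Encoding is reversible (the
per-site allele map is stored) and cannot change pairwise Hamming
distances, which the tests assert.

## Phase-confidence and frequency filters

Haplotypes statistically phased from genotypes contain switch errors that
mimic recombinants. Two guards, applied before analysis:

* keep both haplotypes of individuals with at most one heterozygous site
  (phase is then unambiguous up to that site);
* or keep haplotypes whose exact allele string recurs at least `min_count`
  times across all populations jointly (default 3, i.e. "more than twice");
  an identical switch error recurring independently is unlikely.

The recurrence threshold is exposed because "more than two times" admits a
≥ 2 reading; the default takes the strict > 2 reading, and the choice is a
flag, not code. Manual curation (excluding haplotypes that would make the
network unreadably multidimensional) is supported only as an explicit
user-supplied exclusion list — never a heuristic — and every filter
decision is written to the run log.

## Median networks

Unique binary haplotypes are closed under the coordinate-wise majority
(median) of every triple; latent vectors not on any shortest path between
two observed haplotypes are discarded; edges join vectors differing in
exactly one *character* (a maximal group of sites with identical column
patterns, moving as a block). In the resulting median graph, shortest-path
label counts equal raw Hamming distances (asserted as an invariant),
tree-compatible data yield zero cycles, and each pair of mutually
incompatible characters (four-gamete test) contributes a rectangle.

The number of pairwise incompatible characters bounds the hypercube
dimension of the reticulation. Construction refuses to proceed when a
mutually incompatible clique exceeds `max_dim` (default 3) and names the
haplotypes involved, so the user curates explicitly — the same practice as
excluding "complicating" haplotypes before drawing a network by hand.
Node iteration is ordered, so output is reproducible run to run.

An *external branch* is the chain of edges from a haplotype node to the
nearest branching vertex (degree ≥ 3) or interior observed node; its length
is the count of site labels along it. A haplotype sitting on a branching
vertex has length 0 by convention.

### Parallel-substitution candidates

A median network converts homoplasy into reticulation, so a repeated
substitution cannot be distinguished from a recombination signal site by
site. Weight arbitrates: a class of several sites moving together is
credible as a transferred segment, while a *single* site incompatible with
a multi-site class is more parsimoniously explained as a parallel or back
substitution. Sites carried by weight-1 characters that conflict with at
least one character of weight ≥ 2 are flagged and excluded from support
lists (reported separately on each call). This is deliberately
conservative: it never touches multi-site classes, so genuine recombination
support is never discarded.

## Network-based recombinant calls

For every rectangle (chordless 4-cycle), a call is emitted iff

* exactly one corner is strictly nearest the outgroup (site-weighted
  distance);
* the opposing corner anchors exactly one observed haplotype — the
  recombinant — whose external branch is *strictly* shorter than both
  parents' (ties produce no call and are left for manual review);
* the remaining opposing corners anchor the two parents. Anchoring means
  the haplotype is uniquely nearest that corner among the four; ambiguous
  anchoring skips the rectangle.

Stacked rectangles produced by nested characters (a "ladder") can imply the
same recombinant/parent trio; the rectangle anchored closest to the named
haplotypes is kept, which makes the support classes those of the
haplotypes themselves rather than of interior medians.

Supports are the (parallel-filtered) labels of the two edges incident to
the outgroup corner: the sites the recombinant shares with each parent.
The *forward* parent is the one sharing the smaller-ordinal class — the 5′
segment — an orientation re-derived from the data on every call rather than
trusted from any input ordering. The breakpoint interval is
`(max(support_forward), min(support_backward))`; interleaved supports raise
an error naming the pattern conversion-like. `alt_cost` counts the parallel
substitutions a no-recombination explanation would need on either side.
Calls with a single supporting site on either side are flagged
low-confidence. A recombinant whose parental lineage is absent from the
sample does not oppose the outgroup across any rectangle and is therefore
*not* called — expected behaviour, not a miss.

### Marker refinement

When a marker lies inside a call's interval and the parents differ in
carrier state, the recombinant's state identifies the donor of the
marker-containing segment: matching the backward parent places the
crossover 5′ of the marker (the right endpoint becomes the marker name),
matching the forward parent places it 3′. Parents agreeing on the marker,
or a marker outside the interval, leave the interval unchanged with a
warning.

## The five-step quartet scan

Over a selected ingroup (haplogroup representatives by default — the modal
haplotype per label, ties broken by name — or any explicit list) plus the
outgroup:

* **A** — count singleton sites (derived allele private to one haplotype in
  the selection ∪ outgroup).
* **B** — for each ingroup triple, classify informative sites (exactly two
  1s among the quartet) into the three splits.
* **C** — keep quartets with *exactly one* empty split; the candidate
  recombinant is the member grouped with the outgroup there. Quartets with
  two or three empty splits are star-like: the candidate would not be
  unique, so they are rejected.
* **D** — require the two populated splits to occupy disjoint
  `[min, max]` site ranges (strictly); the crossover lies between them.
* **E** — select the quartet whose candidate has the fewest singletons;
  ties fall to the largest parental singleton sum, i.e. parents with longer
  external branches are preferred. Ties after both criteria yield one
  flagged call per tied quartet (never silently dropped).

Singleton-containing sites are not informative under the standard
definition, so they never enter the classes at step B. The audit trail
(`explain_scan`) records, for every quartet, its class sizes, the step that
rejected it and why, and the step-E scores.

The empty-split requirement is what makes the scan conservative: a lineage
carrying even one parallel change with the outgroup (ancestral where both
would-be parents are derived) fills the would-be-empty split and is vetoed
at C. This is the designed behaviour for conversion-shaped mosaics such as
the O01 haplogroup, which the network detector calls but the quartet scan
deliberately does not.

## Synthetic data

The simulator generates exactly the structure the detectors assume: an
all-ancestral root; lineages created by copying a parent and adding private
substitutions at uniformly random *unused* sites (infinite sites — each
segregating site records one event), optionally confined to windows so that
informative classes are positionally coherent; recombination events joining
a 5′ segment of one lineage to the 3′ segment of another at a fixed
crossover; gene-conversion events copying a fixed tract; deliberate
parallel substitutions shared by named lineages; outgroup-private
substitutions; markers with segment-aware inheritance through events; and
per-population sampling multiplicities. Output is a pure function of the
configuration (one global seed), and ground truth is emitted alongside.

What the generator does **not** emulate: coalescent time structure and drift,
mutation-rate heterogeneity, recurrent mutation (except where injected
deliberately), genotyping error, and ascertainment bias of SNP panels.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under its own model assumptions, not robustness to every
property of population data.

Fixtures:

* **Worked model** (15 sites, 4 haplotypes): parents with five and four
  pre-event substitutions, a crossover between sites 6 and 7, post-event
  substitutions 13 (p1), 12 (p2), 7 (r1), outgroup-private 3, 10, 14, and
  the reciprocal recombinant lost. All expected values (external branches
  {9,13,15}/{1,6,12}/{7}, singletons 3/3/1, supports {2,4,5}/{8,11},
  interval (5,8), costs (2,3)) are hand-derivable and frozen in tests. One
  stated pairwise distance follows from the vectors as d(p2, r1) = 7
  (= |{1,6,12}| + |{2,4,5,7}|).
* **Synthetic 54-site ABO reconstruction**: population reference data for
  the region is not shipped, so a stand-in matrix was *constructed* whose
  five haplogroup representatives (A101-A201-O09, B101, O01, O02, O47, plus
  chimpanzee) exhibit the reported informative-site classes: O01 with B101
  at {11,19,20,21,23,25,28,29,30,31,32}, O01 with O02 at {42,47,48,49}, the
  A haplogroup with O01 at {9,13,15} and with B101 at {36,37,46,50,51,52,53};
  site 54 homoplastic across lineages; site 38 a parallel change in B101 and
  O02 that leaves O01 matching the outgroup (the step-C veto); Δ261 between
  sites 15 and 16 carried by the O lineages; singleton counts 1/3/2/4/3 so
  external-branch comparisons resolve strictly. Everything asserted on this
  matrix tests the *algorithms* against a known construction, not the
  HapMap data themselves.
* **Step-E preference fixture**: a five-haplotype set where two parental
  quartets survive steps C–D for the same candidate and the scan must prefer
  the parent pair with the larger singleton sum — the longer-external-branch
  parent — mirroring the documented substitution of one O-lineage parent
  for another at step E.
* **ABO scenario preset** (60 sites): the inferred gene history — B-type
  and O-type lineages diverging from an A-like ancestor, O01 as a
  B101 × O02 product carrying the transferred deletion marker, A101 joining
  B101's intact-exon-6 5′ side to O01's 3′ side, an O02 × B101 product
  (XV) carrying the deletion, plus the parallel change that triggers the
  step-C veto on O01. The full six-lineage set exceeds three reticulation
  dimensions by construction, so network analysis proceeds on curated
  subsets, as it must on the real data.

### Recovery experiments

The default design uses 40 sites, a crossover after site 20, three shared
substitutions per parental segment (two is the minimum for a non-degenerate
interval; three leaves headroom), three post-event private substitutions
per parent, one for the recombinant, and three outgroup-private changes —
worked-model-like proportions at a size where 100 replicates run in
seconds. Under infinite sites this geometry guarantees detection, so the
observed rates (detection 1.0, interval coverage 1.0, null false positives
0.0, quartet detection 0.0 after an outgroup-parallel injection) are
property checks, not statistical estimates.

## Numerical and determinism choices

* All tie-breaks are explicit: lexicographic name order for modal
  representatives and node iteration; strict inequalities for external
  branch comparison and step-D disjointness; ties at step E return all tied
  quartets flagged.
* Single global seed per simulation; replicate seeds are drawn from one
  generator; every randomized path in tests and the acceptance script is
  seeded.
* Pipeline bundles are byte-stable: sorted JSON keys, ordered graph
  construction, no timestamps. A stage failure removes partial outputs and
  re-raises with the stage name.
* The CLI is a thin veneer; every subcommand is one or two library calls.

## Known limitations

* The network detector requires both parental lineages in the sample; it
  cannot call a recombinant whose parent is missing (by design).
* Gene-conversion mosaics are only vetoed (step C) or surfaced as
  interleaved-support errors, never resolved into tracts.
* The quartet scan reports the single best quartet; secondary events in the
  same selection require re-running on subsets.
* Multistate characters, weighted median-joining (ε-networks), and
  divergence-time estimation are out of scope.
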