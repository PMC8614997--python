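# Methods

This note records the models, conventions and numerical choices behind
phagemosaic, in the order data flows through the package.

## Synthetic ancestor panels

Ancestor genomes are simulated under the Jukes–Cantor (JC) substitution
model. The requested pairwise mismatch fractions `p_ij` (entries in
[0, 0.2]) are converted to JC distances `t = −(3/4)·ln(1 − 4p/3)`, an
additive tree is fitted by neighbor joining (scikit-bio), and a random
root sequence is evolved down the tree: across an edge of JC length
`t`, each site flips with probability `(3/4)(1 − e^{−4t/3})` to a
uniformly chosen different base. Because JC transition matrices
compose, the *expected* leaf-to-leaf mismatch fraction equals the
request exactly; the measured value fluctuates with binomial error
`√(p(1−p)/L)`. Matrices violating the triangle inequality, or whose
fitted tree needs a negative branch, are rejected with an explanatory
error — they are not realizable by any substitution process of this
kind.

Substitutions only: the panel stays collinear (a gap-free multiple
alignment of itself), which is what the attribution and segmentation
machinery assumes. Indel evolution, rearrangements and horizontal
acquisition of novel genes are deliberately not modelled; passing tests
therefore demonstrate correct recovery of planted structure under
collinearity, not robustness to structural variation. Real bred-phage
panels within one genus are highly collinear, but real data should be
pre-aligned before segmentation.

CDS features are tiled deterministically: equal-length genes (a
multiple of 3) separated by fixed 60-bp intergenic spacers, with
identical coordinates in every ancestor. This makes homolog mapping
exactly checkable. Default panel conditions mirror the breeding
setting the package targets: 3–4 ancestors of which two are nearly
identical (divergence 0.005, i.e. 99.5 % identity) and the others
diverge by ~5–9 % — typical within-genus distances for tailed-phage
panels; the near-identical pair is what produces jointly attributable
"AB" stretches.

Progeny construction is fully deterministic: explicit crossover
positions `(position, target ancestor)` switch the template, then
explicit point mutations are applied. No recombination-tract length
distribution is assumed — none is known for this system — so the
caller plants crossovers where the experiment or test requires them.
Mutations are applied after recombination, so a planted mutation may
coincide with a diagnostic site; it is de novo only if it matches no
ancestor.

## Plate and spot-assay simulation

One OD600 reading per (strain, phage-or-control, timepoint, replicate).
Untreated controls grow to `growth_od` (default 1.0, a typical
stationary plate-reader value) at 24 h and 60 % of it at 6 h.
Suppressed wells sit at the blank level (0.02); *resistant regrowth*
wells are suppressed at 6 h but reach 90 % of control by 24 h —
emulating the resistance evolution commonly seen in suspension assays
between 6 h and 24 h. Gaussian noise (sd `noise_sd`, default 0.02 OD)
is truncated at zero. Two replicates by default for kinetic plates,
three for MOI titrations. The generator does not model growth
kinetics, partial suppression, or edge effects; tests on it verify the
statistics' accounting, not robustness to messy real plates.

## Homolog mapping and identity

Each progeny CDS is placed into every ancestor genome by infix
edit-distance alignment (edlib, mode HW), which aligns the whole CDS at
its best location. Identity = matches / alignment columns, gap columns
counting as mismatches — the strictest common convention; the paper-
style notion of "best matching ancestor" is then the ancestor with the
fewest integer mismatches. An ancestor is *not found* for a CDS when
aligned coverage falls below `min_coverage` (0.5) or identity falls
below 0.7: the best chance placement of an unrelated nucleotide
sequence in a long genome scores ≈0.5–0.6, while genuine homologs in a
panel of related phages score ≥0.8. Nucleotide identity is used
throughout; amino-acid comparison would blur the diagnostic sites the
segmentation needs.

## Attribution

Ties are decided on integer mismatch counts, not floating-point
identities: the label set of a CDS is every found ancestor within
`tie_margin` (default 0, exact co-optimality) mismatches of the
minimum. "Identical to both" — two ancestors at 0 mismatches — thus
yields a dual call naturally. A CDS whose best identity is below the
`identity_floor` (0.8, configurable and recorded in output metadata) is
classified *none*: an operational cutoff for "no recognizable
relation". Composition summaries report dual/multi classes as their own
categories (bp and percent of total coding length) rather than
splitting them fractionally, because a jointly attributable stretch is
genuinely ambiguous. A CDS that is internally chimeric receives the
label of its overall best match (its majority segment); the
segmentation module flags it explicitly.

## Minimal-switch segmentation

Diagnostic sites are alignment columns where the ancestors are not all
identical; each site supports the subset of ancestors matching the
progeny allele. The segmentation minimises
`c·(#sites whose support excludes their label) + λ·(#switches)` by
dynamic programming over (site, label) — exact, O(sites·labels²).
Defaults `c = 1`, `λ = 2`: a switch must be supported by at least three
concordant sites to pay for itself, a parsimony prior appropriate for
panels where diagnostic sites are dense relative to recombination
tracts. λ is the one knob that matters and is logged in output
metadata. Ties between co-optimal paths are broken by fewest switches,
then by panel order, making results deterministic.

Three refinements deal with ambiguity:

* **Sites matching no ancestor** (candidate de novo mutations) cost the
  same under every label, so they can never force a switch; they are
  routed to the de novo caller.
* **Breakpoint bounds** are taken from the flanking *firm* sites — the
  last site supporting the left label but not the right, and the first
  site supporting the right label but not the left. Sites in between
  are consistent with either ancestry (every co-optimal path switches
  somewhere inside), so this open interval is the only one guaranteed
  to contain the true crossover. The midpoint is reported for
  convenience only; downstream analyses should use the interval.
* **Segment label sets** are merged over the segment's *core*: boundary
  sites that the neighbouring segment's label also explains for free
  are excluded before computing which labels tie for minimal cost.
  Without this, a boundary site sourced from the neighbouring ancestor
  could break the joint labelling of a stretch where two near-identical
  ancestors are indistinguishable.

A gene is flagged **chimeric** when a breakpoint interval lies strictly
inside it — the switch must then have happened within the gene. An
interval straddling a gene boundary (crossover in an intergenic spacer,
or unresolvable to one side) does not trigger the flag. Segments
spanning fewer than `min_support` (2) sites are kept but flagged
low-confidence.

Segment genomic extents, when needed as lengths (e.g. "the first 2.3
kbp of the gene"), partition the region at breakpoint midpoints, with
the outer segments extended to the region edges; the resolution of such
lengths is therefore one inter-diagnostic-site spacing (~20 bp at 5 %
ancestor divergence).

## De novo variants

A position is de novo iff the progeny allele differs from every
ancestor allele — including positions in dual-attributed stretches
(must differ from both) and non-diagnostic columns. Coding variants are
annotated on the coding strand: codon number = floor(offset/3) + 1,
effect `<refAA><codon><altAA>` or `syn`, translated with the
bacterial/phage genetic code (table 11; identical to the standard code
for all substitutions simulated here). The reference codon is the
progeny codon with the variant base reverted to the attributed
ancestor's allele when an attribution is supplied, else to the modal
ancestor allele (ancestors may disagree at a de novo position; the
modal choice is reported alongside all per-ancestor alleles so nothing
is hidden).

## Host-range statistics

* OD ratio = treated / control; control wells must be positive.
  Classification is strict: ratio < 0.1 is *suppressed*, exactly 0.1 is
  growth. No blank subtraction by default (optional when a blank column
  is provided).
* KHR per replicate = 100 × suppressed strains / strains; the headline
  number is the mean over replicates ± sample SD, with the strict
  per-strain consensus (suppressed in k of n replicates) reported
  alongside as a matrix of codes — both conventions are emitted because
  either may be wanted.
* PHR counts only *clear* plaques; opaque lysis is negative. Duplicate
  strain rows are rejected.
* EOP = PFU(test strain) / PFU(propagation host); zero test PFU is 0
  with a below-detection flag, and EOP is invariant under rescaling all
  titers.
* MOI profiles aggregate replicates by per-strain majority (ties → not
  suppressed) at 24 h; MOI levels lacking controls are omitted with a
  warning.
* The EOP/OD-ratio association uses Spearman rank correlation with a
  seeded permutation p-value (≥10 000 permutations): rank-based because
  EOP spans orders of magnitude and its zeros must be floored (at one
  tenth of the smallest positive value, a nominal detection limit);
  permutation-based because no distributional form is defensible at
  panel sizes of 20–50 strains. Constant inputs give a degenerate,
  not-significant result instead of an error.

## Scenario reconstructions

`phagemosaic.scenarios` rebuilds two described mosaic loci at full
scale: a 3000-bp internally chimeric tail-fiber gene (2300 bp C /
400 bp A≡B / 300 bp C) and a 17-gene, ~20-kb region with eight
crossovers and one de novo Gln166→Arg change. Where the locus
description requires the near-identical pair to be *locally identical*
(the jointly attributed stretches), the builders copy A onto B within
that window; elsewhere the pair keeps its global 0.5 % divergence. The
sources of the genes between the described ones are not constrained by
any observation; the reconstruction assigns them so that all eight
crossovers separate strongly divergent sources and are therefore
unambiguously recoverable. These problem sizes (3–21 kb genomes, ≤4
ancestors) resolve every planted feature while keeping the whole test
suite and the acceptance script in the seconds range.

## Known limitations

* Collinearity is assumed everywhere; indels, inversions and genes
  absent from all ancestors are out of scope (a CDS absent from the
  panel is classified *none*, nothing more).
* Breakpoint resolution is bounded by diagnostic-site density; between
  two identical ancestors there are no diagnostic sites and switches
  between them are undetectable in principle (reported jointly
  instead).
* The segmentation is a parsimony method, not a probabilistic model:
  it reports no posterior uncertainty beyond the breakpoint intervals
  and the low-confidence flags.
* Host-range statistics treat wells independently; no growth-curve
  kinetics, no plate spatial effects, no ANOVA-style modelling.
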