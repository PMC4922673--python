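# Methods

`simcyto` analyses the polytene-chromosome cytogenetics of the *Simulium
cholodkovskii* lineage of black flies (Diptera: Simuliidae): three species
(*S. cholodkovskii*, *S. decimatum*, *S. nigricoxum*) that all carry a unique
whole-arm reciprocal translocation (IS + IIIL, IL + IIIS) on top of 14 fixed
inversions relative to the standard banding sequence of the subgenus
*Simulium*. This note records the models, conventions and numerical choices
behind each stage.

## Banding-sequence model

A chromosome arm is an ordered tuple of band tokens `(section, subband,
orientation)`. Sections are the 1–100 numbering of the subgeneric standard
map; one token per section by default, finer where a named rearrangement
resolves inside a section (the provisionally attributed band at section 7 of
IS, and the two bands of section 85 removed by the IIIL 85d deletion).
Tokens carry an orientation flag so that inversion composition is an exact
involution, but comparisons are unsigned by default: polytene maps record
band *order*, not strand.

Inversion breakpoints are 0-based half-open inter-token positions, which
makes composition of overlapping inversions unambiguous. Published maps
resolve breakpoints only to within one or two fine bands and give no numeric
coordinates, so the packaged registry defines a self-consistent reference
geometry honouring every stated structural constraint: IS-18/IS-19 and
IS-18/IS-21 each share a coincident breakpoint, IS-21 lies entirely inside
IS-20 (the pair is absolutely linked), the IIS-6 break coincident with an
IIS-1 breakpoint is stored as two mutually exclusive alternatives (6a the
default), and the interchange acts at whole-arm level with the centric
region atomic — the proximal- and distal-break derivations are both
representable through the centric assignment, since the two cannot be
distinguished microscopically.

`verify_derivation` recomposes a scenario's steps onto the standard and
compares band order; independently of that composition it cuts the derived
sequence into maximal fragments contiguous (possibly reversed) in the
standard and letters them by standard position, so that alphabetical
reordering must reconstruct the standard exactly — the check the published
figure captions describe. Fragment *counts* are reported but not asserted
anywhere: the figure-caption lettering convention cuts more fragments than
maximal decomposition yields, and only reconstructability is well defined.

Minimum inversion distances use breadth-first search over unsigned reversal
space with a visited set and an explicit depth guard that raises rather than
returning a truncated answer. This is exact and fast at cytological scale
(≤ ~8 tokens); the test suite cross-checks it against an independent
iterative-deepening search on random 7-token orders.

## Population genetics

The observation unit is one larva: site, sex, per-rearrangement copy count
(0/1/2 rearranged homologues = ss/si/ii), and the sex-chromosome
configuration read from the homologues (X0Y0 = microscopically
undifferentiated; X0Y1…X0Y4 = a Y demarked by one to four linked inversions
of the nested IS series; X1/Y1 = the *S. nigricoxum* IIS system).

* Frequencies are rearranged constituents over `2 × larvae with data`,
  pooled across sites by constituent counts. Presentation follows the
  survey's dialect: two decimals, round-half-to-even computed exactly on
  rationals (1/40 prints 0.02), `<0.01` for positive raw values below 0.01,
  and `1.00` reserved for true fixation.
* Hardy–Weinberg: Pearson chi-square of the three genotype classes against
  expectations at the observed allele frequency, df = 1, no continuity
  correction (this reproduces the published χ² = 0.42 for ss=29, si=34,
  ii=7). Monomorphic input raises a degenerate-test signal.
* Sex linkage is a pure function of the evidence counts plus the recorded
  configurations: fixed (two copies everywhere), X-linked (all females
  homozygous, all males hemizygous), Y-linked (every carrier a male with a
  differentiated-Y configuration, single copy), Y-linked with X occurrence
  (the same plus rarer female carriers on a differentiated X — the IS-23
  situation, which demarks both a genetic X and Y). Single-carrier Y calls
  (IS-25, IS-26) cannot rest on statistics; they rest on the configuration,
  exactly as the underlying slides were read. Sex-linked entries are routed
  out of the numeric table into categorical marks (X, Y, Y/X).
* The census reports configuration percentages (one decimal, half-even) per
  sex with every larva of that sex in the denominator; the one decimatum
  male whose IS-20,21 homologue could not be attributed to X or Y appears as
  an `unresolved` category — the published percentages are x/16.
* The hybrid screen flags larvae heterozygous for at least one diagnostic of
  each parental set (diagnostics: near-fixed inversions, > 0.95 in
  *S. cholodkovskii* — IS-20, IS-21, IIIL-16; > 0.82 in *S. decimatum* —
  IIS-7, IIL-18); completeness is the heterozygous fraction of the combined
  sets and a full F1 carries them all.

### The encoded survey

Only IS-22's genotype counts were published; all other cells are rounded
frequencies plus footnote censuses. `lineage.build_records` reconstructs a
deterministic 138-larva table whose realised counts reproduce every
published cell under the dialect above, with the jointly constrained
carriers placed explicitly (the linked IS-20/21 pair, IIL homologue classes
consistent per arm, the nested Y series, the X/Y double-heterozygote males,
and the single partial-hybrid male — heterozygous for IS-20,21, IIS-7 and
IIL-18 but lacking IIIL-16). Unconstrained rare carriers are placed at fixed
indices; any placement matching the marginal counts reproduces the published
analyses, so this choice is presentation, not inference.

## Cytophylogeny

Characters are rearrangements with per-taxon states {absent, polymorphic,
fixed, X-linked, Y-linked}. Polarity is by outgroup comparison and is
arm-limited: IS, IIL, IIIS, IIIL and the interchange resolve against both
outgroups (*S. erythrocephalum*, *S. vittatum*), IL against
*S. erythrocephalum* only (single-outgroup calls stay flagged), and IIS
against neither — all IIS characters, and the unresolved IIIL repattern, are
unresolvable cells that never contribute to a tree score. Presence at any
frequency counts as present-polymorphic (the shared polymorphisms reach as
low as 0.02).

Tree search enumerates all rooted binary topologies (exhaustive; capped at
8 taxa) and scores each derived character under Dollo parsimony: one origin,
losses free to recur. State changes run on a star with polymorphic at the
centre — fixation, linkage or loss passes through a polymorphic stage — and
edge costs are star distances. Two choices matter and are deliberate:

* **Stem acquisition is charged.** Each character pays the distance from
  absent to its root state. With a free root, a derived state present in two
  of three taxa costs 1 on *every* topology (gain on the internal edge, or
  stem origin plus one loss), and a linked autapomorphy is cheaper on
  topologies that place its taxon at the root; charging the stem makes
  shared derived states informative and removes the root artefact. On the
  lineage matrix the published topology
  `((cholodkovskii, decimatum), nigricoxum)` is then uniquely optimal
  (score 64 against 72 for both alternatives — the margin is exactly the
  8 shared polymorphisms).
* **Distinct non-polymorphic fates force a polymorphic ancestor.** In
  minimal-change reconstruction of ancestral states, a node whose
  descendants demand different terminal fates (fixed in the Palearctic pair,
  X-linked in *S. nigricoxum* for IIS-4) takes the polymorphic state — the
  mandatory intermediate — rather than an arbitrary tie-break.

Shared polymorphisms are counted toward grouping but carry the standing
caveat that introgression between the sympatric pair is an equally plausible
source; `infer_tree(include_polymorphic=False)` (CLI
`--exclude-polymorphic`) rescores the search without them. Co-optimal
topologies are returned in `ties`, never silently broken.

## Translocation establishment model

Gamete and cross arithmetic is exact (`fractions.Fraction`). A heterozygous
male under perfect alternate disjunction produces four balanced sperm
classes at 1/4 each (translocated/typical × X/Y; 50% X-bearing because the
sex chromosome, II, segregates independently of the interchange between I
and III). Disjunction fidelity α moves mass (1−α) to unbalanced classes,
split evenly over sex alleles; unbalanced zygotes are inviable and removed
before selection. Females contribute one functional egg per meiosis, always
balanced and X-bearing, so the egg distribution is per functional egg.
Heterozygote × heterozygote therefore yields 1 typical : 2 heterozygote :
1 translocation homozygote among viable offspring, and homozygotes first
appear in generation 2 (F2) of the founding scenario.

The population layer is a two-sex Wright–Fisher process: constant even N,
equal sex ratio each generation, non-overlapping generations. Each of the N
offspring draws a mother uniformly among females and a father among males;
a zygote receiving an unbalanced paternal complement causes the whole draw
to be repeated, so α < 1 acts as a fertility cost on heterozygous males (the
only fertility lever; heterozygote fertility is otherwise full). Viability
selection 1 : 1 : 1+s is applied by rejection. Assortative mating strength
`a` is the probability that a translocation-*carrier* female restricts her
draw to males of her own genotype class; the typical majority mates at
random. (A rule that also lets typical females assort would bar the lone
founding male from ever mating and send the fixation probability to zero at
a = 1, the opposite of the scenario the parameter exists to express.)

The sex-weighted allele frequency (p_females + p_males)/2 is the martingale
coordinate of the neutral process; from one heterozygous male it starts at
1/(2N), which is therefore the neutral fixation probability (observed
0.02535 at N = 20 over 20 000 replicates, within binomial error of 0.025).
Fixation probability is monotone in s and in α on a seeded grid. One master
seed drives deterministic per-replicate streams (NumPy `SeedSequence`), so
identical configurations reproduce byte-identical results.

## Synthetic data

`synth.generate_population` draws genotypes as two Bernoulli allele copies at
the target frequency (Hardy–Weinberg proportions; with `hw_sampling=False`
counts are allocated deterministically at expectations). Constraints are
enforced absolutely for every seed: linked pairs share one draw, Y-series
members are assigned through a per-male configuration draw (matching how the
footnote censuses are parameterised — configuration probabilities, not
allele frequencies), and X/Y-exclusive pairs produce homozygous-X females
and double-heterozygote males. What the generator does *not* emulate:
site-level structure beyond the spec'd frequencies, linkage disequilibrium
other than the declared absolute constraints, observation error in reading
bands, and within-arm exclusivity of alternative sequences (e.g. IIL-16/17/18
compete for homologues in reality; synthetic columns are independent unless
constrained). Passing tests therefore demonstrate correctness of the
analyses under the survey's declared structure, not robustness to misread
slides.

## Problem sizes and tolerances

Chosen once, as the package's own calibration: HW type-I error check at
n = 400, 800 replicates (acceptance band 0.03–0.07); synthetic-survey HW
calibration over 300 seeds at the survey's n = 70 (rejection rate < 0.09);
martingale check 6 000 replicates × 15 generations (band ± 0.006); neutral
fixation 20 000 replicates with a ± 4-standard-error band; reversal-distance
oracle on 7-token orders (state space ≤ 5040). Exact quantities (gamete
distributions, crosses, frequencies, census percentages) are computed on
rationals and asserted exactly.

## Known limitations

* Registry breakpoint positions are a reference geometry, not measurements;
  any analysis depending on *where* (rather than whether) sequences differ
  inherits that convention.
* The reconstructed per-larva table matches published marginals and
  footnotes but not the unpublished joint genotype distribution.
* The Yukon population (a Y-chromosome variant of *S. nigricoxum*) is not
  encoded as a fourth tip; its IIS/IIL characters would be unresolvable and
  would not change the topology.
* The simulator has no meiotic mechanics below the gamete-class level
  (no adjacent-1/adjacent-2 classes, no chiasma placement) and no spatial
  structure.
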