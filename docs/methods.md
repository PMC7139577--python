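# Methods

This note records the models implemented in `rosfam`, their assumptions,
the parameters that matter, and the choices made where the design was
genuinely open.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study system and data model

The package targets comparative analysis of the 11-family ROS gene network
in small sets of closely related genomes.  Its data layer is deliberately
minimal: a `GeneModel` (GFF3-convention coordinates — 1-based, closed
intervals — family, status, source, CDS, protein) and an
`OrganismAnnotation` (ordered gene collection plus chromosome sizes).
Status classification is purely sequence-based:

- **pseudogene** — internal stop codon, or length not divisible by 3
  (frameshift);
- **partial** — undetermined nucleotides (N) or a missing start/stop;
- **complete** — otherwise.

An N-containing sequence that *also* carries an internal stop is a
pseudogene: a stop/frameshift is direct evidence of non-functionality,
whereas Ns only indicate missing data.  This precedence is a package
decision; counting conventions for N-containing genes are not fixed by any
single standard.

Gene names follow the positional convention: prefix + family tag + 2-digit
number in (chromosome, start) order, with chromosome labels sorted
numerically before lexically.  Orthologs in non-reference organisms reuse
the reference ortholog's suffix under their own prefix, so `EgrPrx07` and
`EguPrx07` name one ortholog group.

## The synthetic-data generator

The generator is a forward model of the processes the analysis stages are
meant to *infer*; it exists so every stage can be scored against known
event truth.

**Species tree.** Ultrametric, fixed topology
`((camaldulensis,(gunnii,(grandis,globulus))),outgroup)`, default split
ages 0.15 / 0.89 / 1.27 MYA with the outgroup at 112 MYA.  Family
simulations default to the four-taxon ingroup tree (root 1.27 MYA); the
deep outgroup branch is only used for dating runs, where it would otherwise
contribute nothing but saturation.

**Gene families.** Continuous-time birth–death per gene with exponential
waiting times (Gillespie sampling per branch): duplication rate λ, loss
rate μ, and pseudogenization rate ψ (complete genes only), all in
events/gene/MY.  A duplicate is inserted adjacent to its parent with
probability `tandem_prob` (10 kb from it — inside the 15 kb cluster rule)
and otherwise at a uniform dispersed position (20 kb gaps — outside it), so
tandem-cluster detection is genuinely exercised by the layout.  Every event
is logged with its placement; replaying the log from the root inventory
reproduces the leaf inventories exactly, which is the basis of the
recovery tests.

Default per-family parameters mirror the contrast the study system shows:
one large duplication-rich family (CIII Prx: 170 initial copies, tandem
arrays of 8/8/9/12/6, λ = 0.03, μ = 0.05, ψ = 0.05, 25 % ancestral
pseudogenes), mid-sized dynamic families (Kat, 1CysPrx, GPx), and static
low-copy families (Rboh 7, PrxII 3, APx-R 2, singletons for 2CysPrx, PrxQ,
DiOx).  The event rates were sized so that pairwise gained/lost counts on
the ingroup tree land in the low tens, matching the magnitude of published
cross-species comparisons; they are test conditions, not estimates of
*Eucalyptus* biology — no generative process is published for these
genomes.

**Sequences.** Indel-free codon-aware evolution: candidate substitutions
arrive at `clock_rate` per site per MY (Jukes–Cantor-uniform over targets),
synonymous candidates are always accepted, nonsynonymous ones with
probability min(1, ω), and candidates creating stops (or breaking the
start/terminal-stop codon) are rejected — so ω is the generative analogue
of Ka/Ks and functional genes keep intact ORFs.  Pseudogenes evolve free of
all constraints and receive one forced internal stop at pseudogenization.
Because site counting in the NG86 estimator normalizes away the same
stop-codon exclusions the generator applies, neutral simulations (ω = 1)
estimate Ka/Ks ≈ 1 without bias; the acceptance script verifies this by
Monte Carlo.  Default `clock_rate` is 0.002 substitutions/site/MY — a
conservative angiosperm-scale nuclear rate giving ~0.5 % ortholog
divergence across the 1.27-MY ingroup depth.  Default CDS length is 333
codons (~1 kb), the size scale of class III peroxidases.

**Expression.** Negative-binomial counts per non-pseudogene gene per
tissue (mean `mean_depth` = 50, dispersion 5 over seven vegetative/floral
tissues); pseudogenes get zeros.  Dispersion → ∞ recovers Poisson, which
the tests check by moments.

**Emission.** GFF3 (`gene`/`mRNA`/`CDS`; pseudogenes flagged
`pseudo=true;biotype=pseudogene`), genome/CDS/protein FASTA (genes embedded
in random background sequence, reverse-complemented on the − strand), a
long-format counts TSV, and truth tables (presence and event log).  About
5 % of complete leaf genes receive an N-stretch ("partial" models) and 5 %
are labelled as PCR-detected, emulating incomplete assemblies and targeted
re-sequencing.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: indels and alignment uncertainty, rate
heterogeneity across sites or branches, codon-usage bias, GC-biased gene
conversion, recombination, whole-genome duplication, and assembly artefacts
beyond uniform N-stretches.  Recovery rates measured here are therefore
upper bounds for real annotations.

## Ortholog matching and presence/absence

Reciprocal best hits by percent identity within the same family: protein
identity for intact genes, CDS identity whenever a pseudogene is involved
(its translation is unreliable).  Equal-length sequences (the indel-free
simulator case) are compared site-by-site; unequal lengths fall back to
global affine-gap alignment.  The default threshold is 70 % amino-acid
identity — permissive within a genus, with the family restriction
preventing cross-family capture.  Exact identity ties (a freshly born
duplicate still identical to the true ortholog) are broken toward the
closest positional rank within the family, then lexicographic id: close
relatives conserve gene order, and a pure lexicographic tie-break would be
arbitrary.  This is a tie-break only, not a synteny-based orthology method.

The presence matrix is built against a chosen reference organism; genes
unmatched to the reference are reconciled transitively among the other
organisms, taking candidate pairs in decreasing identity order and skipping
any union that would place two genes of one organism in the same group
(conflicts therefore resolve to the highest identity, deterministically).
Under realistic gain/loss rates a small fraction of matrix cells is wrong
for an irreducible reason: when an ortholog has been lost, its slot is
taken by a near-identical paralog that no identity-based method can
distinguish.  The exact-recovery guarantees are therefore stated — and
tested — on the truth-map path (no sequence noise), while sequence-based
matching is scored as an agreement rate.

Presence patterns are reported neutrally (gained/lost/common per organism
pair, Venn regions) rather than as polarized gain *events*: without an
outgroup, a gene present in one organism and missing elsewhere cannot be
attributed to gain or loss.

## Duplication detection

- **Tandem clusters**: single-linkage chaining of same-family neighbours
  with intergenic distance (next.start − prev.end − 1) below `max_gap`
  (default 15 000 bp, the genome-wide average intergenic distance for the
  study system, exposed as a parameter).  Interleaved genes of other
  families are ignored by default (`family_restricted`), since published
  clusters are family-named.
- **Segmental blocks**: longest strictly increasing (direct) or strictly
  decreasing (inverted) chains of paralog anchor points per chromosome
  pair, greedy extraction of disjoint chains, `min_block` = 3 pairs — a
  2-pair "block" is too easily coincidence.
- **Duplication order**: each internal node of a midpoint-rooted
  neighbor-joining tree over member CDS p-distances is one duplication;
  events are ordered by decreasing node height, where height is the *mean*
  distance to descendant tips — the strict-clock age estimate.  (The
  maximum would be inflated by single fast-evolving tips and demonstrably
  misorders young cherries.)  Order recovery is inherently noisy when
  successive duplications are separated by few substitutions, so the tests
  score adjacent-pair order concordance aggregated over 20 replicate
  ladders rather than demanding a perfect order per replicate.

Chromosome statistics exclude unplaced scaffolds (labels `X`, `XX`) from
percentages; percentages are rounded half-up to one decimal (the built-in
banker's rounding would not reproduce printed tables), densities are genes
per Mb.

## Family statistics

Coverage = 100·db/(db+pcr); prediction accuracy = 100·correct/total
(2 decimals); new-gene percentage = 100·pcr/total.  All use half-up
rounding at printed precision.  Conservation categorization calls a family
**duplicated** if its cross-organism size coefficient of variation is ≥
`cv_threshold` (default 0.15), any organism holds ≥ 2× the minimum size, or
tandem clusters were detected for it; otherwise **non-duplicated**.  The CV
threshold separates the two groups the study system exhibits given its
family sizes; it is exposed in the configuration.  Note that published
accounts place GPx inconsistently (listed once among the duplicated and
once among the stable families); `categorize_conservation` simply reports
the computed class rather than hard-coding either reading.

## Expression levels

level(family) = (family count sum / number of family genes) / network
total.  The numerator is an *average*, so levels do not sum to 1 across
families; they are scale-invariant and zero exactly when the family is
silent.  Pseudogenes are excluded from the family-size denominator — they
cannot be expressed, and counting them would deflate pseudogene-rich
families; whether published denominators included them is unstated, so this
is flagged as an interpretation.

## Ka/Ks (NG86) and divergence dating

Site counts: per codon position, the fraction of non-stop one-step changes
that are synonymous (renormalized so each position contributes exactly 1;
S + N = 3 × codons to 1e-9).  Differences: equal-weight average over all
orderings of the differing positions, excluding pathways through stop
codons (if every pathway is blocked, all are used so the count stays
defined).  Codons containing gaps/N in either sequence, and stop codons,
are skipped in both.  Jukes–Cantor correction; p ≥ 3/4 raises an explicit
saturation error rather than returning NaN; Ks = 0 yields an explicitly
undefined ratio, never a silent infinity.  The implementation is verified
against an independent exhaustive enumeration over all 61×61 sense-codon
pairs and cross-checked against Biopython's NG86 (whose stop-site
normalization differs slightly) at 10 % tolerance.  NG86 with equal
pathway weights was chosen because it is deterministic and
oracle-checkable; likelihood codon models are out of scope.

Selection classes: ratio < 1 negative, > 1 positive, within ±0.05 of 1
neutral (the classification in the source analyses is qualitative; 0.05 is
the package's tolerance), Ks = 0 undefined.

Dating: ortholog groups complete in every organism are concatenated (CDS,
lexicographic group order) into one "chimeric" sequence per organism;
pairwise Jukes–Cantor distances feed average-linkage (UPGMA) clustering,
which is the maximum-parsimony choice under the strict-clock assumption
already made; all node heights are rescaled by one factor so the outgroup
split equals the calibration age (112 MYA by default), making the
calibration node exact by construction.  Bayesian relaxed-clock dating is
deliberately out of scope; the strict-clock stand-in matches the clock
assumption the analysis makes anyway.  Acceptance uses split ages
(1, 2, 3, 10 MY) with clock 0.01/site/MY on 10-kb concatenations — ≥ 100
expected substitutions on the shortest branch — because the real
0.15/0.89/1.27-MYA estimates depend on the real genomes and are not
desk-reproducible; with a deep 112-MYA outgroup, any rate high enough to
resolve a 0.15-MY split would saturate the outgroup distance.

## Problem sizes and determinism

The simulated study dataset holds ~215 genes per organism across the 11
families (~870 total), 1-kb CDS, seven tissues.  Monte-Carlo checks use
100 pairs (neutral and purifying Ka/Ks), 50 dating replicates, 20
tandem-ladder replicates, and 1000 birth–death replicates for the Yule
expectation — sizes at which every check completes in seconds while
leaving Monte-Carlo error well inside the asserted bounds.  A single
integer seed drives every stage through hierarchically spawned
`numpy.random.SeedSequence` streams; identical (inputs, config, seed)
produce byte-identical pipeline outputs, and every report carries the
configuration hash in its header.

## Known limitations

- Identity-based RBH orthology without synteny or tree reconciliation;
  accuracy degrades when recent duplicates shadow lost orthologs.
- Whole-genome duplications are not called (no reproducible procedure is
  defined for them here); TD vs SD discrimination is purely positional.
- NG86 underestimates rates at high divergence (explicit saturation errors
  rather than corrections); no transition/transversion weighting.
- Strict-clock UPGMA dating has no rate-variation model and one
  calibration point; ages inherit any clock violation proportionally.
- The simulator's realism limits listed above bound what green tests imply
  about real genomes.
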