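# Methods

## The genetic design being modelled

A `C(1)RM, Dp(1;Y)` (or `C(1)DX, Dp(1;Y)`) female carries both of her X
chromosomes attached to one centromere, plus a Y chromosome onto which a
fragment of the *D. melanogaster* X has been translocated. Crossed to a male
of species *P*, her clutch segregates four genotype classes, each with
Mendelian expectation ¼:

| class | composition | fate in an interspecific cross |
|---|---|---|
| `nullo_X` | Y^P / Dp(1;Y^mel) | dies before cellularisation, every cross |
| `metafemale` | C(1)^mel / X^P | three X doses; (near-)embryonic-lethal |
| `attachedX_female` | C(1)^mel / Y^P | hybrid female; dies embryonic (san) or at pupation (sim/mau) |
| `dp_male` | X^P / Dp(1;Y^mel) | the assayed class: viable unless the duplication carries a dominant lethal |

Only `dp_male` sons routinely reach adulthood in hybrids, so the survival of
one cross series measures whether one duplicated X fragment, in single
dominant dose, is lethal to hybrid males — and the developmental checkpoint
census (fertilized embryos → hatched L1 → pupae → adults) tells at which
stage.

## Simulator

`simulate_cross` draws genotype counts from a symmetric four-way multinomial
and thins each class through the three stage transitions with independent
binomials. A `PlantedLocus` (band position, stage, penetrance, species set)
multiplies the `dp_male` survival at its stage by `1 − penetrance` whenever
the duplication interval contains the band and the paternal species is in
the set. Loci are points, not intervals — the simplest architecture under
which "overlap ⇒ possibly shared cause" has a well-defined ground truth.

Parameters and defaults:

- **Clutch size 300, 3 replicates per cross.** Three replicates is the
  screen's own census design; 300 embryos per replicate keeps binomial noise
  on a hatch proportion below ~2.5 percentage points.
- **Survival table** (per species × genotype, per transition): nullo-X 0 at
  hatch everywhere; santomea female classes 0.05 at hatch (escapers);
  sim/mau female classes 0.9 at hatch, 0 at pupation; intraspecific
  metafemales 0.05 per stage (overall eclosion 1.25×10⁻⁴, under the ~0.2%
  reported ceiling); intraspecific attached-X females and all `dp_male`
  0.9 per stage. The source observations are qualitative; these numbers are
  chosen once so that unperturbed crosses sit far above the 10% rule and
  fully penetrant lethals far below it, and they are stated in
  `default_survival_table`'s docstring rather than hidden.
- **Sex sorting.** Hatch counts include every genotype (embryos cannot be
  sexed at scoring), while pupal/adult tallies are male-only by genotype
  label, emulating mouthpart-pigment and *Sxl::GFP* sorting.
  `sex_sorted=False` tracks all classes, which is what the conservation
  property (all survival 1 ⇒ everyone eclosed) is tested against.
- **Nullo-X denominator.** Nullo-X zygotes are counted as fertilized embryos
  and embryonic deaths (the protocol counts all fertilized embryos, dead and
  hatched); `count_nullo_as_fertilized=False` probes sensitivity to the
  opposite convention.
- **Seeding.** One root seed; each cross derives its own
  `SeedSequence([root, crc32(stock|background|species|line)])`, so a single
  cross can be replayed without simulating the panel.
- **Default panel.** 40 stocks tiling the 120 (division × subdivision) slots
  of the euchromatic X with span 4 / step 3, i.e. adjacent stocks overlap by
  one subdivision. The planted architecture (9 embryonic + 3 pupal
  santomea loci; 2 larval sim+mau loci) places each locus in a
  tile-exclusive slot with carrier tiles pairwise disjoint, so its minimal
  region count is exactly the planted count.

What the generator does **not** emulate: cuticle phenotypes, mating
behaviour, sperm motility (insemination is a Bernoulli flag), egg-count
variation between females, background-specific sensitivity differences
(the C(1)DX-only lethality the real screen set aside), and duplications
whose endpoints are only partially included. Passing tests therefore show
the *inference machinery* is correct under the stated generative model, not
that real censuses satisfy that model.

## Lethality classification

Replicates of a cross are pooled; the verdict is the earliest transition
(hatch, then pupation, then eclosion) whose pooled survival falls below the
threshold (default 0.10). Earliest-stage precedence reflects observability:
a cross that dies as embryos never exposes its later stages. The embryonic
denominator is all fertilized embryos ("total" mode, as the rule is
printed), although only ~¼ of zygotes are the assayed male class; a
"male_only" mode dividing the male hatch tally by the Mendelian quarter is
available for sensitivity. Later transitions use individuals entering the
stage, preferring the sex-sorted male tally as the larval denominator.
Pooled-vs-per-replicate application of the rule is genuinely underdetermined
by the protocol; pooling is the default, with a majority-vote mode behind a
flag. Crosses with no replicates, fewer than `min_replicates` (default 3),
no observed insemination, or no embryonic progeny are excluded with
machine-readable reason codes — they measure reproductive isolation upstream
of zygote formation, not inviability.

A duplication is *called* lethal only when both attached-X backgrounds give
the same lethal stage. Disagreements (lethal in one background, or at
different stages) are kept in the output with a discordance flag; stocks
assayed in one background are flagged and never called.

## Minimal regions

"Two overlapping lethal duplications share their cause" is formalised as
minimum interval piercing: the smallest set of bands such that every lethal
interval contains one. The right-endpoint greedy is exactly optimal on
intervals, and the optimum equals the maximum number of pairwise disjoint
lethal intervals, making the count provably conservative. The pairwise
merging phrasing is ambiguous for chains (A∩B≠∅, B∩C≠∅, A∩C=∅); piercing
resolves the chain to two regions, the minimum consistent with "shared
cause". Piercing is done within each (paternal line, stage) class: a region
is one allele class acting at one stage, and one cytological neighbourhood
may house two regions of different stages. Ties on right endpoints break by
stock id for determinism.

## Statistics

- **Stage-uniformity χ²**: Pearson goodness of fit of the per-stage region
  counts against uniform allocation; upper-tail p via the regularized upper
  incomplete gamma (`exp(−x/2)` exactly at df = 2).
- **Homogeneity χ²** for r×k count tables, no continuity correction; zero
  marginals are an error rather than a silent 0/0.
- **Sidak threshold** `1 − (1−α)^{1/m}` for m independent comparisons.
- **Snowball comparison**: OLS fits of region count against Ks, degree 1 and
  2 (full polynomial with intercept; a pure `c·Ks²` form behind a flag), AIC
  under the Gaussian MLE with k = coefficients + 1 (the residual scale is a
  fitted parameter; the source does not state its convention). A fit with
  rss below the floor (default 10⁻¹²) is degenerate: its likelihood is
  unbounded, so it is reported with AIC = −∞ and a flag instead of a
  spuriously precise number. The five-point default dataset has three
  distinct abscissae, so the quadratic is always degenerate-perfect there —
  the qualitative preference (quadratic ≪ linear) is the reproducible
  statement; no published AIC magnitudes are reproducible from the five
  points under any convention we tried, and none are asserted.

Numerical notes: fits use `numpy.linalg.lstsq` on a Vandermonde design;
degree-d fits require n > d+1 points and ≥ d+1 distinct abscissae (named
"collinear design" error otherwise); χ² inputs are validated for positive
expectations and matching lengths.

## Problem sizes

The default analyses run a 40-stock panel × 2 backgrounds × 5 lines × 3
replicates of 300 embryos (≈ 360k simulated zygotes per pipeline run); the
recovery study repeats the single-line pipeline over 50 seeds. These sizes
give binomial standard errors an order of magnitude smaller than the 10%
decision margin, which is why recovery of the planted architecture is
essentially deterministic.

## Known limitations

- Cytological coordinates are ordinal; BED exports use band ranks and say
  so. No mapping to assembly coordinates or gene content.
- The screen detects complete lethality only; semi-lethal alleles and
  partial viability reduction are out of scope by design.
- A region may house several linked alleles; piercing cannot distinguish
  one allele from a tight cluster.
- Real-data mode trusts its input TSVs' replicate structure; it does not
  model between-vial variance (no mixed models here).
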