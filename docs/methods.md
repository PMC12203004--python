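# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## Normalization (geTMM)

Raw gene-level counts are processed in a fixed order: (1) cells with
`0 < count < min_count` (default 5) are set to zero; (2) counts become reads
per kilobase (RPK = count / (length_bp / 1000)); (3) trimmed-mean-of-M-values
(TMM) scaling factors are computed **on the RPK matrix** and each sample is
expressed per million effective RPK (effective library size = RPK column sum
× TMM factor). This length-then-TMM composition is the geTMM variant of TMM
normalization: it makes values comparable both across genes (length) and
across samples (composition bias).

TMM internals follow the canonical algorithm: the reference sample is the one
whose upper quartile of relative expression is closest to the mean upper
quartile; for each sample, M = log2 ratio and A = mean log2 abundance are
computed on library-size-scaled values over genes expressed in both members
of the pair; the most extreme 30% of M (each side) and 5% of A (each side)
are discarded by rank; the factor is 2 to the precision-weighted mean of the
surviving M values, with delta-method weights `1/count − 1/libsize` summed
over the pair. Factors are rescaled to geometric mean one. A single-sample
matrix takes factor 1 (no reference pairing is possible). This implementation
reproduces edgeR's `calcNormFactors(method="TMM")` to printed precision on
random matrices and is verified against a brute-force materialize-sort-trim
oracle to 1e-9 in the test suite.

One subtlety: the precision weights depend on absolute depth, so factors are
only approximately invariant to scaling a single sample's depth (within 2%
for a 3× change in the tests). `tmm_factors(..., weighted=False)` uses a
plain trimmed mean, which is exactly depth-invariant; the weighted mean is
the default because it is the canonical estimator.

**MAG activity filter.** For each sample, all genes of a MAG are zeroed when
fewer than `mag_on_threshold` of its genes have nonzero geTMM there. The
default threshold is 22 — the dataset-derived median used in the motivating
study. `"auto"` recomputes the median of gene-on counts over all
(MAG, sample) pairs, excluding pairs with zero active genes. Whether that
median should pool samples per MAG or treat each (MAG, sample) pair as one
observation is ambiguous in prose descriptions of the procedure; the
per-pair reading is implemented because the filter itself acts per sample.

## Response classification

For a MAG at a day, a gene is "expressed in treatment T" when its filtered
geTMM is nonzero in at least one replicate of (T, day) — the replicate-union
rule (an `all-replicates` rule is available). The expressed genes partition
into both / unamended-only / catechin-only, giving

* `%both` = 100 · n_both / n_total,
* `∆unique` = 100 · (n_unamended_only − n_catechin_only) / n_total.

Thresholds b = 26 and u = 25 (config) split the plane into six categories.
The printed inequalities make `|∆unique| = u` satisfy both a core and an
extreme rule; extreme categories (sensitive, stimulated, lost_function,
gained_function) are evaluated first so the boundary resolves to the extreme
reading — a 25-point asymmetry *is* a response. A grid enumeration test
verifies the six disjointified regions tile [0,100] × [−100,100] exactly
once. Classification depends only on the zero/nonzero pattern, so it is
invariant to uniform rescaling of expression; swapping treatment labels maps
sensitive↔stimulated and lost↔gained while fixing resistant/responsive.
MAGs with no expressed genes at a day are reported `inactive` and excluded
from per-day category proportions.

## Methanogen and carbon-cycle rule calling

Rules live in YAML as boolean expressions (`all`/`any`/`not`) over two
predicate types: "≥ k distinct identifiers from named gene set G" and
taxonomy guards (`column == value`). Identifiers are matched against the
catalog's `ko_id`, `cazy_best_hit` and `camper_id` columns. The shipped gene
sets (Mcr, Hdr, Wood-Ljungdahl, Mtr, ACS/CODH, acetate genes, mtxB
methyltransferases, methanogen hydrogenases) are curated KO defaults and are
deliberately configuration, not code.

Calling proceeds in two stages. *Potential* (from encoded genes, after
Mcr + Hdr confirmation): hydrogenotrophic requires all three of
Wood-Ljungdahl, Mtr and hydrogenase evidence (the conjunction reading of the
rule; each predicate is separately editable in config); acetoclastic requires
Methanosarcinia taxonomy plus ACS/CODH plus (acs, or ack and pta);
methylotrophic requires an mtxB gene. MAGs satisfying several rules are
multifunctional; a confirmed methanogen satisfying none has unresolved
substrate. *Active* (from expressed genes, per sample): at least one
Wood-Ljungdahl gene **and** one hydrogenase for hydrogenotrophic; an
expressed mtxB for methylotrophic; acs alone or ack + pta for acetoclastic
("acs or ack/pta" is read as allowing either acetate activation path).
Active Methanotrichales MAGs are forced to {acetoclastic} — the override is
absolute. MAGs expressing no methanogenesis genes, or too few to meet any
rule, are "ignored". Formate-linked hydrogenotrophy is not a separate
category; fdh evidence can be added as a gene set without code changes.

## Hydrogenase directionality

The shipped map translates (family, group) to one of four activity classes
following the hydrogenase database's activity annotations: group 1 and 2
[NiFe] are H2-uptake (the sensory 2b/2c and [FeFe] C groups are grouped with
uptake, noted in their provenance strings, since the class set has no
sensory tier); group 3a/3b/3d are bidirectional and 3c bifurcating; group 4
is H2-evolving; [FeFe] A1/A2 and B are evolving, A3/A4 bifurcating. A bare
[FeFe] "A" (subgroups unrefined) maps to bifurcating with a warning. Every
entry carries a provenance note and the map is a plain TSV users can
override. Unmapped groups are flagged `unmapped` and still aggregated, so
class totals always partition total hydrogenase expression. Bidirectional
and bifurcating are kept disjoint in totals.

Treatment contrasts use one-way ANOVA on log10(total + 1) per (class, day)
— "log-adjusted" is interpreted as log10 with a pseudocount of 1 —
BH-adjusted across the whole family of tests, with significance tiers at
adjusted p < 0.10 and < 0.05.

## The hydrogen ledger

Species are elemental formulas plus charge; cofactor couples are tracked via
pseudo-element moieties (`Nad`, `Ndp`, `Fdx`) chosen so each couple is
exactly balanced: NADH = NAD+ + 1 H atom + 1 electron; reduced ferredoxin
carries two electrons (charge −2) per unit, which makes Rnf
(Fd_red + NAD+ + H+ → Fd_ox + NADH) electron-neutral as written. All
coefficients are `fractions.Fraction`; there is no floating point anywhere
in the stoichiometry.

Shipped chemistry: catechin → taxifolin is a 4-electron oxidation (the C-4
methylene becomes a ketone; +H2O, 2 NAD+ reduced); each aromatic
dehydroxylation (taxifolin → eriodictyol → naringenin; taxifolin →
dihydrokaempferol) consumes one NADH and releases water; FCR C-ring
reduction consumes one NADH; chalcone-isomerase ring contraction and the
hydrolytic cleavages (phloretin hydrolase, auronol cleavage) are
redox-neutral. The maesopsin cleavage to phloroglucinol +
4-hydroxyphenylacetate leaves one carbon, which the shipped reaction
releases as formate — the balanced resolution of an otherwise
carbon-deficient product pair. Phloroglucinol fermentation is lumped as
`phloroglucinol + H2O + NADPH + 2 NADH + Fd_ox → acetate + butyrate + NADP+
+ 2 NAD+ + Fd_red`: the NADPH is the phloroglucinol-reductase step, the
Fd_red the electron-bifurcating butyryl-CoA dehydrogenase. A frequently
quoted "three acetates and one butyrate" product slate cannot be carbon-
balanced on a single phloroglucinol (C6 vs C10) and is therefore *not*
enforced; the acetate + butyrate stoichiometry is exactly balanced and
makes phloroglucinol fermentation the dominant source of oxidized NAD(P)+,
consistent with the expression evidence. Proton-motive side effects of
PntAB/Rnf (ion translocation, ATP yield) are annotation only and excluded
from the H2 arithmetic.

`net_reaction` sums a route and requires all metabolite intermediates to
cancel; `apply_recycling` then applies PntAB, Rnf, [FeFe]-A3 and [NiFe]-4e
in order, each the maximal integral number of times that drives its target
couple to zero, and verifies every couple closes. The net H2 of the closed
reaction is order-insensitive for any system order that closes the books
(a consequence of electron conservation; the gross A3 intake is not), and
equals an independent closed-form check: half the degree-of-reduction
deficit (4C + H − 2O − charge) between products and substrate. The results —
3, 2 and 1 H2 per catechin for the naringenin, eriodictyol and
dihydrokaempferol routes, 2 per phloroglucinol alone, 4 for the
hydrogenotrophic methanogenesis reference CO2 + 4 H2 → CH4 + 2 H2O — follow
from the chemistry with no tunable parameters. The 3/2/1 pattern is exactly
the count of extra dehydroxylation steps per route.

## LC-MS artifact filter

Binning uses single-linkage chaining on RT-sorted features (consecutive gap
≤ tolerance), which is order-independent and equals the transitive closure
of pairwise closeness; the default tolerance is 0.005 seconds as in the
originating procedure — unusually tight for minute-scaled exports, so the
unit is explicit config. Within a bin, Pearson correlation on raw
intensities (pairwise-complete over recorded samples; undefined correlations
from zero-variance vectors are skipped with a notice) proposes candidates at
r > 0.98, the heavier ion being the parent. A candidate is confirmed only if
its m/z appears in the parent's MS2 within 5 ppm (|Δm|/m × 1e6); a parent
without MS2 confirms nothing. Confirmed fragments are removed; parents are
never removed by their own fragment relationship; the removal log (bin, r,
ppm, parent) replaces the original procedure's manual-inspection step as the
human-review artifact. The full filter is idempotent. Halogen rejection
drops features whose predicted composition contains F, Cl, Br or I;
formula-less features are kept, unparseable formulas are kept with a
warning. Whether correlation should be computed per chromatography mode
(HILIC vs RP) is left to the caller: the filter operates per input table.

## Community statistics

Gene-level geTMM is summed per MAG (column sums conserved exactly) and per
annotation id (a gene contributes once per non-null annotation column;
unannotated genes are reported, not silently dropped). Bray-Curtis uses
BC(x, y) = 1 − 2Σmin(x_i, y_i)/(Σx + Σy); an all-zero sample pair has no
defined distance and is an error. Cross-treatment distance sets at a day
enumerate all unamended × catechin pairs (matched-replicate pairing is a
caller-side subset).

PERMANOVA is re-implemented, not wrapped: distances are Gower-centered
(G = −½ J D² J), factors enter sequentially as dummy-coded terms (type-I
sums of squares via QR-based hat matrices, the default behavior of vegan's
`adonis2(..., by="terms")`, against which it matches exactly on fixtures),
pseudo-F uses the full-model residual, and p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_perm) under free label permutation (no strata) with a seeded
generator. Null calibration (200 simulations, 199 permutations) keeps the
empirical type-I error near the nominal 0.05. Kruskal-Wallis uses the
tie-corrected H; Dunn's post-hoc uses pooled-rank z statistics with the
standard tie term and two-sided normal p values, BH-adjusted across the
pairwise family. Per-feature association modeling (MaAsLin2-style) is not
re-implemented; `kruskal_dunn_bh` applied per feature is the built-in
alternative.

## Synthetic data: what it does and does not emulate

The expression generator plants a response category per (MAG, day) by
sampling a (%both, ∆unique) target from an interior box of the category's
region — at least 7 points from both thresholds before rounding, at least 5
after, verified per MAG with an explicit failure naming the MAG — and
splitting the MAG's genes into both / unamended-only / catechin-only sets.
Counts for "on" genes are `min_count + NB(mean, dispersion)` (negative
binomial, var = μ + 0.3 μ², per-gene lognormal mean profiles around 40,
per-sample depth factors in 0.7–1.3), so planted presence survives the
low-count filter; "off" cells carry sub-threshold noise counts (1–4) at rate
0.02 to exercise it. Sampling boxes also keep each treatment's on-fraction
above ~22% so MAGs pass the 22-gene activity filter under the default
design (60 MAGs, 120–200 genes each, days 0/7/14/21/35, 2 treatments × 3
replicates). Gene lengths are uniform on 300–3000 bp. Replicate presence is
identical within a treatment×day cell unless a dropout rate is set.
Identical seeds give identical outputs.

What this shows — and does not. Perfect category recovery on these data
certifies the bookkeeping (filters, union rule, thresholds, tie precedence),
not robustness: real metatranscriptomes have correlated genes, compositional
artifacts, presence patterns that straddle thresholds, and replicate
variability in which genes are detected. The generator can approach those
regimes (dropout rate, dispersion, noise rate) but its defaults deliberately
sit in the planted-truth regime where the correct answer is unambiguous.
Similarly, the LC-MS generator plants fragments that satisfy all three
criteria with margin (co-elution within tolerance, r > 0.99, MS2 hit within
1 ppm) and independents that cleanly violate one; perfect recall/specificity
there validates the filter logic, not its behavior on borderline real
features. No read-level simulation, assembly structure or phylogenetic
signal is attempted.

## Problem sizes in the test suite

The suite runs the classifier recovery on ten seeds of the default 60-MAG ×
5-day design, the TMM oracle on 100 random 20–100-gene matrices, the
artifact filter on five seeds of the 50-parent/100-independent default, and
the PERMANOVA calibration on 200 null datasets of 12 samples × 20 features
with 199 permutations — sizes chosen so the whole suite completes in well
under a minute per stage while exercising every code path.
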