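# Methods

## The measurement problem

Whole-blood immunophenotyping of an IBM cohort asks, per donor: what
fraction of lymphocytes are CD8⁺CD57⁺ T-LGLs, what do those cells
co-express (CD5 downregulation, the NK receptors CD94/CD56/KLRG1), and
do the changes persist across visits? On top of the per-donor features
sit cohort-level analyses: a multi-criteria diagnostic rule, HLA
case-control association, ELISA seroprevalence, and nonparametric
group comparisons. `lglpheno` implements each layer behind an explicit
contract so any stage can be run on real event tables (CSV or FCS 3.1)
or on simulated ones.

## Synthetic cohort model

The generator is the package's substitute for patient data and defines
the conditions every downstream test runs under.

**Donor level.** Each donor draws a parameter set from group-specific
distributions:

- *%CD8⁺CD57⁺ of lymphocytes* — logit-normal. Location =
  logit(group median): 1.10 % (HC), 1.23 % (LOW), 9.12 % (HIGH). Scale
  is set so the distribution's 95th percentile matches the group's
  reported 95th percentile (3 %, 2.4 %, 14.8 %):
  scale = (logit(p95) − logit(median)) / 1.6449, giving 0.62 / 0.41 /
  0.33. The published full ranges are wider than any two-parameter
  logit-normal can match simultaneously with these percentiles; we
  pin the median and the 95th percentile because both enter the
  classifier (the 3 % cutoff is the HC 95th percentile).
- *CD4:CD8 ratio* — log-normal, medians 2.8 / 2.4 / 0.8.
- *Blood lymphocyte concentration* — log-normal, medians 980 / 880 /
  1240 per µL.
- *Lineage composition* — T fraction of lymphocytes (~0.58), γδ
  fraction of T (~0.05), small fixed DN/DP fractions. The CD57⁺
  fraction **within CD8⁺** is then solved so the planted %CD8⁺CD57⁺ of
  lymphocytes is internally consistent with the lineage fractions
  (clipped to [0.0005, 0.95]; the planted headline value is recomputed
  after clipping so it stays exact).
- *Marker positivity within CD57⁺ cells*, per subset (CD8/CD4/γδ) —
  logit-normal. CD8⁺CD57⁺ locations: CD5-dim 6/7/45 %, CD94 12/13/35 %,
  CD56 10/10/25 %, KLRG1 45/47/80 % for HC/LOW/HIGH. The CD4 KLRG1
  values are chosen so the derived %CD57⁺KLRG1⁺ of CD4 reproduces the
  published medians (0.24 / 0.36 / 3.08 %). Where group medians for
  individual markers are not printed (they live in supplementary
  figures), values are package calibration choices that preserve the
  published ordering: HIGH ≫ LOW ≈ HC, KLRG1 most prevalent, CD56
  least consistent.
- *Intracellular cytokines* — IFN-γ⁺ and perforin⁺ fractions per
  CD8/CD4 at the published medians (e.g. CD8 IFN-γ 19.5/47.1/57.1 %),
  with a ±0.5 log-odds shift between CD45RA⁺ and CD45RA⁻ strata
  (perforin enriched in CD45RA⁺/TEMRA, IFN-γ in CD45RA⁻). IFN-γ and
  perforin are conditionally independent given the stratum, so the
  dual-producer fraction is their product.
- *Ki67* — per CD8 CD57∓/KLRG1∓ strata; HIGH locations 4.05 %
  (CD57⁻KLRG1⁻) down to 2.18 % (CD57⁺KLRG1⁺), i.e. proliferation
  declines with differentiation.
- *Demographics* — age ~N(67.5, 9) HC vs ~N(72–73, 10) patients,
  symptom-duration log-normal (medians 8 / 11 y for LOW / HIGH),
  mobility-aid probabilities 0 / 0.38 / 0.75 split equally across
  stick/frame/wheelchair.
- *Visits* — two per donor, gap uniform on 210–960 days (bracketing
  the reported ~600-day mean); donor parameters are constant across
  visits, so persistence is planted as stable group membership.
- *HLA* — per locus, two alleles drawn i.i.d. from group-conditional
  frequency vectors taken from the published class I/II table (HC
  reuses the LOW vector); the residual mass per locus goes to a
  pattern-valid filler allele. The planted enrichment is
  C*14:02:01G (12.07 % vs 3.49 %).
- *Serology* — seropositive probability 0.382 / 0.314 / 0.01
  (HIGH/LOW/HC); negative fold changes log-normal(median 0.9, σ 0.35),
  positive log-normal(median 4, σ 0.5); ODs are reconstructed as
  blank + fold × (pool − blank) with Gaussian well noise, everything
  in duplicate; a 190-donor healthy reference cohort is generated for
  cutoff derivation.

**Event level.** Each (donor, visit, panel) sample is generated from
its own child seed, so samples are deterministic and order-independent
and the full default cohort (≈15 M events) never needs to be held in
memory. Per event: a scatter cluster (lymphocyte / debris / monocyte,
80/10/10) with Gaussian FSC/SSC; hierarchical Bernoulli lineage and
marker labels given the donor's fractions; and intensities drawn from
a two-component log-normal mixture per channel (10-fold separation
between component medians, σ = 0.35 on the log scale). CD5 is
three-state (negative / dim / bright, one decade apart) so "CD5-dim"
is a gateable interval. Count beads are a separate cluster with side
scatter far above the cell range and uniformly bright fluorescence;
their number is Poisson with mean set by the planted lymphocyte
concentration through the bead-normalisation formula, so absolute
counts are recoverable. Ground-truth labels ride along on every event
table for testing and are never consulted by the gating code.

**What the simulator does not model** — and hence what passing tests
do not show about real data: spectral spillover and compensation,
doublets, autofluorescence, manual-gate subjectivity, batch and
instrument drift, HLA linkage disequilibrium between loci, ELISA plate
effects, and any correlation structure between donor-level features
beyond what the hierarchy induces. Gate cutpoints in real data would
need the valley-finding fitter or manual placement rather than the
known mixture midpoints.

## Gating and features

Gates form an explicit tree (`GateSpec`: channel, side, cutpoint,
parent); an event is in a gate iff it is in the parent and satisfies
the predicate, so child counts can never exceed parents'. Default
cutpoints are the geometric midpoints of the intensity model; for real
data a per-channel cutpoint can be fixed, a quantile, or the
minimum-density valley between the two largest KDE modes (falling back
to a configured default, with a warning, on unimodal input).
Percentages use the stated parent population as denominator and are
flagged missing (NaN) — never 0 — when the denominator is empty;
missing-marker visits stay absent and are excluded listwise per
feature. Absolute counts use cells/µL = gated events / bead events ×
beads per µL (the bead ratio normalises acquisition volume), scaled
×10⁶ to per liter. The bead constant is configurable because the true
beads-per-µL of the product used is not published; absolute counts are
defined only up to it.

## Classification

Aberrancy cutoffs are HC mean + 2 × sample (n−1) SD per feature. The
package also records the empirical HC 95th percentile per feature as a
diagnostic: mean + 2 SD sits near the 97.7th percentile for normal
data, so the two conventions differ for skewed features and are
reported side by side rather than reconciled. All criterion
inequalities are strict. Indeterminate criteria (missing features;
persistence with a single visit) are excluded from the ≥ 3-of-4
denominator, so a single-visit donor meeting criteria 1–3 classifies
HIGH — persistence is confirmatory, not required. Persistence itself
requires the expansion (c1) and aberrancy (c3) criteria at two visits
≥ 183 days apart; whether the ratio criterion must also persist is not
specified anywhere, and we deliberately do not require it. A flag (not
a diagnosis) marks donors whose CD8⁺CD57⁺ absolute count exceeds the
classical 0.5×10⁹/L leukemia threshold.

## Serology

Duplicates are averaged (a > 20 % CV between duplicates flags the
well); fold change = (sample − blank) / (pool − blank), floored at 0;
cutoffs are the empirical 99th percentile of the healthy reference
fold changes using linear interpolation between order statistics (the
definition is recorded in the output for auditability); borderline
equality with a cutoff is negative. Cutoffs are computed on fold
changes rather than raw ODs so they are invariant to common rescaling
of the plate. The case-control association reports the sample odds
ratio, the two-sided Fisher exact p and the uncorrected Pearson
chi-square p (the two can differ noticeably at these group sizes).

## HLA association

Allele frequency is occurrences / (2 × patients typed at the locus).
Alleles at total frequency ≤ 2 % are dropped before testing; a
reporting view additionally applies the ≥ 5 %-in-either-group display
rule. The association statistic is the **carriage** odds ratio —
patients with ≥ 1 copy, homozygotes counted once — because carriage
reproduces the published ORs exactly ((7×40)/(22×3) = 4.24) where
allele-count ORs do not. Zero cells get the Haldane–Anscombe 0.5
correction for the OR only (flagged); the Fisher p is always computed
on the uncorrected table. The interval column is the upper bound of a
90 % exact conditional CI (two-sided 90 % ≙ an upper 95 % bound); the
interval method behind the published "(95th percentile)" column is
unstated, so this column is documented as our convention. Raw p values
are the headline (matching the published table); a Benjamini–Hochberg
column is emitted for reference. A locus with one group entirely
untyped yields a degenerate-flagged row rather than an error.

## Rank statistics

**Scheirer–Ray–Hare.** All N observations are ranked together with
mid-ranks for ties. Two-way ANOVA sums of squares are computed on the
ranks; each term's statistic is H = SS_term / (N(N+1)/12) divided by
the tie correction D = 1 − Σ(t³−t)/(N³−N), with a χ² reference on the
term's ANOVA df. Since SS_total of mid-ranks equals (N−1)·N(N+1)D/12,
this is exactly the classical SS_term / MS_total form with ties
handled once; with a single-level second factor it reduces to the
tie-corrected Kruskal–Wallis H. The interaction is computed only for
complete designs (every cell occupied) and skipped with a warning
otherwise; the pipeline's own usage (marker × donor group) is
complete.

**Dunn.** z_ij = (meanrank_i − meanrank_j) / √((N(N+1)/12 −
Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)), two-sided normal p, optional
Bonferroni. The post hoc offered after the rank factorial test is the
same mean-rank contrast referred to the studentized-range distribution
(k groups, ∞ df) — a rank-Tukey — because the published pairing of a
rank factorial omnibus with a "Tukey post hoc" does not name an exact
procedure; both rank-Tukey and Bonferroni are available.

Shapiro–Wilk normality p values are reported per group as diagnostics,
but the pipeline always runs the nonparametric branch — the
gatekeeping never silently switches to parametric tests.

**Paired tissue comparisons** use the exact one-tailed Wilcoxon
signed-rank test and annotate every row with the minimum attainable
p (0.5ⁿ) for its pair count, making small-n floor effects explicit: at
n = 3 no concordant result can go below p = 0.125.

**PCA** is an eigendecomposition of the feature correlation matrix
(features standardised implicitly); constant features are dropped with
a warning.

## Numerical choices and problem sizes

- All randomness flows from one integer seed through per-purpose child
  seeds; identical config + seed is byte-identical output.
- Event intensities are float32 (matching FCS storage), so FCS round
  trips are exact.
- Type-I calibration of the rank tests uses 10,000 Monte-Carlo
  replicates with 10 observations per cell (2×3 design) and 15 per
  group (Dunn) — sizes chosen so the asymptotic χ²/normal references
  apply — with acceptance bands of ±1.5 Monte-Carlo SE around α=0.05.
- The default test suite runs the full-size default cohort once
  (surface panel, both visits ≈ 14 M events, under a minute) and a
  scaled-down cohort (4,000 events/sample) for everything else.
- The end-to-end calibration check compares the measured HIGH-group
  median %CD8⁺CD57⁺ against the planted cohort median (tolerance
  0.15 percentage points — pure gating error) and against the 9.12 %
  calibration target with a tolerance of 3× the sampling SE of a
  median of 34 logit-normal donor draws (≈ 0.6 % each): the target is
  a distributional location, and a 34-donor median scatters around it
  by design, not by implementation error.

## Known limitations

- The classifier is only as good as its features; with the default
  well-separated mixtures, planted labels are recovered essentially
  perfectly, which bounds optimism about noisy real panels.
- Allele draws are i.i.d. within locus: no Hardy–Weinberg departure,
  no haplotype structure, no population stratification.
- The simulator's DRB3/4/5 loci are modelled like ordinary biallelic
  loci; real secondary DRB loci have copy-number structure.
- Muscle-tissue samples are not simulated; the paired blood/muscle
  operation is exercised on constructed tables.
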