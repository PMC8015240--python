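# Methods

## The assay and the chemotaxis index

The quadrant chemotaxis assay places ~50 young-adult *C. elegans* at the
center of an agar plate divided into two diagonally opposed test quadrants
(spotted with diluted urine or a volatile compound) and two control quadrants
(spotted with diluent). After one hour the worms in each quadrant are
counted; worms still inside a 1 cm circle at the center are treated as
immobile or anosmic and excluded. The plate's chemotaxis index is

    CI = ((T1 + T2) - (C1 + C2)) / (T1 + T2 + C1 + C2)

with +1 pure attraction, -1 pure repulsion, 0 no preference. The denominator
is the *scored* total (worms outside the center circle), not the plated
total: this is the standard convention for this assay and it is the only
denominator under which CI = 0 coincides with "no preference" and the
statistic is unbiased for the underlying preference probability. A plate on
which no worm leaves the center has an undefined CI; such plates are
excluded from aggregation and logged.

One plate is a technical replicate. Samples assayed more than six times are
capped at six by uniform random subsampling (to prevent oversampled patients
dominating), and 4–6 replicate CIs are averaged to one CI per patient, the
unit of all cohort analysis. The SEM uses the sample (n−1) standard
deviation. Each assay block also runs at least three plates with isoamyl
alcohol, a known strong attractant, as a positive control; a block passes QC
iff the mean control CI is at least 0.5 (inclusive) — a configurable
threshold, since only "consistently high" control CIs are expected, not a
published cutoff.

## Synthetic cohort generator

No cohort data are deposited, so the generator is a first-class module that
emulates the study conditions:

- **Cohort structure.** 27 negative-screen, 19 benign, 21 cancer patients;
  4–6 technical replicates per patient with 6 the mode (probabilities
  0.10/0.15/0.75 for 4/5/6, matching "at least six except three patients
  with four").
- **Plate model.** Worms migrate independently: one multinomial draw per
  plate over (center, T1, T2, C1, C2) with center probability
  `immobile_prob` (default 0.25, so ~37.5 of 50 plated worms score,
  matching the reported 34–38 scored per plate) and the rest split
  (1+a)/2 : (1−a)/2 between test and control sides, each side uniform over
  its two quadrants. E[CI | a] = a for every immobile fraction, so varying
  `immobile_prob` moves only the variance. No spatial or temporal worm
  dynamics are modeled — only endpoint counts.
- **Patient heterogeneity.** Patient attraction is the group mean mapped to
  the logit of (1+a)/2 plus Gaussian noise (sd 0.30 on that scale, ~0.15 on
  the attraction scale), mapped back; plates are conditionally independent
  given the patient. Group means default to +0.15 (cancer) and −0.05 (both
  control groups). These are calibration choices, not published values: no
  per-group mean CI is printed anywhere, so the defaults were fixed once so
  that (i) cancer is mildly attractive and controls mildly repulsive, the
  qualitative finding, and (ii) a cohort of the study's size recovers the
  group ordering (significant ANOVA, cancer above both control groups by
  Tukey HSD, benign vs negative screen null) in ≈90% of cohorts. The
  observed cohort's own F statistic was marginal (F≈4.7); matching it
  exactly would require roughly 60% more patient-level noise and would make
  the design's power property fail more than a third of the time, so the
  reliably-powered calibration was preferred and the marginal F is *not* a
  reproduction target.
- **PSA.** Log-normal per group, truncated to the 2.5–20 ng/ml inclusion
  window by inverse-CDF sampling; sigma 0.45 with pre-truncation medians
  2.9 / 4.5 / 8.0 ng/ml (negative screen / benign / cancer). Calibrated
  once so the PSA ≥ 4 rule's expected operating characteristics approximate
  the reported ones (sensitivity ≈94% vs 95%; specificity ≈52% vs 59% —
  full agreement is impossible while keeping benign PSA elevated above
  negative screens, which the cohort's Kruskal–Wallis result requires) and
  so the PSA group separation reproduces P<0.001 in ≈99% of cohorts.
- **Covariates.** Age (mean 63, sd 7, clipped to the 45–75 inclusion
  window), BMI (28 ± 4), prostate size (benign slightly larger: 48 vs
  40–42 cm³, sd 15), smoking prevalence 0.38, Gleason category (cancer
  only) low with probability 13/21. All covariates are generated
  independently of attraction, reflecting the finding that CI correlates
  with none of them. Consequently, passing covariate tests show the
  *pipeline* behaves correctly under independence; they say nothing about
  real covariate structure.
- **Dilution screen.** The preliminary screen simulator assays 4 patients
  per group at five serial dilutions with a shared patient-level deviation;
  by default the full group effect is carried only at 1:100 and attenuated
  to 10% elsewhere, emulating a dilution-dependent response with a single
  discriminating dilution.

What the generator does **not** emulate: assay-block effects (the block id
is carried through but no block term is generated or corrected — the
original analysis applied none), day-to-day drift, correlated covariates,
missing clinical values, and any VOC chemistry or dose–response. Tests that
pass on synthetic cohorts therefore validate the statistical machinery and
its calibration, not the biological claim.

## Statistical stage

All standard tests are delegated to scipy/statsmodels: Shapiro–Wilk per
group (a warn-only gate — the pipeline reports non-normality but still runs
the ANOVA, as the original analysis did after confirming normality), one-way
ANOVA with Tukey HSD post hoc run **only** after a significant ANOVA
(α=0.05), Welch t for two-group CI contrasts, Kruskal–Wallis for skewed
clinical variables (PSA, prostate size), Pearson chi-square without
continuity correction for categoricals, and pairwise-complete Pearson
correlations. The multiplicity adjustment outside Tukey is Holm — the
original analysis adjusted for multiple comparisons without naming the
method, and Holm is conservative and assumption-free. The adjustment family
for the correlation matrix is the set of off-diagonal pairs.

## Classification stage

Three fixed-threshold rules against pathology truth (positive class =
confirmed cancer; benign and negative screen both cancer-free):

- `ci_rule`: cancer iff mean CI > 0. A mean CI of exactly 0 is assigned to
  cancer-free — only CI>0 and CI<0 are defined by the rule as stated, and
  the tie-break is chosen conservatively (fewer false positives); the
  cutoff is configurable.
- `psa_rule`: cancer iff PSA ≥ 4 ng/ml (inclusive, as printed).
- `combined_rule`: logical AND of the two conditions. By construction this
  can only raise specificity and lower sensitivity relative to either
  single rule (tested as an invariant).

Metrics: sensitivity, specificity, accuracy, balanced accuracy =
(sens+spec)/2; display values are rounded half-up to integer percents, raw
proportions are kept in machine output. The no-information rate is the
majority-class prevalence — 46/67 ≈ 68.7% for the study cohort; the
published table prints 66% for this quantity without stating its
computation, and the standard definition is reported here instead. The
accuracy-vs-NIR comparison is a one-sided exact binomial test (successes =
correct calls, n = cohort size, null p = NIR). McNemar's test uses the
continuity-corrected chi-square on the discordant counts ((|b−c|−1)²/(b+c),
1 df), with an exact binomial variant available for small discordant
counts; zero discordance returns p=1 with a flag. Patients missing a
required input are excluded from that model only, with per-model n
reported.

Dilution selection maximizes the CI sign-rule accuracy over dilutions, ties
broken by the larger cancer-minus-control mean CI difference, then toward
the least-dilute option (deterministic).

## Numerical and design notes

- Every stochastic step consumes a `numpy.random.Generator` derived from
  the single run seed; identical config+seed gives byte-identical outputs.
- Simulation scale in the tests: calibration checks use 1,000 null cohorts
  drawn at patient level; recovery checks use 200 full plate-level cohorts;
  simulator-consistency checks use 5,000 plates per setting. These sizes
  put Monte-Carlo error comfortably inside the asserted bands.
- Degenerate inputs: all-center plates (undefined CI) are excluded and
  logged; a patient with only degenerate plates is dropped with a logged
  reason; empty groups, constant samples, and zero marginals raise typed
  errors before any statistic is computed.
- Known limitations: the generator's effect sizes and PSA locations are
  calibration choices (documented above), the published cohort's exact F,
  Tukey p-values and per-patient CIs are not reproducible from printed
  information, and the printed PSA-alone accuracy (71%) is mutually
  inconsistent with its printed sensitivity/specificity at the printed
  cohort sizes (20/21 and 27/46 imply 70.1%) — possibly some controls
  lacked PSA values — so it is not treated as a check.
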