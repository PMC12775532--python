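# Methods

`refcoh` analyses picture-elicited speech along three dimensions of
coherence — referential structure, conceptual-semantic similarity, and
probabilistic predictability — and ties them together statistically.
This note records the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic data do and do not
establish.

## Referential taxonomy

Noun phrases are classified from explicit morphosyntactic features by a
fixed cascade: null subject → lexical pronoun → indefinite DP
(indefinite determiner) → definite DP (demonstrative) → bare anaphoric
→ bare specific (accusative or other specificity-inducing case) → bare
indefinite (bare plural) → bare generic (annotator flag) → bare
residual. The cascade is total: every well-formed span receives exactly
one category, with bare-residual as the fallback. Specificity evidence
deliberately outranks indefiniteness evidence (anaphoric > case-marked
> plural/generic), so a span carrying several marks resolves
deterministically.

Anaphoricity is approximated by head-lemma identity against a registry
of lexical heads mentioned earlier *in the same narration*; a manual
flag can override in either direction, and the registry resets at
picture boundaries because narrations are independent one-minute
descriptions. Genericity and referential anomalies are annotator
judgments passed through as flags — anomaly detection would require
knowledge of the picture, which is out of scope by design.

Inter-rater reliability uses Cohen's κ = (p_o − p_e)/(1 − p_e) with
chance agreement from the raters' marginal label frequencies. A
cross-check against scikit-learn's implementation runs in the test
suite.

## Arrival dynamics and the memorylessness test

Occurrences of each macro-type (definite DP, indefinite DP, bare
indefinite, bare residual) are treated as a point process on the token
axis; inter-occurrence gaps are token-index differences within one
narration and never span narrations, so per-narration gap sums
telescope to last − first position. Mean distance is the arithmetic
mean gap (larger = sparser recurrence).

The scientific null is memoryless production: i.i.d. exponential gaps
with the rate matched to the data (λ̂ = 1/mean gap). Two Monte-Carlo
formulations are computed on every call:

- **two-sample fraction** — each of `n_sim` simulated Exp(λ̂) samples
  of the empirical size is compared to the data by a two-sample KS
  test (signed-ECDF merge statistic, asymptotic Kolmogorov p-value);
  the fraction with p < α is reported.
- **Lilliefors Monte Carlo** — the one-sample KS statistic of the gaps
  against Exp(λ̂), with the null distribution of the statistic
  simulated under per-replicate re-estimation of the rate. Because the
  statistic is scale-free under re-estimation, the null simulation is
  exact, and under continuous exponential gaps the test holds its
  nominal level to within Monte-Carlo error (verified at α = 0.05 with
  2,000 replicate tests of 200 gaps, 1,000 null simulations each).

`method` selects which formulation decides `rejected`; the default
`n_sim` is 100,000, with tests run at 1,000–2,000 under documented
Monte-Carlo tolerances. Samples with fewer than `min_gaps` (default 8)
gaps return an explicit insufficient-occurrences result instead of a
test, mirroring the restriction of the analysis to types with enough
occurrences.

**The token grid.** Real gaps are integers ≥ 1 (two NP heads cannot
share a token). Against a *continuous* exponential null, a pooled
group-level sample of several hundred gaps with mean distances of
10–30 tokens is large enough for the one-sample statistic to detect
the grid itself, regardless of renewal structure. The
`jitter` option therefore dequantises each gap g to g − 1 + U[0, 1)
(seeded), spreading the integer onto its underlying unit cell; a
discrete memoryless stream (geometric gaps) dequantised this way is
indistinguishable from a continuous exponential at these sample sizes.
The option is off at the function level (continuous inputs should not
be perturbed) and on in the pipeline's dynamics stage, whose inputs
are always token-grid gaps. Ties between integer gaps in the
two-sample statistic are handled by the standard ECDF merge without
correction.

Incidence rates are counts per word; exposure is the narration word
count (punctuation excluded, stop words included — stop-word removal
applies only to the similarity metric).

## Semantic metrics

For a processed narration with token embeddings e₁ … e_n, semantic
similarity is the mean cosine of consecutive pairs,
(1/(n−1)) Σ cos(eᵢ, eᵢ₊₁); it is invariant to positive rescaling of
any vector, undefined (None, not an error) below two tokens, and
zero-norm vectors are rejected rather than coerced. Pseudo-perplexity
is exp((1/n) Σ −ln P(wᵢ | context)) — the inverse geometric mean of
the token probabilities (the identity is used as a cross-check in the
tests). The logarithm is natural, fixed. Image-to-text similarity is
the mean cosine between one image embedding and per-utterance text
embeddings (whole-narration embedding is available as an option).

Preprocessing for the similarity path removes punctuation and stop
words (order preserved) so the metric tracks lexical-conceptual
content; the referential and perplexity paths always use the full
token sequence. Both with- and without-preprocessing variants are
computable as a robustness check. The default Turkish stop-word list
covers frequent closed-class items and is a configurable input.

Encoders sit behind a provider contract (token embeddings, token
probabilities, image embeddings; deterministic given input and model
id). The shipped provider is a deterministic hash-of-surface stub:
BLAKE2-keyed unit vectors and probabilities, identical across runs and
platforms. It carries no semantics — pipeline-level similarity values
under the stub are exchangeability baselines, not linguistic
measurements; real encoders plug in behind the same contract.

## Statistical models

**Poisson rate regression.** Category counts per narration are
modelled with a log link and fixed offset log(words), so group
coefficients are log rate ratios against the NC reference; fitting is
IRLS (statsmodels GLM; tolerance 1e-10, ≤ 100 iterations) and the
score equations Xᵀ(y − μ) = 0 are verified in the tests. Continuous
covariates are centered on the analysis sample. Coefficients with
|B| > 10 are flagged as quasi-separated (a group with zero instances
of a category drives its estimate to −∞) and reported as-is rather
than penalised. Model comparison uses the likelihood-ratio test and
ΔAIC for nested designs. Multiplying all exposures by c shifts only
the intercept by −ln c (tested to 1e-8).

**GEE.** Continuous outcomes observed repeatedly per participant are
fit by Gaussian-family, identity-link GEE with an exchangeable working
correlation (moment estimate from Pearson residuals, ≤ 50 iterations,
tolerance 1e-8) and robust sandwich standard errors. With all clusters
of size one, the estimates coincide with OLS (tested to 1e-8). An
outcome lying exactly in the design's column space makes the moment
estimates degenerate; that case short-circuits to the OLS solution
with zero dispersion. The deviance goodness-of-fit summary reports
RSS/dispersion with df = n − p; with the model's own dispersion this
is descriptive (per-df ≈ 1 by construction), so a known or external
`scale` can be supplied to turn it into a genuine misfit diagnostic.

**Spearman partial correlation.** All variables are rank-transformed;
ranked x and y are residualised on ranked covariates (with intercept)
and the Pearson correlation of residuals is reported with a
t-approximation on n − 2 − k df. Residuals that are numerically zero
(a variable fully explained by the covariates) return ρ = 0 rather
than amplifying floating-point noise. Cross-checked against pingouin.

**FDR.** Benjamini–Hochberg step-up q-values (statsmodels), verified
exactly against a brute-force implementation on 1,000 random vectors.
The default family is one model's non-intercept terms (the layout of a
per-outcome coefficient table); other family compositions can be built
by calling `bh_fdr` directly on any p-vector.

## Synthetic data

The generator emulates the statistical skeleton of four-group
picture-description corpora: group sizes 34/53/64/39 (NC/FEP/UHR/FHP),
four narrations per participant, negative-binomial narration word
counts (means 300/215/230/250, dispersion 10), and per-word incidence
rates per category of the order observed in picture description
(0.001–0.075). Group multipliers encode the expected direction of
effects — definite-type and anaphoric production reduced and
bare-residual production elevated in first-episode psychosis (the 0.70
definite-DP multiplier doubles as the target of the end-to-end
recovery check), lexical pronouns reduced at ultra-high risk, anomaly
flag rates elevated in all clinical groups.

Occurrence streams live on the token grid. Memoryless categories use
the defining window property of the Poisson process transplanted to
the grid: a Poisson(rate × words) occurrence count with positions
uniform over distinct word slots, so per-narration counts are exactly
Poisson (the rate models' likelihood) and dequantised gaps match a
continuous exponential. Structured categories use gamma-gap renewals
(shape 3) generated in continuous time and floored. By default
indefinite DPs are structured in every group *except* FEP, where they
are memoryless — the arrival-dynamics contrast of interest — and all
other categories are memoryless. Cross-category collisions on a token
are resolved by probing to the next free word slot, which preserves
counts exactly (the rate models' target) and displaces a small
fraction of points by one token. Spans carry exactly the features
their generating category requires, and fresh lemmas keep bare
non-anaphoric NPs out of the anaphora registry, so the classifier
recovers the generating label for ≥ 99% of spans (verified; the
remainder are first-mention anaphorics resolved by flag).

Auxiliary streams: embedding sequences are unit-sphere random walks
e_{i+1} = normalize(ρ e_i + √(1−ρ²) ε) whose consecutive cosine rises
monotonically with ρ; token probabilities have truncated-normal
negative logs so pseudo-perplexity concentrates at exp(mean NLL);
clustered outcomes realise an exchangeable correlation by splitting
the noise variance between a cluster intercept (ρσ²) and i.i.d. noise
((1−ρ)σ²).

What the synthetic data do *not* contain: real lexical or syntactic
structure (filler tokens are drawn i.i.d. from a small vocabulary),
meaningful embeddings, participant-level covariates (age, education)
or symptom scales, and participant-level rate heterogeneity beyond
group membership. Passing tests therefore establish that the pipeline
recovers known generating structure — rates, rate ratios, renewal
families, correlation parameters — not that any clinical effect holds
in real speech.

## Problem sizes and calibration checks

The test suite and the acceptance script regenerate everything at run
time. The main calibrations: level of the Lilliefors Monte-Carlo test
measured over 2,000 replicate tests (200 gaps, 1,000 null simulations,
α = 0.05) with gamma-renewal power checked at n = 50 and 200;
end-to-end recovery of the 0.70 definite-DP rate ratio over 200
simulated corpora of 50 participants per group (Wald 95% CI coverage
checked against a [0.92, 0.97] band); GEE recovery of slope 0.09 and
working correlation 0.4 from 200 clusters of 4. The acceptance script
uses 600/400/60 replicates for the corresponding quantities.

## Known limitations

- The anaphora proxy is lemma identity; real coreference (synonyms,
  bridging, pronominal chains) is out of reach of the automatic path
  and must come in through manual flags.
- The exponentiality test assumes i.i.d. gaps within the pooled unit;
  pooling across participants mixes rates and can mimic mild
  clustering. Per-participant testing is exposed for sensitivity
  checks.
- Gamma-gap renewals floored to the grid are tested against a
  continuous null; their detection is the intended behaviour, but the
  test cannot distinguish grid-free gamma structure from gamma
  structure plus grid effects.
- The one-NP-head-per-token exclusion means no grid process can have
  both exactly exponential gaps and exactly Poisson counts. The
  generator prioritises exact counts; the residual trace that distinct
  placement leaves in the gap distribution is below the detection
  threshold of the dequantised test at per-participant sample sizes
  but surfaces in a minority of corpora once several hundred gaps are
  pooled at occupancies of ~8% per word.
- The stub provider supports contract and pipeline testing only;
  substantive semantic results require a real encoder behind the
  provider contract.
- No small-sample GEE corrections and no mixed-effects Poisson models
  are provided.
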