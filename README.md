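# refcoh

Three-dimensional coherence analysis of picture-elicited speech:
**referential structure** (a noun-phrase taxonomy and the arrival
dynamics of NP types over narrative time), **conceptual-semantic
similarity** (embedding-based consecutive-cosine similarity, masked-LM
pseudo-perplexity, image-to-text similarity), and the **statistical
layer** that ties them together (Poisson rate regression with a
word-count offset, GEE for clustered outcomes, Spearman partial
correlations, Benjamini–Hochberg FDR). A synthetic-corpus generator
with the same statistical skeleton makes every stage runnable and
testable at desk scale.

The package is aimed at computational psycholinguists studying speech
markers on the psychosis spectrum — settings where narrations from
neurotypical controls (NC) are compared with first-episode psychosis
(FEP), ultra-high-risk (UHR) and family-history (FHP) groups — but the
data model is language- and study-agnostic: narrations are token
sequences with explicit morphosyntactic feature flags (JSON lines),
and all results are plain CSV.

## The core quantities

**Referential taxonomy.** Each NP span is classified by a fixed
cascade into indefinite DP, definite DP, bare anaphoric / specific /
indefinite / generic / residual, null subject, or lexical pronoun —
the categories that carve up the referential spectrum in article-less,
pro-drop languages such as Turkish (indefiniteness via *bir*,
definiteness via demonstratives, specificity via accusative
case-marking, subjects via verb agreement alone).

**Arrival dynamics.** Within a narration, occurrences of a macro-type
form a point process on the token axis. Memoryless production means
exponential inter-occurrence gaps; the package tests this with the gap
distribution matched at λ̂ = 1/mean(gap), by Monte-Carlo
Kolmogorov–Smirnov in two forms (fraction of significant two-sample
comparisons against simulated exponential samples, and a Lilliefors
one-sample statistic with a simulated null).

**Semantic metrics.** For token embeddings e₁ … e_n,

    similarity = (1/(n−1)) Σᵢ cos(eᵢ, eᵢ₊₁)
    PPPL       = exp((1/n) Σᵢ −ln P(wᵢ | context))

with punctuation and stop words removed only on the similarity path.

**Inference.** Counts per narration are modelled as
count ~ Poisson, log μ = Xβ + log(words), so group effects are log
incidence-rate ratios against NC; repeated continuous outcomes use
Gaussian GEE with an exchangeable working correlation and sandwich
errors; p-values are FDR-corrected per model family.

## Worked example

```python
import numpy as np
from refcoh import (
    GeneratorConfig, simulate_corpus, exponentiality_test, pool_gaps,
    inter_occurrence_gaps, occurrence_positions, poisson_glm_offset, build_design,
)
from refcoh.pipeline import counts_frame

cfg = GeneratorConfig(group_sizes={"NC": 20, "FEP": 20, "UHR": 20, "FHP": 20})
corpus = simulate_corpus(cfg, seed=42)

counts = counts_frame(corpus.annotations)
fit = poisson_glm_offset(
    counts["definite_dp"].to_numpy(),
    np.log(counts["word_count"].to_numpy(dtype=float)),
    build_design(counts),
)
print(fit.table().round(3))
```

```
         term      B     Se        z      p      q
0   Intercept -3.042  0.030 -100.839  0.000    NaN
1  group[FEP] -0.311  0.051   -6.111  0.000  0.000
2  group[FHP]  0.083  0.043    1.925  0.054  0.081
3  group[UHR]  0.030  0.045    0.668  0.504  0.504
```

The intercept −3.042 is the NC log rate of definite DPs per word
(e^−3.042 ≈ 0.048, the configured 0.05 baseline), and the FEP
coefficient −0.311 estimates the configured 0.70 rate ratio
(e^−0.311 ≈ 0.73, within sampling error at this corpus size);
the other groups, generated at the NC rate, stay near zero. Arrival
dynamics on the same corpus:

```python
by_group = {}
for ann in corpus.annotations:
    gaps = inter_occurrence_gaps(occurrence_positions(ann, "indefinite_dp"))
    by_group.setdefault(ann.group, []).append(gaps)
for grp in ("NC", "FEP"):
    pooled = pool_gaps(by_group[grp], group=grp, macro="indefinite_dp")
    res = exponentiality_test(pooled, n_sim=2000, seed=7, jitter=True)
    print(f"{grp}: n_gaps={res.n_gaps} mean_distance={res.mean_gap:.2f} "
          f"mc_p={res.mc_p:.4f} rejected={res.rejected}")
```

```
NC: n_gaps=1646 mean_distance=13.46 mc_p=0.0000 rejected=True
FEP: n_gaps=1193 mean_distance=13.18 mc_p=0.6330 rejected=False
```

NC indefinite DPs are generated by a structured (gamma-renewal)
process and the memorylessness null is rejected; FEP indefinite DPs
are generated memorylessly and it is not — the arrival-dynamics
contrast the pipeline is built to detect.

## Command line

```bash
refcoh run-all --out runs/demo --seed 17 --n-sim 2000
```

runs simulate → annotate → dynamics → semantics → fit → report and
writes `corpus.jsonl`, `annotations.csv`, `counts.csv`,
`dynamics.csv`, `semantics.csv`, `fit_poisson.csv`, `fit_gee.csv`,
`report_descriptives.csv` and a checksum manifest into `runs/demo`.
Individual stages are available as subcommands (`simulate`,
`annotate`, `dynamics`, `semantics`, `fit`, `report`); a generator
config YAML can be passed with `--config`.

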