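# hypbench

Homology-aware benchmarking of proline-hydroxylation (Hyp) site predictors.

Post-translational modification predictors are routinely published with
excellent self-reported accuracy and then fail on sites discovered later.
`hypbench` implements the evaluation methodology that exposes this gap for
proline hydroxylation — the PTM of collagen's (Gly-X-Y)ₙ repeats and of
scattered signalling motifs — as a reusable, fully testable pipeline. It is
aimed at method developers and assessors who need leakage-free benchmark
construction and replica-based scoring for binary site predictors.

## What it does

**Benchmark construction.** Every candidate proline is a fixed-length window
of W = 13 residues centered on the site; gaps (`-`) substitute non-canonical
residues and pad windows at sequence termini. Window pairs are scored
elementwise with BLOSUM62 plus an affine penalty for each maximal gap run
(−5 opening, −1 per extension), and scores become distances via
d(i,j) = S<sub>max</sub> − s(i,j). All sites are clustered with UPGMA
(average linkage, deterministic tie-breaking), and **negatives that fall in a
cluster containing any hydroxylated proline are removed** — they are too
similar to positives to be trusted as negatives.

**Evaluation.** Positives are split by evidence source (Literature, MS-HeLa,
MS-Kim, their union MS, and collagen subsets; MS-HeLa sites are kept only at
confidence ≥ 0.8). Each predictor is scored on 1,000 balanced replicas —
70% of a split's positives plus an equal number of pool negatives, re-drawn
per replica — with the six standard metrics

> Sn = TP/(TP+FN), Sp = TN/(TN+FP), WACC = (Sn+Sp)/2,
> PREC = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN),
> MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

reported as mean ± sample stdev over replicas, plus PR/ROC curves for
score-bearing methods. Baselines: Bernoulli(0.5) random calls, majority-vote
consensus, and a *naive profile* upper bound — one positional log-odds
profile per positive cluster, scanned with Gumbel-calibrated E-values and an
E ≤ 1.0 decision rule (its training deliberately overlaps the test set).

**Synthetic data.** A generator emulates the statistical structure of the
real problem: collagen-like proteins with prolines at 28%/45% of X/Y repeat
positions and Y-prolines hydroxylated at 85% (≈38% Y-Hyp, the canonical
collagen statistics), non-collagen proteins with motif-borne sites confined
to disorder-marked intervals, ~10% positive-proline prevalence, per-site
confidence scores, configurable annotation incompleteness, and a "novel"
motif that surfaces only in the MS sources. A simulated predictor with a
memorization weight reproduces the failure mode under study: near-perfect on
its training era, random on novel motifs.

## Worked example

```python
from hypbench.assembly import make_replicas
from hypbench.metrics import aggregate, confusion, metrics
from hypbench.pipeline import cluster_and_assemble
from hypbench.synth import (SimulatedPredictorConfig, SyntheticConfig,
                            generate_proteome, simulate_predictor)

data = generate_proteome(SyntheticConfig())          # default benchmark
clustered = cluster_and_assemble(data.proteins, data.annotations)

cfg = SimulatedPredictorConfig(training_split="Literature", seed=2026)
preds = simulate_predictor(clustered.windows, clustered.splits, data.manifest, cfg)
calls = {p.key: p.call for p in preds}
for split in ("Literature", "MS-HeLa"):
    reps = make_replicas(clustered.splits[split], n_replicas=1000, seed=6)
    agg = aggregate([metrics(confusion(calls, r)) for r in reps])
    print(split, {k: round(v["mean"], 3) for k, v in agg.items()})
```

prints (160 proteins, 2,114 candidate prolines, 1,931 clusters, 30 negatives
removed by the positive-cluster filter):

```
Literature Sn=1.000 Sp=0.984 WACC=0.992 F1=0.992 PREC=0.985 MCC=0.985
MS-HeLa    Sn=0.033 Sp=0.985 WACC=0.509 F1=0.063 PREC=0.607 MCC=0.065
```

The memorizing predictor looks essentially perfect on the split it was
trained on (MCC 0.985) and performs at chance on the novel-motif MS-HeLa
split (WACC 0.509, MCC 0.065) — the benchmark detects pure memorization that
a training-era evaluation would crown state of the art.

The same pipeline is available from the shell:

```bash
hypbench all --out runs/demo            # simulate → cluster → evaluate → characterize
hypbench evaluate --out runs/demo --split MS-HeLa --predictions my_method.tsv
```

Every run writes its fully resolved configuration (`resolved_config.yaml`)
next to its outputs; identical config + seed reproduces every artifact
byte-for-byte.

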