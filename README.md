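# nautica

Classification of transcription-factor (TF) pair interactions into
**co-operation (COOP)**, **competition (COMP)** and **non-interaction
(NINT)**, by combining three signals per candidate pair:

1. a boolean positional-interaction label from an upstream ChIP-seq
   co-binding predictor (e.g. TICA), OR-aggregated across cell-line
   contexts;
2. the presence of a direct edge between the two TFs in a protein–protein
   interaction (PPI) network (BioGRID-style, physical evidence);
3. *N₁₂*, the number of shared interactors (common neighbours) of the pair
   in the PPI network, counting TF and non-TF partners and excluding the
   pair members themselves.

Positional predictors can detect that two TFs bind the same spots but not
*why* — co-operating TFs recruit each other or bind DNA as one unit, while
competing TFs bind the same spot or partner mutually exclusively. The PPI
network disambiguates: co-operating TFs tend to share many partners (they
sit in the same complexes) and often interact directly, while competitors
and non-interactors share few.

## The decision tree

With predictor label *t*, direct edge *e* and shared-interactor count
*N₁₂*, and two fitted integer thresholds *τ_L* (default 5) and *τ_H*
(default 8):

| *t* | *e* | rule |
|-----|-----|------|
| 1 | 1 | COOP |
| 1 | 0 | COOP if *N₁₂* ≥ *τ_L*, else COMP (subclass COMP+) |
| 0 | 1 | COOP if *N₁₂* ≥ *τ_L*, else NINT |
| 0 | 0 | COMP (subclass COMP−) if *N₁₂* ≥ *τ_H*, else NINT |

Thresholds are inclusive on the high-*N₁₂* side. A network-only baseline
tree (NINT for *N₁₂* < *L*, COMP for *L* ≤ *N₁₂* < *H*, COOP otherwise;
default *L* = 1, *H* = 10) is provided for comparison. Both trees are
fitted by exhaustive grid search maximising per-class recall on a curated
training table.

Because curated test sets over-sample rare high-*N₁₂* pairs, recall is
**calibrated**: each test pair is weighted by the relative population size
of its *N₁₂* bin (eleven bins: 0–9 and a collapsed 10+ tail) in a null
distribution, with the smallest non-empty bin as weight-1 base and
`floor(count/base)` elsewhere. Precision is estimated in closed form from
an assumed NINT:COOP:COMP population split (y, x_coop, x_comp) and
per-class recalls R:

    P_INT = (x_coop·R_COOP + x_comp·R_COMP)
            / (x_coop·R_COOP + x_comp·R_COMP + y·(1 − R_NINT))

Predicted classes are additionally validated by co-complex enrichment
against a CORUM-style complex database (percentage of each class found
co-complexed, and fold-increases between classes).

## Worked example

No real BioGRID/ChIP-seq data is needed to try the package — the
`nautica.simulate` module generates a seeded synthetic world with the same
statistical structure (scale-free PPI backbone, planted class-dependent
shared-partner counts, noisy predictor labels):

```python
import nautica as n
from collections import Counter

cfg = n.SimulationConfig(seed=7, n_proteins=500, n_tfs=100,
                         attachment_edges=3, n_pairs=30)
net, tf_list = n.generate_network(cfg)
curated, predictions, truth = n.plant_pairs(cfg, net)

net, eligible = n.filter_network(net, tf_list)      # degree >= 3 eligibility
preds = n.PredictionTable(predictions.assign(predicted=predictions.predicted.astype(bool)))
cands, skip = n.assemble_candidates(net, preds, eligible)
print("candidates:", len(cands), "skipped:", skip.total())

th = n.NauticaThresholds(tau_l=5, tau_h=8)
print(dict(Counter(n.classify_nautica(c, th).label.value for c in cands)))

model = n.PrecisionModel(split=(0.8, 0.1, 0.1),
                         r_nint=0.83, r_comp=0.39, r_coop=0.75)
print("P_INT:", round(n.precision_interaction(model), 2))
print("fold over random at x=0.1:", round(n.fold_over_random(0.1), 2))
```

prints

```
candidates: 30 skipped: 0
{'COOP': 20, 'NINT': 6, 'COMP': 4}
P_INT: 0.46
fold over random at x=0.1: 2.28
```

i.e. all 30 planted pairs were classifiable (both members eligible TFs),
most are called co-operations (the planted class mix is COOP-heavy, as
literature-curated sets are), and under an 80/10/10 NINT:COOP:COMP
population assumption the closed-form interaction precision is 0.46 —
about 2.3× better than random guessing when 10% of pairs are of each
interacting class.

The same pipeline is available from the shell:

```bash
nautica run-all --seed 7 --out-dir out/
# out/: fixtures/, classifications.tsv, sensitivity_grid.tsv,
#       confusion_calibrated.tsv, metrics.json, enrichment.tsv, manifest.json
```

Subcommands `simulate`, `build-network`, `classify`, `fit`, `evaluate` and
`enrich` run the individual stages on your own files (see `--help` of
each). Exit codes: 0 success, 2 config error, 3 data-format error, 4 empty
result.

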