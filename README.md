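# ctgansurv

Survival analysis of cancer transcriptomes is chronically starved of
samples: a cohort has hundreds of patients and tens of thousands of genes,
so risk models overfit. One remedy is *style transfer* between cancer
types — learning a map that re-expresses patients of a large cohort (say
breast cancer) in the distribution of a small one (say colon cancer), and
using the transferred samples as extra training data. `ctgansurv`
implements a cycle-consistent adversarial network that jointly transfers
**gene expression and survival time** between two cohorts, together with
the full evaluation pipeline: per-gene Cox concordance gene selection,
supervised principal components (SuperPC) survival modelling,
Kaplan–Meier / log-rank risk stratification, and clustering-based
generative-model diagnostics.

## Model

Two generators G_AB : A→B and G_BA : B→A map whole feature vectors
(selected genes plus log2(survival days + 1)); two discriminators D_A, D_B
score domain membership with least-squares targets. The objective is

    L = L_GAN(G_AB, D_B, A, B) + L_GAN(G_BA, D_A, B, A) + λ_cyc L_cycle + λ_id L_identity

with

    L_GAN(G_AB, D_B, A, B) = E_b[(D_B(b) − 1)²] + E_a[D_B(G_AB(a))²]
    L_cycle = E_a‖G_BA(G_AB(a)) − a‖₁ + E_b‖G_AB(G_BA(b)) − b‖₁
    L_identity = E_b‖G_AB(b) − b‖₁ + E_a‖G_BA(a) − a‖₁

Generators are residual MLPs (2 dense+BN+ReLU blocks, 3 residual blocks,
2 more dense+BN+ReLU blocks, linear output); discriminators are 3-layer
leaky-ReLU MLPs with a scalar linear output. Training gives the generators
three updates per discriminator update and repeats the epoch schedule
three times on the same data. Generated samples carry their source
patient's event indicator; survival-time transfer can be switched off
(`expression_only` mode).

Downstream, genes are ranked by the Harrell C-index of univariate Cox
fits against the *target* cohort's survival, and the top k (default 300)
genes of the target are used for both domains. SuperPC screens genes by
univariate Cox Wald z, takes the first principal component of the
survivors, and drives a Cox model with it; augmentation quality is read
off the test-fold C-index over repeated train/test splits of the real
data (generated samples only ever join training folds).

## Worked example

```python
import numpy as np
import ctgansurv as cs

# two synthetic cohorts sharing latent structure, survival driven by
# 10 of 50 genes
cfg = cs.SyntheticConfig(n_a=400, n_b=400, n_genes=50, n_informative=10, seed=0)
dom_a, dom_b, truth = cs.simulate_pair(cfg)

genes = cs.select_top(cs.score_genes(dom_b), k=50)
ds_a, ds_b = dom_a.subset_genes(genes), dom_b.subset_genes(genes)

model = cs.CtganModel(cs.GeneratorSpec(51, hidden_width=64),
                      cs.DiscriminatorSpec(51, (128, 64, 32)), genes, seed=0)
history = cs.train(model, ds_a, ds_b, cs.TrainConfig(epochs=60, n_repeats=3, seed=0))
print(f"cycle loss {history[0].cycle:.1f} -> {history[-1].cycle:.1f}")

gen_b = cs.generate(model, ds_a, direction="AB")          # 400 B-style samples
res = cs.run_cv_benchmark(ds_b, {"ctgan": gen_b}, n_rounds=20, seed=1)
print({k: round(v, 3) for k, v in res.medians.items()})
```

Output from this exact script:

```
cycle loss 259.2 -> 29.4
{'real': 0.732, 'ctgan': 0.73}
```

The cycle loss (mean L1 reconstruction error per sample, summed over the
51 features) drops about ninefold, i.e. the round trip A→B→A returns close
to the original patients. The benchmark medians are test-fold Harrell
C-indices of SuperPC over 20 random splits of the real B cohort: training
on real B alone versus real B plus the 400 transferred A patients. On
this clean, well-sampled fixture the baseline already sits near the
information ceiling, so the two conditions tie; augmentation earns its
keep on small, noisy target cohorts (see `docs/methods.md`).

A command-line interface mirrors the library
(`ctgan simulate | preprocess | select-genes | train | transfer |
benchmark | evaluate | run`); `ctgan run --config run.yaml --out out/`
chains every stage and writes a manifest that reproduces the run.

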