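# quantiseq

Absolute quantification of the tumor immune contexture from bulk expression
data: a constrained least-squares deconvolution toolkit in the quanTIseq
style, for computational immuno-oncologists who want per-sample **cell
fractions** — not enrichment scores — for ten immune cell types plus an
uncharacterized remainder.

## The model

Each bulk sample's expression over signature genes is modeled as a
non-negative mixture of cell-type reference profiles:

    M_{g} = sum_c S_{gc} F_c          over g in G*,

where `S` is a signature matrix (signature genes x 10 cell types, median
TPM profiles), `M` is the TPM-normalized mixture column, and `G*` the
signature genes present in the mixture. Fractions are estimated per sample
by constrained least squares,

    minimize ||S F - M||^2   subject to   F_c >= 0,  sum_c F_c <= 1,

so the slack `F_other = 1 - sum_c F''_c` measures uncharacterized (e.g.
malignant) cells. Two corrections follow the regression:

* **Treg/CD4 collinearity heuristic** — when the raw regulatory-T-cell
  fraction falls below 0.02, the system is re-solved without the
  non-regulatory CD4 column; the final Treg fraction is the mean of the
  two fits and CD4 is reduced accordingly (floored at zero).
* **mRNA-content scaling** — `F'_c = F_c / n_c`, then
  `F''_c = F'_c * f / f'` with `f = sum F_c`, `f' = sum F'_c`, converting
  mRNA fractions into cell fractions using per-type mRNA abundance proxies
  `n_c` (median housekeeping-gene expression per cell type).

With per-sample total cell densities from imaging, fractions scale to
cells/mm². The package also implements the full signature-construction
pipeline (quantized cell-specific selection, tumor-expression, gene-set
specificity, expression-range, fraction-correlation and
restricted-expression filters, plus curated blacklists), an in-silico
mixture simulator with tumor-purity and sequencing-depth grids, leave-K-out
benchmarking, and deconvolution-based prognostic scores (immunoscore, TB
score).

## Worked example

```python
import numpy as np
import pandas as pd
import quantiseq as q

bundle = q.make_fixtures(seed=0)                     # synthetic inputs
S = q.apply_gene_blacklists(bundle.signature, "default")

rng = np.random.default_rng(11)
draw = rng.dirichlet(np.ones(10))
draw[8] = max(draw[8], 0.15)                         # keep Tregs estimable
f_true = pd.Series(draw / draw.sum() * 0.4, index=S.cell_types)
mixture = pd.DataFrame({"s1": S.values.to_numpy() @ f_true}, index=S.gene_ids)

model = q.DeconvolutionModel(mixture, bundle.signature,
                             mrna_scale=False, prepare=False)
results = model.fit()
print(results.summary())
```

prints

```
Constrained least-squares deconvolution
=======================================================
samples: 1    cell types: 10
signature genes used: 153 (100% of signature)
mRNA-content scaling: off

mean fractions across samples:
  B.cells              0.0117
  Macrophages.M1       0.0274
  Macrophages.M2       0.0570
  Monocytes            0.0023
  Neutrophils          0.0059
  NK.cells             0.1926
  T.cells.CD4          0.0036
  T.cells.CD8          0.0096
  Tregs                0.0541
  Dendritic.cells      0.0358
  Other                0.6000
```

The ten immune fractions sum to 0.40 — the immune content planted in the
mixture — and `Other` reports the remaining 0.60 of uncharacterized
(here: simulated tumor) content. `results.summary()`,
`results.residuals()`, `results.scale_to_densities(...)` and
`results.plot_fractions()` hang off the results object.

The same pipeline is scriptable from the shell:

```bash
quantiseq make-fixtures --seed 0 --out fixtures/
quantiseq simulate --n 10 --purities 0:0.2:0.8 --depths 1e6 --out sim/
quantiseq build-signature --out sig.tsv
quantiseq deconvolute --mix sim/mixtures.tsv --sig sig.tsv \
    --mrna-scale FALSE --out fractions.tsv
quantiseq score --fractions fractions.tsv --score immunoscore --out scores.tsv
```

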