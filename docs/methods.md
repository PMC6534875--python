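# Methods

## Deconvolution model

A bulk sample's expression over the signature genes present in the mixture
(`G*`) is modeled as a non-negative linear mixture of cell-type reference
profiles, `M = S F`, with `F_c >= 0` and `sum_c F_c <= 1`. Both sides are
on a linear TPM scale: TPM is a within-sample relative abundance, so the
coefficients `F_c` are mRNA fractions of the ten immune cell types, and
the slack of the sum constraint is the mRNA share of cells not represented
in the signature ("Other": malignant, stromal, endothelial, ...). The
Other fraction is deliberately not rescaled, because the mRNA content of
that heterogeneous population is unknown.

The fit assumes: (i) expression adds linearly across cells on the natural
scale; (ii) the signature profiles match the infiltrating cells'
transcriptional states reasonably well (profiles derive from blood cells,
a known limitation in tissue); (iii) signature genes are not expressed by
the uncharacterized cells — the tumor-gene blacklist and the tumor filter
in signature construction exist to enforce this.

### Solver

The constrained problem is a small convex QP (10 unknowns). We solve the
non-negativity-only problem with Lawson–Hanson NNLS (scipy); when its
solution already satisfies `sum F <= 1` the sum constraint is inactive and
the solution is optimal as-is. Otherwise the optimum lies on the
`sum F = 1` face and is found exactly by enumerating the faces of the
simplex (subsets of coordinates clamped to zero) and solving each
equality-constrained KKT system; the best feasible candidate is the global
optimum of the convex program. Exact, deterministic, no random
initialization; the test suite checks it against an independent
brute-force KKT enumeration on 200 random instances (objective gap
<= 1e-6). Face enumeration costs 2^C KKT solves and is only practical for
the C <= ~12 cell types this tool targets.

### Treg/CD4 heuristic

Regulatory and non-regulatory CD4 T-cell profiles are nearly collinear,
which drives low-abundance Treg estimates to zero. When the raw Treg
fraction is below 0.02, the system is re-solved without the CD4 column;
the final Treg fraction is the mean of the two fits and the CD4 fraction
is reduced by it (floored at zero). The adjusted immune fractions are then
rescaled so their total matches the pre-adjustment total: rescaling to an
absolute sum of 1 would contradict the `sum F <= 1` semantics and destroy
the Other fraction, so preserving the immune total is the consistent
reading. The heuristic operates on raw regression fractions, before mRNA
scaling, since it corrects a regression artifact. Tested contract: it
triggers exactly below 0.02 and reproduces the mean/max formulas.

### mRNA scaling

`F'_c = F_c / n_c`, `F''_c = F'_c * f / f'` with `f = sum F_c`,
`f' = sum F'_c`. This converts mRNA fractions to cell fractions while
preserving the total immune fraction. The scaling factors `n_c` proxy
per-cell-type mRNA content by the median expression of the PSMB2
housekeeping gene across each type's libraries. Their default values are
derived deterministically from the bundled synthetic compendium
(normalized to median 1); they are a configuration table
(`ScalingFactors`), and analyses of real data should supply factors
derived from a real compendium. Scaling is disabled for simulated
benchmarks, whose ground truth is mRNA fractions by construction.

## Signature construction

Candidate markers come from a labeled compendium of purified-cell
libraries (TPM, genes detected in >= 2 immune libraries). Expression is
quantized per gene into low/medium/high by exhaustive two-threshold search
minimizing within-bin variance of log2(x+1); ties share a bin, constant
genes are all-low, and bins are monotone in expression. A gene is a
candidate for type c iff it is high in every library of c and low/medium
in every other library — which makes marker ownership unique by
construction. Candidates then pass through:

* **tumor expression** — dropped if median log2 expression exceeds 7 in
  all provided cancer cell lines, or if mean bulk-tumor expression is
  below 1 TPM (both thresholds from the reference method; summaries are
  injected as plain tables);
* **gene-set specificity** — dropped if listed in a gene set tagged for a
  different cell type; CD4 sets are not used against Treg candidates
  (FOXP3-like markers legitimately appear in CD4 population sets);
* **range** — dropped if any library exceeds 700 TPM (high-expression
  genes dominate the least-squares objective);
* **correlation with true fractions** — dropped unless Pearson r >= 0.6
  with the owner type's fraction across simulated mixtures (inclusive
  threshold);
* **restricted expression** — per external dataset d, the ratio R_gd of
  in-type to out-of-type median expression; the top 30 genes per type by
  median_d(R_gd), among those with median >= 2, survive (ties broken by
  gene symbol; zero denominators treated as +infinity). Treg candidates
  exclude CD4 libraries from the out-group and face an extra Treg-vs-CD4
  pass at threshold 1.

Profiles are per-type medians over libraries. Filters not supplied with
side data are skipped — the leave-K-out benchmark varies only the
compendium, so its rebuilds use the compendium-intrinsic filters
(detection, cell-specific selection, range).

Two curated blacklists shrink a signature after construction: a 17-gene
variable-expression list applied by default for RNA-seq (`rmgenes`), and a
17-gene tumor-associated list applied in tumor mode. For microarray input
the full matrix is kept by default, since arrays often lack signature
genes. Conditioning is summarized by the ratio of extreme singular values
of the linear-scale matrix (the scale deconvolution operates on); on both
the synthetic stand-in and the published signature, removing the
variable-expression genes lowers the condition number.

The published 170-gene signature is distributed as a supplementary
spreadsheet of the reference method and is not bundled here; the package
ships a **synthetic** 170-gene stand-in (138 synthetic markers plus both
blacklists' genes) whose blacklisted rows are planted with near-uniform,
variable expression across types — the documented reason those genes were
curated out — so the bookkeeping (170 -> 153) and the conditioning
ordering are exercised end to end. Its condition numbers are properties of
the stand-in, not of the published matrix.

## Simulator

Mixtures are composed at the expression level: the expected profile is the
fraction-weighted sum of per-type median TPM profiles (renormalized to
10^6) plus a tumor profile; finite sequencing depth is emulated by
multinomial resampling of gene counts at the target number of read pairs,
then conversion back to TPM. This preserves the depth-noise structure of
read-level mixing without FASTQ machinery; per-gene deviations scale as
sqrt(TPM * 10^6 / depth), so convergence to the exact linear mixture is
tested on that standard-error scale rather than with a fixed TPM bound.

Immune fractions are drawn uniform on [0,1] and renormalized to sum to
1 - purity (fractions must form a composition); the tumor fraction equals
the purity. The reference design crosses 100 mixtures with 11 purities
(0:10:100%) at 10^6 read pairs, plus depths {1,2,5,10,20,50,100} x 10^6 at
the 60%-purity anchor, base depth counted once: 1700 datasets. One RNG
stream per mixture index is spawned from the design seed, so a mixture
keeps its composition across purities and depths and generation is
bit-reproducible.

## Synthetic study conditions

The bundled generator plants: 13 markers per type at 60–250 TPM in the
owner type with type-varying low-level leakage (log-normal around 0.3
TPM); decoy genes that look cell-specific but must be caught by each
filter; PSMB2 with per-type levels reflecting mRNA content (granulocytes
low, myeloid cells high); tumor-only markers; and a background
transcriptome carrying the remaining TPM mass. Between-library variability
is log-normal (sigma 0.15, ~15% CV), and each type has 4 libraries — close
to the reference compendium's average of ~5 — so that leave-one-out
rebuilds retain 3 libraries per type.

What passing these benchmarks shows: the selection filters, solver,
corrections and bookkeeping behave as specified under realistic noise and
depth. What they do not show: performance on real tissue, where profile
mismatch (blood-derived signatures vs tumor-infiltrating states),
platform effects, and expression of signature genes by malignant cells
dominate the error budget — none of which the generator emulates.

## Numerical choices and degenerate inputs

* TPM columns sum to 10^6 within 1e-3 relative; renormalization is
  idempotent and rejects all-zero samples by name.
* Microarray matrices with maximum below 50 are treated as log2 (linear
  intensities always exceed this); quantile normalization maps each
  sample's order statistics onto the mean sorted profile, averaging ties,
  which preserves within-sample rank order.
* Duplicate gene symbols collapse by per-sample median (midpoint for even
  counts); probe collapse keeps the probe with the highest mean.
* Fewer than max(10, C) shared signature genes is an error; below 80%
  coverage a warning.
* Zero mixtures give zero fractions; `F_other` is clipped at 0 against
  roundoff; all-zero fraction vectors skip the mRNA-scaling division.
* Per-sample failures in multi-sample runs are collected and reported;
  remaining samples are processed.

## Benchmarks computed by scripts/acceptance.py

Design enumeration (1700), signature bookkeeping (170/153) and condition
numbers on the stand-in, solver-vs-oracle worst objective gap (200
instances), noiseless regression recovery (100 mixtures), full-chain
marker-selection precision against planted truth, leave-K-out per-type and
overall Pearson r and RMSE (60 mixtures, 10^6 read pairs, 60% purity), and
tumor-content RMSE (30 mixtures). Problem sizes are chosen so the script
completes in about a minute on one CPU while keeping Monte-Carlo noise
well inside the tested margins.

## Known limitations

* The published signature matrix and its condition numbers are not
  reproducible offline; the stand-in covers the logic, not the artifact.
* mRNA scaling factor defaults are synthetic-compendium-derived proxies.
* The heuristic's rescaling convention ("sum to 1" in the reference
  description) is interpreted as preserving the immune total; alternative
  readings would change fractions for triggered samples by a constant
  factor.
* Scores (immunoscore, TB score) implement the dichotomization only;
  survival modeling belongs to standard survival packages.
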