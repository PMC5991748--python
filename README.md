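# mirmod

Network-module biomarker discovery for miRNA expression cohorts.

Single-marker screens ignore the co-regulatory structure of miRNAs. `mirmod`
implements the module-level alternative: detect co-expression modules in a
disease cohort, verify which modules are technically reproducible, find the
modules whose wiring is *disrupted* relative to healthy controls (the
"activated" candidate biomarkers), rank hub miRNAs with a network-constrained
classifier, and quantify the diagnostic value of module-level expression
scores.

## The method

Given a disease cohort, a technical replicate of the same samples, and a
normal cohort (features × samples, normalized log intensities):

1. **Co-expression network + modules (WGCNA-style).** Pearson correlations,
   unsigned soft-threshold adjacency `a_ij = |cor(x_i, x_j)|^β` with β chosen
   by the scale-free topology criterion (smallest power with fit R² ≥ 0.8),
   the topological overlap measure

   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   and average-linkage clustering on `1 − TOM` with a dynamic branch cut
   (minimum module size 3).
2. **Module consensus (MCR).** Partitions of two cohorts are cross-tabulated;
   each module pair gets a one-sided Fisher/hypergeometric overlap p-value,
   and `MCR = NM_overlap / (NM_a · NM_b) × 100%` summarizes how consistent
   the module structure is across cohorts.
3. **Preservation / activation (Z_summary).** Each reference module is scored
   in a test cohort by 4 density statistics (meanCor, meanAdj, propVarExpl,
   meanKME) and 3 connectivity statistics (cor.kIM, cor.kME, cor.cor), each
   standardized against permuted pseudo-modules of the same size:

   `Z_summary = [ median(Z_density components) + median(Z_connectivity components) ] / 2`.

   `Z_summary ≥ 10` means strong preservation, `≥ 2` preservation, `< 0`
   disruption. A module disrupted versus normal controls but reproducible
   versus the technical replicate is an **activated module** — the candidate
   disease biomarker.
4. **Hub ranking (network-constrained SVM).** A linear SVM separating disease
   from normal samples with objective
   `mean hinge + λ_margin‖w‖² + λ_net wᵀLw`, where `L` is the normalized
   Laplacian of the thresholded TOM network; large |w| marks hub miRNAs and
   the induced subgraph of the top-ranked miRNAs is the biomarker
   sub-network.
5. **Diagnostics.** Module biomarkers are scored per sample by the
   (SVM-weighted) mean member expression; ROC/AUC (concordance estimator,
   ties ½) and the Youden-optimal cutoff (max Se + Sp − 1) quantify
   diagnostic performance, including an exhaustive member-subset search.
6. **Annotation.** Module targets are the three-way intersection of local
   target-prediction exports; target sets get hypergeometric term enrichment
   with Benjamini–Hochberg adjustment.

A synthetic three-cohort generator (one-factor Gaussian block modules with
known disrupted modules and differentially expressed features) provides
ground truth for every stage.

## Worked example

```python
import numpy as np, pandas as pd
from mirmod import (generate_cohorts, CoexpressionNetwork,
                    ModulePreservation, classify_modules)
from mirmod.simulate import default_design

design = default_design(seed=1)            # 300 miRNAs, 10 modules, 90/90/34
ref, rep, norm, truth = generate_cohorts(design)

net = CoexpressionNetwork.from_expression(ref)
part = net.detect_modules(min_module_size=3)
print(net.network.beta, len(part.module_labels))   # 14.0 10

res_rep = ModulePreservation(ref, rep, part, beta=net.network.beta).fit(
    n_perm=100, seed=11)
res_norm = ModulePreservation(ref, norm, part, beta=net.network.beta).fit(
    n_perm=100, seed=11)
table, biomarkers = classify_modules(res_rep.z_summary, res_norm.z_summary)
print(biomarkers)                                  # [8, 9, 10]
```

The three modules reported as activated biomarkers (Z_summary < 0 versus the
normal cohort, ≥ 0 versus the replicate) are exactly the three whose
co-expression the generator disrupted in the normal cohort.  Their weighted
module score separates disease from normal samples with AUC ≈ 0.99, and the
cross-validated network-SVM reaches sensitivity/specificity ≈ 0.94/0.82 on
the same cohorts.

The full pipeline also runs from a config file:

```bash
mirmod run-all configs/synthetic.yaml     # or: mirmod simulate / coexpr / ...
```

Each stage writes plain CSV/JSON/SIF/GraphML artifacts under stable names,
and the run manifest records a content hash per output, so re-running a
config reproduces identical hashes.

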