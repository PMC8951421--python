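# tadfunc

Do protein-coding genes that share a topologically associating domain
(TAD), a gap region between TADs, or a spatially proximate pair of
genomic regions also share biological functions?  `tadfunc` is a
library-plus-CLI that answers this question end to end:

* **Domain model** — TADs and the derived *gap regions* of a chromosome,
  with genes assigned to the single domain that entirely contains their
  body (boundary-straddling genes are excluded).
* **Functional similarity** — GO annotations filtered to experimental
  evidence codes (EXP, IDA, IPI, IMP, IGI, IEP) with namespace roots
  removed; gene pairs scored by a Wang-style hybrid semantic similarity
  with best-match-average (BMA) aggregation, in [0, 1].
* **Pair statistics** — intra- vs inter-domain gene pairs (duplicates
  removed by a >90 % identity & e-value < 0.01 filter, sets rebalanced
  to equal size), compared by the two-sided Wilcoxon rank-sum test;
  expression similarity GESS = 1 − |log₂(EC_A+1) − log₂(EC_B+1)| /
  (log₂(max+1) − log₂(min+1)), correlated with functional similarity.
* **Network communities** — functional similarity networks (edge iff
  similarity ≥ threshold), Girvan–Newman divisive communities, and the
  *same-TAD-belonging ratio* (distinct TADs / community size) against
  size-matched random communities.
* **Spatial networks and link prediction** — Hi-C contacts aggregated to
  gene pairs; HiC-GGSI networks (contacts ≥ t₁ and genomic distance ≥
  t₂) and HiC-TAD-GGSI networks (plus same-TAD edges); a linear graph
  autoencoder (encoder Z = ÃW with Ã = D^{−1/2}AD^{−1/2}, decoder
  Â = σ(ZZᵀ)) trained on 7:2:1 edge splits and scored by AUC/AP with
  t-based confidence intervals over repeated splits.
* **Function inference** — neighbour-voting on reconstructed networks
  (edges with confidence > 0.6): a candidate GO term's score is its
  occurrence count among radius-one neighbours, evaluated by the best
  semantic similarity of the top-1/top-4 predictions to the true terms.
* **Long-range regions** — 40 kbp bin pairs with normalised contacts
  ≥ 10 (strong) or in (0, 0.2] (weak) beyond a distance threshold;
  gene groups overlapping each bin compared by a symmetric
  average-of-best similarity, reported when ≥ 0.5.

Real mouse/human data are not required: a first-class synthetic-data
module generates every input (BED, OBO, GAF, contact triples, TSV
tables) with planted within-TAD functional modules, distance-decay Hi-C
structure with TAD enrichment and long-range loops, module-correlated
expression, and planted duplicate pairs — so every stage's finding is
recoverable from scratch on a desk-scale chromosome.

## Worked example

```python
import numpy as np
from tadfunc import simulate, compare_distributions
from tadfunc.pipeline import RunConfig, intra_inter_scores, build_networks
from tadfunc.graph_autoencoder import run_repeats

data = simulate(seed=0)          # 10-TAD synthetic chromosome, ~300 genes
cfg = RunConfig()

intra, inter = intra_inter_scores(data, cfg, "tad")
p, tier = compare_distributions(intra, inter)
print(f"intra-TAD mean similarity {np.mean(intra):.3f}  "
      f"inter-TAD mean {np.mean(inter):.3f}  Wilcoxon p {p:.2e} ({tier})")

_table, ggsi, tad_ggsi = build_networks(data, cfg)
for name, net in (("HiC-GGSI", ggsi), ("HiC-TAD-GGSI", tad_ggsi)):
    df, auc, ap = run_repeats(net.graph, n_repeats=10, seed=0)
    print(f"{name:13s} test AUC {auc.mean:.3f} ± {auc.half_width:.3f}  "
          f"AP {ap.mean:.3f} ± {ap.half_width:.3f}")
```

prints

```
intra-TAD mean similarity 0.431  inter-TAD mean 0.182  Wilcoxon p 1.33e-63 (***)
HiC-GGSI      test AUC 0.896 ± 0.010  AP 0.867 ± 0.019
HiC-TAD-GGSI  test AUC 0.962 ± 0.004  AP 0.949 ± 0.008
```

Genes sharing a TAD are far more functionally similar than matched
inter-TAD pairs, and adding same-TAD edges to the Hi-C gene network
makes its topology markedly easier for the autoencoder to reconstruct —
the package's two central observations on the positive-control data.

The same stages are scriptable from the shell (`tadfunc simulate`,
`tadfunc domains`, `tadfunc gosim`, `tadfunc pairs`, `tadfunc fsn`,
`tadfunc ggsi`, `tadfunc gae`, `tadfunc longrange`), and
`tadfunc run --out DIR` executes everything end to end from one master
seed, writing per-stage TSVs and a JSON summary.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generative
process, the numerical choices and the known limitations.
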