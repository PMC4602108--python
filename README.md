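# floranet

Candidate-gene discovery for floral organ morphogenesis by integrating four
classic systems-biology layers: weighted gene co-expression modules,
sequence-based protein–protein interaction (PPI) prediction, Gene Ontology
over-representation, and alignment-free phylogenetics. A synthetic-data
module plants known structure into every input, so the whole pipeline is
testable offline against ground truth.

## The problem and the method

Flower development in *Arabidopsis thaliana* is driven by interacting
regulator complexes (the ABCDE / floral-quartet picture), yet most genes
co-expressed with the known regulators have no assigned role. The strategy
implemented here proposes new participants by requiring several independent
lines of evidence to agree:

1. **Co-expression modules (WGCNA-style).** From an expression matrix
   `x_i` over `m` samples with a binary floral/non-floral trait `T`, build
   the unsigned weighted network `a_ij = |cor(x_i, x_j)|^β`, choosing the
   soft power β as the smallest integer in 1..40 whose connectivity
   distribution fits a scale-free law with signed `R² ≥ 0.6`. Convert to
   topological overlap (TOM), cluster `1 − TOM` by average linkage, and cut
   at a fixed height; clusters under 30 genes fall into the grey module.
   Per gene, compute the trait significance `GS_i = |cor(x_i, T)|` and the
   module membership `kME_i(q) = cor(x_i, E(q))`, where `E(q)` is the
   module eigengene (first principal component of the module submatrix).
2. **PPI prediction.** Curate experimentally validated pairs (drop
   proteins < 50 residues or with unknown residues; optionally remove
   pairs redundant at ≥ 40 % sequence identity), build a balanced negative
   set from protein pairs with disjoint subcellular localizations, encode
   each protein by lag-1..30 auto-covariances of seven z-scored
   physicochemical property series, and train an RBF SVM at
   `c = 5.278, γ = 0.574`. Candidate partners of the seed genes must pass
   the module co-expression threshold
   `α = (w_max − w_min)·0.6 + w_mean`, be predicted to interact, and share
   a subcellular compartment.
3. **Enrichment.** Per module, upper-tail hypergeometric tests of term
   over-representation, Bonferroni-corrected, flagged at corrected
   `P < 0.005`; tested terms are linked at Cohen's `κ ≥ 0.3` and merged
   into functional groups.
4. **Phylogenetics.** Composition vectors: K-tuple frequencies (K = 6)
   with the Markov background `a₀(s₁..s_k) = f(s₁..s_{k−1}) f(s₂..s_k) /
   f(s₂..s_{k−1})` subtracted as `(f − a₀)/a₀`; distances
   `D = (1 − cosine)/2`; neighbor-joining trees relate candidates to the
   known (seed) genes.

The pipeline's report ranks candidate genes by
(module significance, kME, SVM score).

## Worked example

```python
from floranet.config import PipelineConfig
from floranet.pipeline import run_all

result = run_all(PipelineConfig(seed=1), "out/")
rep = result.report
print("beta:", rep["parameters"]["beta"])
print("modules:", rep["coexpression"]["modules"])
print("held-out AUROC:", round(rep["ppi"]["holdout_auroc"], 3))
for c in rep["candidates"][:3]:
    print(c["gene"], round(c["kME"], 3), c["predicted_partners"], c["nearest_seed"])
```

prints

```
beta: 6
modules: {'turquoise': 50, 'blue': 40, 'brown': 30}
held-out AUROC: 1.0
G0011 0.965 ['G0022'] G0012
G0003 0.962 ['G0013'] G0013
G0041 0.961 ['G0042'] G0042
```

The synthetic study plants three co-expressed modules (50/40/30 genes plus
80 noise genes over 60 samples, the first module trait-linked at 0.9); the
run recovers them exactly as the turquoise/blue/brown modules, with the
trait module on top (module significance 0.859 vs 0.175/0.083). The
interaction classifier, trained on 300 synthetic pairs and evaluated on
held-out proteins, separates planted interaction families from
non-interacting pairs (AUROC 1.0). Each reported candidate (e.g. `G0011`)
is a module gene that passed the co-expression threshold (α = 0.679 here),
was predicted by the SVM to interact with a seed gene, shares that seed's
compartment, and sits next to a seed in the composition-vector tree — in
this run all six predicted edges are planted ground-truth interactions.

The same stages are scriptable from the shell:

```bash
floranet simulate --seed 1 --outdir data/
floranet coexpress --expression data/expression.tsv --trait data/trait.tsv --outdir out/
floranet run-all --seed 1 --outdir out/
floranet report --report out/report.json
```

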