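# netlogit

Network-based prioritization of human disease genes with a binary logistic
regression fitted over the whole gene universe.

## The problem and the method

Genes whose disruption causes similar genetic diseases tend to lie close to
each other in biological networks — protein–protein interaction maps,
pathway co-membership graphs, co-expression networks.  `netlogit` exploits
this to rank every *unknown* gene (no recorded disease association) as a
candidate for a given disease class `d_k`, integrating one or several
networks in a single fast model:

1. **Priors.** Every gene gets a prior probability of carrying label 1
   (= associated with `d_k`).  Known genes are fixed: 1 if associated with
   `d_k`, 0 if known only for other diseases.  Unknown genes get either the
   zero prior (`P0`) or a protein-complex prior (`Pc`): for a gene in a
   complex, `p̂ = max A/B` over its complexes, where `A` counts the
   complex's known `d_k` genes and `B` its known disease genes of any
   disease; a gene in no informative complex falls back to the genome-wide
   base rate `C/D`.
2. **Prior configuration.** A binary label vector `x̂` is sampled,
   per gene, as Bernoulli(`p̂`).
3. **Features.** Each gene's feature vector counts its network neighbors by
   label: `F1` = (1, φ₁, φ₀) on one network; `F2` adds the same counts over
   the distance-exactly-2 neighborhood; `F3` concatenates direct counts
   across `l` networks, giving `2l + 1` columns.
4. **Model.** The posterior `p(xᵢ = 1 | φᵢ) = exp(wᵀφᵢ)/(1 + exp(wᵀφᵢ))`
   with `w` maximizing the log-likelihood
   `ln L(w) = Σᵢ [xᵢ wᵀφᵢ − ln(1 + exp(wᵀφᵢ))]`
   over **all** N genes (known + unknown), from `w = 0`.  The negated
   likelihood is convex, so the optimum is unique off separation.
5. **Decision scores.** Posteriors of the n unknown genes become
   self-inclusive percentiles `qᵢ = |{j : pᵢ ≥ pⱼ}| / n ∈ (0, 1]`.
6. **Evaluation.** Leave-one-out cross-validation: each known gene of
   `d_k` (and `⌊s/2⌋` negative controls drawn from known genes of other
   classes) is demoted to unknown, the whole algorithm re-runs, and the
   held-out gene's decision score feeds a pooled ROC with Mann–Whitney AUC.

Real curated inputs (OMIM, HPRD, KEGG, …) are deliberately out of scope;
a synthetic benchmark generator plants disease modules in stochastic block
model networks, module-aligned complexes/pathways and block-correlated
expression, so everything is testable offline.

## Worked example

```python
import netlogit as nl

bench = nl.generate_benchmark(nl.BenchmarkSpec(seed=1))   # 2,000 genes, 12 classes
dataset = nl.Dataset.assemble(
    bench.universe, bench.networks, bench.disease_map, bench.complexes
)

# Rank candidates for one disease class with integrated networks + complex prior
scores = nl.run_disease(dataset, "C01", nl.RunConfig(feature_mode="F3",
                                                     prior_strategy="Pc", seed=1))
top = sorted(scores.records(), key=lambda r: r[3])[:3]
for gene, posterior, q, rank in top:
    print(f"{rank:>2}  {gene}  posterior={posterior:.3f}  q={q:.4f}")

# Leave-one-out evaluation pooled over all 12 classes
result = nl.evaluate_all(dataset, nl.RunConfig(feature_mode="F3",
                                               prior_strategy="Pc", seed=1))
print(f"pooled AUC = {result.auc:.3f} over {result.n_experiments} experiments")
```

prints

```
 1  G0025  posterior=0.992  q=1.0000
 2  G0066  posterior=0.968  q=0.9993
 3  G0026  posterior=0.963  q=0.9987
pooled AUC = 0.997 over 720 experiments
```

The three top-ranked genes are unknown genes from the module in which class
`C01`'s known genes were planted — exactly the candidates the method should
recover — and the pooled AUC says that held-out disease genes rank far
above the negative controls.  The same pipeline is available from the shell
via `netlogit simulate | rank | evaluate | build-net`.

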