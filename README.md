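# gravgrn

Supervised inference of **directed** gene regulatory networks (GRNs) from
single-cell expression data and a partial prior network.

Most graph-neural link predictors treat a GRN as an undirected graph: an
inner-product or distance decoder scores the pair {i, j}, not the ordered
edge i → j. But regulation is directional — a transcription factor (TF)
drives its targets, not the other way around. `gravgrn` addresses this with
three pieces:

1. **Gravity-inspired graph autoencoder (GIGAE).** A two-layer graph
   convolution on the out-degree-normalized adjacency
   Ã = D_out⁻¹(A + I) encodes each gene as a latent vector zᵢ ∈ ℝᵈ plus a
   scalar *mass* m̃ᵢ. The decoder scores a directed edge by a log-transformed
   Newtonian acceleration of i toward j:

   ```
   Â[i,j] = σ( m̃′ⱼ − log ‖zᵢ − zⱼ‖² )
   ```

   The target's mass carries all the directionality: genes with high mass
   attract incoming edges, and Â[i,j] ≠ Â[j,i] whenever masses differ.
   Freezing all masses to a constant recovers a symmetric (undirected)
   autoencoder — the GAE ablation baseline.

2. **Gene-importance fusion (WF).** An out-degree-oriented PageRank variant
   scores regulator importance on the prior network via the damped iteration
   v′ = β M* v + (1 − β) e / n (β = 0.85), where M* spreads each gene's score
   over the genes it interacts with. Scores are fused into both the input
   features, X = α·PBM + (1 − α)·T (α = 0.1, T the expression matrix, PBM the
   scores broadcast over cells), and the decoder masses,
   m̃′ = α·PageRank*(G) + (1 − α)·m̃.

3. **Random-walk regularization (RWR).** node2vec walks over the training
   network (length 9, window 3, 5 walks/gene) feed a negative-sampling
   Skip-Gram loss on the fused embeddings Z′ = [Z | m̃′]; its gradient flows
   back into the encoder, evening out the latent distribution of
   structurally similar genes.

Training minimizes weighted binary cross-entropy between Â and the training
adjacency (plus the Skip-Gram term) with Adam (lr 0.001, 100 epochs),
keeping the best-validation-AUROC checkpoint. Known edges are split 85/5/10
into train/validation/test positives with balanced sampled negatives, and
held-out directed-edge prediction is reported as AUROC and AUPRC.

The whole model — encoder, decoder, both losses, and their analytic
gradients — is implemented in numpy; every gradient is verified against
finite differences in the test suite. It runs comfortably on one CPU.

## Worked example

```python
from gravgrn import TrainConfig, evaluate, make_fixture, split_edges, train

dataset = make_fixture("standard")          # 200 genes x 300 cells, 201 edges
split = split_edges(dataset.grn, seed=0)    # 170 train / 10 val / 21 test
model = train(split, dataset.expression, TrainConfig(variant="full", seed=0))
result = evaluate(model, split.test_pos, split.test_neg)
print(f"test AUROC = {result.auroc:.3f}, AUPRC = {result.auprc:.3f}")
```

prints

```
test AUROC = 0.825, AUPRC = 0.889 (21 positives vs 21 negatives)
```

AUROC is the probability that a true regulator→target edge outranks a random
non-edge on the balanced held-out set; 0.5 is chance. On the same fixture the
symmetric-decoder baseline (`variant="gae"`) averages ~0.76 over seeds while
the gravity decoder (`variant="gigae"`) averages ~0.86 — the direction-aware
mass term is doing real work. The `examples/` directory has one short script
per capability (importance scoring, training, the five-variant ablation,
novel-edge ranking, data simulation); each prints what it computes and what
the numbers mean.

A thin CLI mirrors the library:

```bash
gravgrn simulate --fixture standard --out data/
gravgrn train --expression data/expression.csv --network data/network.tsv \
              --out model.npz --seed 0
gravgrn rank --checkpoint model.npz --expression data/expression.csv \
             --network data/network.tsv --top-k 20
```

## Input formats

* **Expression**: CSV/TSV, genes as rows (first column gene identifiers),
  cells as columns. Assumed preprocessed upstream (filtering/normalization).
* **Networks**: two-column edge list (regulator, target), header autodetected.
* Splits serialize to a directory of edge-list TSVs for exact reruns.

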