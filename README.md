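# molactive

Binary molecular classification with a directed message-passing neural
network (D-MPNN), trained under pool-based active learning with uncertainty
sampling and combined by averaging the models of the final iterations —
plus the surrounding workflow a drug-discovery group needs: SMILES
cleaning, dataset assembly and splitting, classification and
virtual-screening statistics, and a synthetic structure–activity generator
that makes the whole stack testable on a laptop.

The motivating application is stage-wise *drug-likeness* prediction:
given a compound's structure, estimate the probability that it clears a
development milestone (entering in-vivo testing, entering clinical trials,
reaching market approval). Positives and negatives for such tasks come
from curated compound collections; labels are expensive, which is exactly
the regime where active learning pays off.

## The model

Hidden states live on **directed bonds**. With atom features $x_v$ and
bond features $e_{vw}$:

$$h^0_{vw} = \tau(W_i\,[x_v; e_{vw}])$$

$$m^{t+1}_{vw} = \sum_{k \in N(v)\setminus w} h^t_{kv}, \qquad
  h^{t+1}_{vw} = \tau\!\left(h^0_{vw} + W_m\, m^{t+1}_{vw}\right)$$

After $T$ steps, atoms collect their incoming bond states,
$m_v = \sum_{w \in N(v)} h^T_{wv}$, $h_v = \tau(W_a [x_v; m_v])$, the
molecule is sum-pooled, $h = \sum_v h_v$, and a feed-forward head over
$[h;\,d]$ — where $d$ is a z-scored vector of 200 RDKit global
descriptors — yields $\hat y = \sigma(f([h; d]))$. $\tau$ is ReLU. The
network, its backpropagation and the Adam optimizer are implemented
directly in NumPy and run on one CPU.

**Active learning.** A small stratified fraction (default 5%) of the
training pool is labeled to initialize the model. Each iteration retrains
from scratch, scores the unlabeled pool by uncertainty
$1 - \max_i P(y_i\,|\,x)$, and moves the most uncertain batch into the
labeled set; batch sizes grow geometrically ("denser at the beginning,
sparser at the end"). A passive baseline draws the same batch sizes at
random. Because every iteration sees a different training set, the
iteration models are natural ensemble members: the final prediction is
the mean probability of the last $N$ models,
$y = \frac1N \sum_n y_n$, with $N$ chosen on validation accuracy.

**Evaluation.** ACC, MCC, precision, recall, F1 from thresholded
confusion counts; rank-based ROC AUC with midrank ties; and the
enrichment factor
$\mathrm{EF}_\gamma = \frac{\mathrm{NTB}_\gamma}{\mathrm{NTB}_{total} \cdot \gamma}$
for virtual-screening runs, where $\mathrm{NTB}_\gamma$ counts true
actives in the top $\lceil \gamma N \rceil$ of the ranking. A
low-similarity test-set builder removes test molecules whose maximum
ECFP4 Tanimoto similarity to the training set exceeds 0.85.

## Worked example

Generate a 400-compound synthetic task (planted substructure rule, 5%
label noise, imbalance ≈ 1.9), run active learning with the desk preset,
pick the ensemble, and evaluate:

```bash
molactive synth ds.csv --n 400 --seed 7 --noise-rate 0.05
# wrote 400 records (pre-noise imbalance 1.90)

molactive train ds.csv run --strategy active \
    --config src/molactive/presets/desk.yaml --seed 7
# active run: 7 iterations, final val ACC 0.931

molactive ensemble run --max-size 5
# selected ensemble of N=1

molactive evaluate run/ensemble.json ds.csv metrics.json
# ACC 0.930  MCC 0.848  F1 0.902  AUC 0.957

molactive screen run/ensemble.json ds.csv screen.csv
# AUC 0.957  EF0.01=2.72  EF0.02=2.72  EF0.05=2.72  EF0.1=2.72
```

Reading the output: the model recovers the planted rule well above the
label-noise ceiling (ACC 0.93 with 5% flipped labels), and the screening
enrichment saturates its bound — with 147 actives among 400 compounds the
best achievable EF is 400/147 ≈ 2.72 at every cutoff, so a perfect top
slice prints 2.72 across the board. On strongly imbalanced screening
fixtures (e.g. 50 actives in 1000) EF at small γ approaches 1/γ instead.

`src/molactive/presets/` also ships the full-scale task presets
(hidden 300, batch 500, depth 2, learning rates 1e-3/1e-3/5e-4) together
with notes on the public corpora they correspond to; those runs require
downloading the corpora and are not part of the test path.

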