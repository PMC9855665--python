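# Methods

## Model

The classifier is a directed message-passing neural network. Hidden
states are attached to directed bonds (two per chemical bond), so that a
message flowing v→w never immediately echoes back through w→v: the
message for bond v→w aggregates the incoming states at v *excluding* the
reverse edge. The update is skip-connected to the initial bond state,

    h0_vw   = relu(W_i [x_v ; e_vw])
    m_vw^t+1 = Σ_{k∈N(v)\w} h_kv^t
    h_vw^t+1 = relu(h0_vw + W_m m_vw^t+1)

with T update steps (default 2). Readout sums each atom's **incoming**
final bond states, maps through `W_a` with a bias, and sum-pools atoms
into a molecule vector. A feed-forward head (depth 2, ReLU between
layers) acts on the molecule vector concatenated with 200 z-scored RDKit
descriptors and ends in a sigmoid.

Design choices where the formulation left room:

- *Readout direction.* The printed readout variant sums the **outgoing**
  states h_vw^T; the conventional directed-MPNN readout sums incoming
  states h_wv^T. Incoming is the default; a `readout_direction="outgoing"`
  config flag preserves the other variant. For symmetric feature schemas
  the two differ only in which atom each state is credited to.
- *Bond-state update.* The update is implemented as the skip-connected
  form `relu(h0 + W_m m)`, the only reading under which the initial state
  h0 participates in every step.
- *Biases.* `W_i`/`W_m` carry no bias (the convention of reference
  directed-MPNN implementations); the readout and head do.
- *Descriptor entry point.* Global descriptors join after pooling,
  concatenated to the molecule vector before the head. Scaling (per-
  descriptor z-score, population SD, fit on the training fold only) is on
  by default; failed descriptors are NaN and imputed to the training
  mean, and zero-variance descriptors scale to 0.
- *Optimization.* Adam (β = 0.9/0.999), minibatch binary cross-entropy,
  Glorot-uniform initialization, early stopping on validation loss with
  patience (default 10 at full scale, 5 in the desk preset), best-epoch
  weights restored. All randomness flows from one integer seed.
  Everything is NumPy on one CPU; forward and backward passes are
  vectorized over a concatenated batch graph, and the backward pass is
  hand-derived (the adjoint of the message step m_e = S_src(e) − h_rev(e)
  is dh_f = G_dst(f) − dm_rev(f) with G the source-scatter of dm).
  Correctness is pinned by tests against central finite differences and
  against an independent loop-unrolled forward implementation.

## Feature schema

Atoms: one-hot element over {C,H,O,N,P,S,Cl,Br,I,F}+other, one-hot degree
0–5, formal charge, one-hot hybridization (SP…SP3D2+other), aromaticity
flag, one-hot total-H count 0–4, atomic mass / 100. Bonds: one-hot order
(single/double/triple/aromatic), conjugation flag, ring flag. Hydrogens
are implicit. The 200 global descriptors are the first 200 entries of
RDKit's descriptor registry, pinned by name and backend version in
`src/molactive/data/descriptor_manifest.json`; tests reference the
manifest, so a backend upgrade that reorders the registry fails loudly
rather than silently changing features.

## Cleaning workflow

Seven ordered steps, each tallied separately so input and output counts
always reconcile: (1) organic filter — at least one carbon; (2) element
whitelist {C,H,O,N,P,S,Cl,Br,I,F}; (3) largest fragment by heavy atoms,
ties by total atoms then lexicographic canonical SMILES; (4) charge
standardization via RDKit's Uncharger (protonation-state charges are
neutralized where valence permits; quaternary nitrogens and internally
compensated groups such as nitro stay charged); (5) aromatic perception;
(6) canonical SMILES; (7) duplicate removal keeping the first occurrence.
Unparseable SMILES are counted under a separate parse-failure tally and
never raise per record. The pipeline is idempotent: cleaning its own
output removes nothing.

Splits follow the 9:1 train/test convention with five independent 4:1
train/validation folds drawn from the training portion; one seed derives
six sub-seeds (test draw + five folds).

## Active learning and ensembling

The initial labeled set is 5% of the training pool by default,
stratified by class (a flag disables stratification); stratification
guards against single-class initializations on imbalanced pools. Batch
sizes follow b_j = round(first_batch_fraction · pool · growth^j) with
round-half-up, truncated and the final batch clipped so the schedule
exhausts the unlabeled pool exactly (defaults 0.05 and 1.5; for a pool of
1000 this realizes 50, 75, 113, 169, 253, 340). Each iteration retrains
from scratch under a derived sub-seed — this removes path dependence and
keeps members diverse for the ensemble — and the model trained on the
fully labeled pool is appended as the last member. Uncertainty ties are
broken by ascending pool position, making selection fully deterministic.

The ensemble averages member *probabilities* (thresholding happens after
averaging); candidate ensembles are suffixes of the iteration sequence
("the last N models"), N ≤ 5 by default, chosen by validation accuracy
with ties to the smaller N. The mean is computed in centered form
(p₀ + mean(pᵢ − p₀)) so an ensemble of identical members reproduces the
single member exactly in floating point.

## Evaluation

Confusion counts threshold at 0.5 with "probability ≥ threshold is
positive" (the boundary case is positive). Any zero denominator in MCC,
precision, recall or F1 yields 0. AUC is the Mann–Whitney rank statistic
with midrank ties (computed via `scipy.stats.rankdata`; scikit-learn's
implementation serves as an independent cross-check in the tests, never
as the implementation). EF_γ uses a top set of ceil(γN) with stable
tie-breaking; it is bounded by 1/γ and equals 1 in expectation under
random ranking, which the tests verify over 200 permutations. The
low-similarity subset keeps test molecules whose maximum ECFP4
(Morgan radius 2, 2048 bits) Tanimoto to the training set is ≤ 0.85 —
"above the threshold" is read strictly.

## Synthetic structure–activity generator

The generator enumerates a closed chemical space: 8 scaffolds (benzene,
pyridine, furan, cyclohexane, C3–C6 chains) decorated with up to two of 9
substituents (F, Cl, Br, OH, NH2, COOH, NO2, CH3, OCH3) at any carbon
position — 2512 unique canonical molecules, all inside the element
whitelist, so generated libraries are fixed points of the cleaning
workflow. Activity is s(mol) = 2·[aromatic N] + 1·[halogen] +
1.5·[hydroxyl] + 0.1·heavy atoms: substructure terms exercise the graph
pathway, the size term the global descriptors. Labels are the top
fraction 1/(1+r) of the score ranking for requested imbalance r (stable
tie-breaking at the threshold score, so realized class counts match the
target exactly; the recorded `realized_imbalance` is measured on these
pre-noise labels). Each label then flips independently with probability
`noise_rate`. The study conditions used throughout the test suite are
n = 1000, noise 0.1, imbalance 1.9; the screening fixture uses n = 1000,
imbalance 19 (50 planted actives) with noise 0.02.

What the generator does *not* emulate: realistic molecular-property
distributions, scaffold diversity of vendor catalogs, activity cliffs,
assay-specific noise structure. Passing tests therefore demonstrate that
the machinery is correct and that the method's qualitative behavior
(label efficiency of uncertainty sampling, ensemble no-harm, enrichment
of a real signal) emerges when signal exists — not that any particular
accuracy transfers to real corpora.

The learnability guarantee is stated against the pre-noise ground truth:
an ECFP4 logistic baseline trained on noisy labels must reach held-out
AUC ≥ 0.9 against the clean labels. (Against the noisy labels themselves,
symmetric 10% flips cap the expected AUC of even a perfect scorer at
≈ 0.90, which would make the check a coin flip.)

## Problem sizes and numerical notes

The test suite and the acceptance script run everything at desk scale —
hidden size 32–64, depth 2, n = 400–1000 molecules, ≤ 30 epochs, 3–5
seeds — chosen so the planted rule is comfortably learnable and the
statistical comparisons (active ≤ passive label budget in ≥ 4/5 seeds)
are reproducible in minutes on one CPU. Full-scale presets are shipped
but exercised only against their configuration schema.

Tolerances: forward-pass equivalence against the loop-unrolled oracle is
asserted at 1e-6 (float64 summation-order noise); metric equivalences at
1e-9; per-record batch-position differences up to one ulp are tolerated
(BLAS row blocking). Degenerate inputs are contracts, not surprises:
bond-free molecules read out zero messages, single-class training sets
and empty pools raise, NaN losses abort with diagnostics.

## Known limitations

- Retraining from scratch each iteration is O(iterations × epochs); fine
  at desk scale, the dominant cost at corpus scale (where warm-starting
  would trade diversity for speed).
- The descriptor set is pinned by registry order, not curated; a few
  RDKit descriptors are redundant or near-constant on small molecules
  and rely on the z-scaler to neutralize them.
- Checkpoints store weights as JSON for portability, which is compact
  enough at desk scale but ~3× larger than a binary format at
  hidden size 300.
- Uncertainty sampling is the only query strategy; no query-by-committee
  or expected-model-change variants.
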