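# strandpair

Prediction of hydrogen-bonded residue–residue pairings between β strands
from predicted contact maps.

## The problem

Structure prediction of mainly-β proteins hinges on getting the β-sheet
topology right: which strands pair, in which orientation, and at which
register.  On a predicted residue contact map, a pair of interacting
strands leaves a characteristic signature — a contiguous line of high
values running diagonally (parallel strands) or anti-diagonally
(antiparallel strands).  `strandpair` turns that signature into an explicit
prediction: given two upstream contact maps (a coevolution coupling matrix
and a deep-learning contact predictor's output), the amino-acid sequence,
and a 3-state secondary-structure profile, it outputs a symmetric L×L
matrix of probabilities that residues *i* and *j* are hydrogen-bonded
bridge partners across strands.

The pipeline has three stages:

1. **Ridge detection.**  γ-normalized scale-space ridge features
   (Lindeberg): smooth the map at variances *t* ∈ {1, 2, 4}, take the
   per-pixel Hessian, and score bright ridges by
   *S* = *t*^γ · max(0, −λ₁) with γ = 3/4, keeping the max-over-scales
   height and the ridge orientation θ (encoded as cos 2θ, sin 2θ).
2. **Feature assembly.**  2D channels (both contact maps + ridge
   height/direction of each), 1D channels broadcast along rows and
   columns (secondary-structure probabilities, one-hot residue identity),
   and 0D constant planes (ln(1+N)/10 for the homolog count N, L/500) —
   56 channels with a validity mask excluding |i−j| < 3.
3. **Residual network.**  A 1×1 convolution embeds the stack, then a
   series of residual blocks, each two repeats of (normalization → leaky
   ReLU → 3×3 convolution) around a shortcut; the first repeat's
   normalization averages row normalization (RN) and column normalization
   (CN), the second uses instance normalization (IN).  A 1×1 convolution
   plus logistic squashing and symmetrization gives the probability map.
   Training is Adam on a masked binary cross-entropy under k-fold cross
   validation; the operating cutoff is chosen by pooled cross-validation
   F1, and the deployed predictor averages the fold models.

The network and its backpropagation are implemented in NumPy, so every
run is bit-reproducible given the seed.  A synthetic β-sheet simulator
(planted strand topologies, noisy contact maps, perturbed
secondary-structure profiles) makes training, evaluation and constraint
export fully testable at desk scale with no external data.

Scoring is residue-level precision / recall / F1
(F1 = 2PR/(P+R)) over unordered pairs with |i−j| ≥ 3, plus PR curves with
step-integrated AUPRC.  Predicted β pairs can be exported as folding
restraints: 3.5–6 Å for predicted β–β partners, enriched to 1·L total
constraints with non-redundant general contacts at 3.5–10 Å.

## Worked example

```python
import strandpair as sp

# 60 synthetic proteins, 50-100 residues, default noise
params = sp.SimulationParams(length_range=(50, 100))
train = sp.generate_dataset(60, params, seed=11)
test = sp.generate_dataset(20, params, seed=1011)

model = sp.BetaPairingModel.from_proteins(train)
results = model.fit(
    sp.ModelConfig(n_blocks=4, n_channels=16, use_rncn=True, in_channels=56),
    sp.TrainConfig(learning_rate=1e-3, n_folds=2, max_epochs=8, seed=7))

print(f"CV-selected cutoff: {results.cutoff:.3f}")
mtest = sp.BetaPairingModel.from_proteins(test)
report = results.evaluate(mtest.tensors, mtest.labels)
print(report.tail(1).to_string(index=False))
```

Output (single-threaded, seed 7):

```
CV-selected cutoff: 0.537
    id  precision   recall       f1
pooled   0.995169 0.962617 0.978622
```

The pooled row is the micro-average over all held-out proteins: at the
cross-validation cutoff of 0.537 the model recovers 96% of the planted
bridge partners at 99.5% precision (F1 = 0.979).  Thresholding the better
raw simulated contact map at its own F1-optimal cutoff reaches only
F1 ≈ 0.54 on the same proteins — the network's gain comes from combining
two independently-noised maps with the ridge and sequence channels.

The same pipeline is scriptable from the shell:

```bash
strandpair simulate --n 60 --seed 11 --out-dir data/
strandpair train --data-dir data/ --out-dir model/ --n-folds 2
strandpair predict --model-dir model/ --data-dir data/ --out-dir preds/
strandpair evaluate --pred-dir preds/ --data-dir data/ \
    --cutoff "$(cat model/cutoff.txt)" --out report.tsv
strandpair constraints --probs preds/p0000.pred.txt \
    --general data/p0000.mapb.txt --cutoff 0.5 --out p0000.rr
```

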