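# spikescreen

Spiking-neural-network virtual screening of molecules from binary
fingerprints.

QSAR classification — predicting a binary biological endpoint such as
clinical-trial toxicity or blood–brain-barrier permeability from a
molecule's structure — usually encodes each molecule as a molecular
fingerprint: a fixed-length bit vector marking the presence of
substructures (166 MACCS keys, or hashed extended-connectivity/ECFP
bits). Binary vectors are also exactly what spiking neural networks
consume, so a fingerprint can be injected into a spiking network with no
input conversion at all. `spikescreen` implements that idea end to end
for computational chemists and ML practitioners: standardize SMILES,
fingerprint, balance classes, train a shallow spiking classifier with
surrogate gradients, and evaluate it honestly with repeated nested
cross-validation.

## The model

Each unit is a discrete-time leaky integrate-and-fire (LIF) neuron with
reset by subtraction. With membrane decay β ∈ (0, 1), threshold θ and
input current I<sub>t</sub>:

    U_t = β · V_{t−1} + I_t
    s_t = H(U_t − θ)            (Heaviside spike)
    V_t = U_t − s_t · θ         (reset by subtraction)

The network is fully connected: one input per fingerprint bit, one
hidden LIF layer, and two output LIF neurons. The fingerprint is applied
as a constant current at every one of T simulation steps (default
T = 25); the predicted class is the output neuron with more spikes over
the window (rate coding), and the continuous score is the positive
neuron's share of output spikes.

Hard spikes are not differentiable, so training uses a surrogate
gradient: the forward pass keeps the Heaviside step, while the backward
pass substitutes d/du σ(k·u) = k σ(k·u)(1 − σ(k·u)) for the Dirac delta,
with slope k a hyperparameter. The loss is a rate-coded cross-entropy on
the softmax of output spike counts, minimized over shuffled mini-batches
of 64 with any of seven optimizers (Adam, Adamax, SGO, Adagrad,
Adadelta, AdamW, RMSProp), optional global-norm gradient clipping, and
weight decay.

Hyperparameters (hidden size, β, k, optimizer, learning rate, weight
decay, clipping, epochs) are chosen by random search inside the inner
loop of a nested cross-validation; the outer loop measures balanced
accuracy (mean of sensitivity and specificity, in %) and ROC AUC, and
the whole procedure is repeated with fresh folds to report mean ± std.
Class imbalance is handled by oversampling the minority class, either
dataset-wide before splitting or — recommended — inside each training
portion only, so no held-out fold contains copies of training molecules.

## Worked example

Screen a generated fingerprint dataset (200 molecules per class, 166
bits, 30 class-informative bits) with a small search grid:

```sh
spikescreen screen --synthetic --n-per-class 200,200 \
    --outer-k 3 --inner-k 2 --repeats 2 --draws 4 --steps 15 \
    --seed 11 --out run/
```

prints

```
BA 87.310 ± 6.219 %  AUC 0.879 ± 0.063
```

i.e. across two repetitions of the 3-fold outer loop the selected
networks recovered the planted class signal with ~87 % balanced
accuracy and 0.88 AUC on held-out molecules. `run/top_models.csv` ranks
the searched configurations, result-table style:

```
hidden,beta,slope,optimizer,lr,wd,gc,mean_ba,std_ba
64,0.8,50.0,Adam,0.002,0.0,False,89.93,1.12
64,0.95,50.0,Adam,0.002,0.0,False,86.19,1.12
...
```

and `run/manifest.json` records the grid, seeds and fold indices needed
to replay the run bit-identically.

Other commands: `spikescreen encode` converts a SMILES/label CSV into a
MACCS (166-bit) or ECFP (radius 2, 1024-bit) matrix with a skip report;
`spikescreen neuron --beta 0.9 --current 0.2 --steps 8 --out trace.csv`
writes a membrane-potential trace — with these settings the potential
charges geometrically (0.20, 0.38, 0.54, …) until it crosses θ = 1 at
step 6, spikes, and resets by subtraction to 0.043. Real datasets in
MoleculeNet CSV layout are screened with
`spikescreen screen --dataset my.csv --label-col <task>`.

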