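# walklrp

Walk-level relevance analysis for message-passing interatomic potentials.

Machine-learning force fields (MLFFs) built on graph neural networks can
reach excellent test-set accuracy while still having learned chemically
implausible interactions — a failure mode that shows up later as unstable
molecular-dynamics trajectories.  `walklrp` implements an explainability
pipeline that makes the learned interactions measurable: it decomposes a
message-passing model's energy prediction onto *walks* (ordered sequences of
atoms relaying messages through the network) by higher-order layer-wise
relevance propagation, and derives from those walk relevances a set of
interaction statistics — interaction range, pairwise interaction strength,
many-bodyness and decay laws — that can be compared against physical
expectations.

Because training state-of-the-art MLFFs is out of desk scope, the package
ships a small invariant message-passing potential (a SchNet-style
continuous-filter convolution, written in NumPy and fully
relevance-tractable) together with a synthetic-systems module whose analytic
Morse + three-body labels provide exact ground truth for every statistic.

## The quantities

For a depth-`T` network a walk `W = (v_0, …, v_T)` steps along neighbor-graph
edges or stays put (the combine step).  Relevance propagation with the
ε-rule,

```
R_j = Σ_c  z_jc / (Σ_j' z_j'c + ε·sign)  R_c ,
```

applied while retaining atom indices yields one scalar `R_W` per walk, with
conservation `Σ_W R_W = y`.  From these:

* **importance** `p_w = |R_W| / Σ|R_W'|` — a probability distribution over walks;
* **extent** `d(W)` — diameter of the smallest sphere enclosing the atoms in `W`;
* **interaction range** `λ^thresh = max{ d(W) : p_w ≥ p_min }` (default
  `p_min = 0.001`), or the generalized expectation
  `λ_a^pow = (Σ p_w d(W)^a)^(1/a)` (default `a = 4`);
* **interaction strength** `s_ij` — summed importance of walks traversing
  atoms `i` and `j` (inclusive: other atoms allowed; exclusive: none);
* **many-bodyness** `γ(R) = log10(P100(S_R) / P10(S_R))` over the strengths
  `S_R` of pairs at (approximately) equal distance `R`, averaged to `γ̄`.
  A strict 2-body force field gives `γ̄ = 0`; one unit of γ means equally
  distant pairs differ by a factor of 10 in strength;
* **decay fits** — exponential vs power-law least squares on binned median
  strength against distance.

## Worked example

```python
import walklrp as w

# generate a Morse-labelled ensemble of 6-atom clusters
spec = w.GeneratorSpec(topology="random_cluster", n_atoms=6, min_distance=1.1,
                       n_samples=200, seed=7)
data = w.label_conformers(w.generate_conformers(spec), w.PairPotentialParams())

# fit a depth-2 message-passing potential (scikit-learn style estimator)
est = w.MessagePassingPotential(depth=2, cutoff=4.0, epochs=400, lr=8e-3,
                                seed=0).fit(data, [c.energy for c in data])

# decompose one prediction onto walks and measure the learned interactions
rmap = w.walk_relevances(est.params_, est.config_, data[0])
dist = w.walk_importance(rmap)
table = w.pair_interaction_strength(rmap)
```

This prints (numbers produced by the code above):

```
validation RMSE: 0.131 kcal/mol
walks: 216, y = -0.1539, conservation residual = 4.00e-06
lambda_thresh(p_min=0.001) = 3.13 A
lambda_pow(a=4)            = 1.86 A
    i  j  distance  strength
13  3  5     1.502     0.064
3   0  4     1.722     0.060
5   1  2     1.731     0.059
```

The model explains 216 = 6³ walks (the 4 Å cutoff makes the 6-atom graph
complete); their relevances recover the prediction to 4·10⁻⁶ relative.  The
strongest pair interactions sit near the Morse equilibrium distance
(1.5 Å), and the thresholded interaction range of ~3 Å says the model stops
using walks that span more than about two coordination shells.

The same pipeline is scriptable from the shell:

```
walklrp generate --n-atoms 6 --n-samples 100 --out data.xyz
walklrp train --data data.xyz --epochs 200 --out model.json
walklrp explain --checkpoint model.json --data data.xyz --out walks.csv
walklrp metrics --checkpoint model.json --data data.xyz --outdir metrics/
walklrp stability --energies energies.txt
```

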