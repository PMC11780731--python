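# Methods

## The toy potential

The trainable model is a minimal invariant message-passing network of the
continuous-filter-convolution family.  Atom `k` starts from a learned
element embedding `H_0,k ∈ R^m` and is updated for `t = 1…T`:

```
H_t,k = act( C_t H_{t-1,k} + Σ_{j ∈ neigh(k)} Γ_t(r_kj) ⊙ U_t H_{t-1,j} )
```

`neigh(k)` is the set of atoms within the cutoff `c`; `Γ_t(r)` is a small
filter network (one hidden layer of shifted softplus) over a Gaussian
radial-basis expansion of the distance, optionally damped by the cosine
cutoff `½(1 + cos(πr/c))`; `act` is shifted softplus, or identity for the
linear models used by the oracle tests.  An atom-wise readout MLP maps
`H_T,k` to a per-atom energy; the total is their sum, which makes the
prediction exactly invariant under rigid motions and permutations.

Two design choices serve relevance propagation rather than accuracy:

* **Bias-free combine/message/readout layers.**  Only the filter networks
  carry biases, and filters act as constant gates during propagation.  With
  all relevance-carrying layers bias-free, the per-neuron contributions sum
  exactly to the pre-activation and the ε-rule conserves relevance up to the
  stabiliser alone.
* **Energy-only model.**  Explanations target the scalar prediction;
  forces are derivable but are not a propagation target.

Defaults: `m = 16` neurons per atom, filter and readout hidden width 16,
`n_rbf = round(4·c)` so the radial grid spacing is 0.25 Å for every cutoff
(a depth ladder with constant `T·c` then shares one spacing), Gaussian width
equal to the grid spacing.  The filter-network depth/width are fixed package
choices, not tuned values.  Training is full-batch Adam (default
`lr = 5·10⁻³`) on standardised energies, with a seeded deterministic
validation split (fraction 0.15) and checkpointing that always includes the
untrained epoch-0 initialisation; divergence (non-finite loss) aborts with
the epoch number.  All randomness flows from one integer seed; two fits
with the same seed and data are bitwise identical.

## Walk relevances

Relevance starts at each atom's readout energy contribution (sum pooling is
trivially conservative), is redistributed over the readout and each
message-passing layer by the ε-rule

```
R_j = Σ_c  z_jc / stab(Σ_j' z_j'c)  R_c ,      stab(z) = z · (1 + ε)
```

and the atom index is retained at every layer instead of being pooled,
giving one scalar per walk `(v_0, …, v_T)`.  Consecutive repeated indices
are legal walks: the combine term `C_t H_{t-1,k}` is the self-transition.
Nonlinearities pass relevance through unchanged (standard LRP treatment);
the γ-rule (positive weight parts boosted, denominators recomputed) is
available by configuration.

The stabiliser is *relative* (`z·(1+ε)`), which keeps the per-step
conservation factor at exactly `1/(1+ε)` independent of activation scale;
ε is therefore genuinely dimensionless and the total conservation residual
is ≈ `(T+2)·ε` for any model.  Exactly zero denominators (possible only for
ε = 0 or dead units) drop their relevance share; the dropped count is
surfaced on the result and shows up in the conservation residual.

Walk enumeration is exact and exponential, `O(Σ_k (deg(k)+1)^T)`; a
configurable cap (default 10⁷) aborts enumeration with an explicit error
rather than thrash.  Polynomial-time reformulations are out of scope.
Per-walk propagation reuses precomputed per-edge redistribution matrices,
so the cost per walk is one `m×m` matrix-vector product per layer.

Two independent oracles validate the engine: on identity-activation models
the walk relevance has a closed form (the embedding of `v_0` pushed through
the per-step matrices `C_t` or `diag(Γ_t)U_t` and the readout), and walk
counts must equal powers of the adjacency-plus-identity matrix.

## Metrics

* **Importance** `p_w = |R_W|/Σ|R_W'|`.  Absolute-value normalisation is the
  only choice that yields values in [0,1] for signed relevances; it is also
  what makes strengths comparable across conformers.
* **Extent** is the diameter of the minimum enclosing sphere of the walk's
  (deduplicated) atoms, computed by Welzl's algorithm with exact
  circumsphere solves and a subset-enumeration fallback for degenerate
  boundary sets; a brute-force candidate-sphere oracle checks it to 1e-9 Å.
* **Interaction range**: thresholded maximum extent (default
  `p_min = 0.001`) and the generalized expectation (default `a = 4`).
  `p_min = 0` is rejected — it would always return the geometric maximum,
  ignoring the model.  The power statistic is evaluated in scaled form to
  stay stable for large `a`.
* **Strengths**: inclusive (visited-atom set ⊇ {i,j}) and exclusive
  (= {i,j}, revisits allowed).  Self-strength (walks visiting only atom i)
  is a documented extension.  Per-conformer tables are concatenated for
  multi-conformer statistics.
* **Element matrices** take the mean of log10 strengths per element pair,
  split at 1.6 Å into bonded/nonbonded; mean-of-logs (not log-of-mean) is
  used; empty cells stay NaN with a count matrix alongside.
* **Many-bodyness** bins pairs by distance (default width 0.5 Å, minimum
  20 pairs per retained bin; explicit edges or disjoint windows may be
  passed instead, e.g. narrow windows at exactly repeated distances).
  γ = log10(P100/P10) per bin with numpy's linear-interpolation percentile
  convention; γ̄ is the unweighted mean over retained bins.  Non-positive
  strengths are excluded from logs and counted; dropped bins are counted.
* **Decay fits** use per-bin medians and least squares in log space for
  both candidate laws; the lower squared residual wins, and a near-constant
  profile raises a degenerate flag.  At least five occupied bins are
  required.

## Synthetic systems

The generator produces chains (exact spacing), rejection-sampled random
clusters (bounded retries, explicit packing failure), dimer scans, and
"embedded-pair" ensembles in which designated same-element pairs sit at
exactly repeated separations inside varying random neighbourhoods.  Labels
come from a Morse pair potential `u(r) = D(1−e^{−a(r−r_e)})² − D`
(defaults D = 3 kcal/mol, r_e = 1.5 Å, a = 1.2 Å⁻¹ — bond-like scales so
clusters at ~1.1 Å minimum distance produce energies of a few tens of
kcal/mol) plus an optional three-body term: per triple, `sin²` of each
vertex angle damped by `exp(−(r₁+r₂)/ρ)` and scaled by an amplitude, which
is identically zero on collinear triples and disabled at amplitude 0.

Analytic pair strengths are `|u(r_ij)|`; with a three-body term each
triple's absolute energy is shared equally (⅓ each) onto its three pairs.
This gives the end-to-end calibration pair: at exactly repeated distances a
strict 2-body potential yields γ̄ = 0 to machine precision, while a growing
three-body amplitude yields strictly growing γ̄ (the bin maximum and 10th
percentile are affine in the amplitude with different slopes).

What the synthetic conditions do *not* emulate: chemical element diversity
beyond a small palette, realistic force-field functional forms,
conformational ensembles from dynamics, and the system sizes of real
biomolecules.  Passing tests therefore demonstrate correctness of the
decomposition and metrics, and qualitative behaviours of small trained
models — not quantitative fidelity to any production MLFF.

## Study conditions for the trained-model checks

Problem sizes are chosen so the full pipeline stays desk-scale: ensembles
of 120–200 clusters with 6–9 atoms, depth-2 models with 10–16 neurons per
atom, 150–400 epochs.  Under these conditions the fitted models reach
validation RMSE below 5 % of the label standard deviation; strength-vs-
distance medians of a depth-2 model whose 3.5 Å cutoff is well below the
~8 Å cluster diameter prefer an exponential fit over a power law (the
walk-count decay bakes this in); and training on three-body-labelled data
extends the thresholded interaction range relative to the untrained
initialisation in the majority of seeded repeats.

## Known limitations

* Exponential walk enumeration restricts analyses to small molecules or
  shallow networks (the cap errors out otherwise).
* Equivariant (vectorial-feature) architectures are not supported; the LRP
  treatment here covers scalar invariant features only.
* The ε-rule with a relative stabiliser conserves well but can assign large
  cancelling relevances to individual walks when pre-activations are tiny;
  the γ-rule is exposed for such cases.
* MD itself is not simulated; the stability criterion classifies an energy
  series produced elsewhere (unstable iff any sample leaves
  −200…200 kcal/mol, or is non-finite).
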