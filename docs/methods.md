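# Methods

## The inverse problem

Electrocardiographic imaging (ECGI) reconstructs cardiac electrical sources
from multi-lead body-surface potentials. Under the quasi-static
approximation the forward relationship is linear,

    Phi = H U,

where `U` (n nodes × t frames, mV) is the transmembrane potential (TMP)
sequence on the heart, `Phi` (m leads × t) the body-surface potential (BSP)
sequence, and `H` (m × n) the lead-field (transfer) matrix encoding
geometry and conductivity. With m ≪ n and a smoothing forward kernel the
problem is severely ill-posed — on the default phantom `cond(H) > 10¹⁴` —
so the solution must be regularised.

## Graph-based total variation

TMP distributions during the ST plateau (infarct imaging) and during
depolarisation (pacing imaging) are piecewise flat: nodes fall into a small
number of electrophysiological classes (scar vs healthy; activated at
similar times) with sharp boundaries. Spatial total variation exploits this
but only couples spatially adjacent nodes and processes one frame at a
time.

The method here instead measures similarity between nodes by the Euclidean
distance between their whole TMP *time courses*,

    l_ij = || u_i - u_j ||_2 ,

builds a k-nearest-neighbour graph on those distances (directed lists
symmetrised by union, ties broken toward the lower node index), and
weights every retained edge with a Gaussian kernel

    W_ij = exp( - l_ij² / sigma² ),    sigma = mean l over retained edges.

The penalty is the weighted anisotropic TV over the graph,

    || grad_G U ||_1 = sum_edges sum_frames sqrt(W_ij) | U[i,s] - U[j,s] | ,

equivalently the entrywise L1 norm of `D U`, where `D` is a sparse E × n
operator with one row per edge carrying `+sqrt(W_ij)` at node i and
`-sqrt(W_ij)` at node j. The reconstruction solves

    min_U  || H U - Phi ||_F²  +  mu * || D U ||_1 .            (*)

The graph is built once from a low-resolution initial estimate — the
second-order Tikhonov solution

    U_hat = (HᵀH + lambda LᵀL)⁻¹ Hᵀ Phi,

with `L` the surface Laplacian of the heart mesh — and is not rebuilt
during the iterations. Because the trajectory distance uses the full
sequence, the graph couples the frames and the whole sequence is solved at
once, in contrast to frame-by-frame TV.

## Optimisation

Problem (*) is a smooth-plus-nonsmooth composite with a linear operator
inside the nonsmooth term, solved by a forward–backward primal-dual
(Condat–Vũ type) iteration:

    U⁺ = U - tau * ( 2 Hᵀ(H U - Phi) + Dᵀ V )
    V⁺ = prox_{sigma g*}( V + sigma D (2 U⁺ - U) )

where `g = mu ||.||_1`, so the dual prox is an entrywise clip of V to
[-mu, mu], computed through the Moreau decomposition
`prox_{s g*}(x) = x - s prox_{g/s}(x/s)` with the soft-threshold operator
`prox` of the L1 norm.

Step sizes: the data-term gradient `2 Hᵀ(HU - Phi)` is Lipschitz with
constant `beta = 2 ||H||₂²` (spectral norm squared, computed by a
deterministic power iteration). We set `tau = 1/beta` and take the largest
dual step allowed by the convergence condition

    1/tau - sigma ||D||₂² >= beta/2,

scaled by a safety factor `gamma = 0.99`; the condition is asserted at run
time on every solve. Note the Lipschitz constant of the gradient of
`||HU-Phi||_F²` is `2||H||₂²`, not `2||H||₂`; the squared form is what the
convergence condition requires, and it is what the package uses.

The iteration stops when the relative Frobenius change of U drops below
`tol = 1e-5` or after `max_iter = 500` iterations. Because this class of
primal-dual methods is convergent but not monotone in the objective, the
solver tracks the objective of every iterate and returns the best one seen
(the starting point included); the last entry of the recorded objective
trace is the returned iterate's objective, which therefore never exceeds
the initial one. The dual variable starts at zero, the primal at the
Tikhonov estimate. All linear solves use Cholesky factorisation, never an
explicit inverse.

## Baselines

* **Tikhonov-2** — the closed-form surface-Laplacian solution above; also
  the initial estimate for the graph.
* **IRTV** — iteratively reweighted spatial TV, frame by frame: edge
  weights `w_e = 1/(|(D0 u)_e| + eps)` are re-estimated from the current
  solution (`D0` the unit-weight spatial incidence operator,
  `eps = 1e-3 ×` the current estimate's dynamic range, floored at 1e-9),
  and each weighted inner problem is solved with the same primal-dual
  engine, warm-started; 5 outer stages share the `max_iter` budget evenly.
  Weights start uniform, so one outer stage is exactly unweighted spatial
  TV. The per-frame problems share `H` and `D0` and are separable across
  frames, so they are solved simultaneously with per-(edge, frame) clipping
  radii — numerically identical to a frame-by-frame loop, just vectorised.

## Synthetic phantom

The phantom emulates a torso-tank-style validation setup entirely in code:

* **Heart mesh** — a quasi-uniform point cloud on an ellipsoidal myocardial
  shell (semi-axis ratios 1.0 : 0.85 : 1.25, mean radii 25–50 mm, default
  n = 800 nodes; the clinical-scale n = 2223 is one config change away).
  Nodes sit on concentric Fibonacci-lattice layers with a small seeded
  jitter. Spatial adjacency is symmetric 6-nearest-neighbours; `L` is the
  combinatorial graph Laplacian; eight segments are the coordinate octants.
* **Lead field** — an infinite homogeneous-medium monopole kernel
  `1/(4 pi sigma_c d)` (conductivity 0.2 S/m) from every node to each of 64
  leads on a 150 mm sphere, with each column mean-subtracted across leads
  (a Wilson-central-terminal analogue). This reproduces the two properties
  the inverse methods are sensitive to — spatially smooth columns and
  severe ill-conditioning — without patient-specific BEM/FEM modelling.
* **Infarct truth** — plateau-phase map, scar ball (default radius 20 mm)
  around a segment centroid at −84 mV, healthy tissue at 27 mV, constant
  over a 100-frame (100 ms) sequence.
* **Pacing truth** — an isotropic constant-velocity wavefront (default
  0.6 mm/ms) from a pacing node; each node follows a logistic upstroke from
  −84 to 27 mV with a 2 ms time constant, shifted by its activation time.
  Sequence lengths 150–250 frames.
* **Noise** — additive white Gaussian noise at a prescribed SNR in dB,
  defined against the mean-square signal power of the whole BSP matrix;
  every draw is seeded.

What the phantom does **not** emulate: realistic torso inhomogeneity and
geometry, fibre anisotropy, ionic-model AP morphology (notably
repolarisation), measurement drift or correlated lead noise, and
electrode-placement error. Passing results therefore demonstrate the
correctness and the comparative behaviour of the algorithms under
controlled conditions, not clinical-grade accuracy.

## Evaluation

* **CC / RE** — Pearson correlation and relative L2 error between
  reconstruction and truth. Default scope is the flattened whole sequence;
  per-frame values (and their means) are also reported by the experiment
  tables, since the two conventions can differ.
* **Activation time** — per node, the frame of maximum forward difference
  dU/dt (steepest upstroke); nodes with peak-to-peak excursion below 10 mV
  are flagged unactivated (NaN). A threshold-crossing alternative would
  behave similarly on the logistic template.
* **Localization error** — distance between the earliest-activated nodes of
  the reconstructed and true activation maps (ties resolved to the centroid
  of the tied nodes).

## Parameter handling in the studies

The two regularisation weights are tuned by grid search against ground
truth on a *held-out* noise realization, then fixed for the evaluation
realizations — one value per (SNR, method):

* `lambda` (Tikhonov / initial estimate): geometric grid spanning 0.1×–10⁴×
  the trace-ratio scale `tr(HᵀH)/tr(LᵀL)`. The library default outside the
  studies is `0.01 ×` the trace ratio, which is deliberately light; on the
  default phantom the tuned value is ~30× the ratio.
* `mu` (TV weight): geometric grid spanning 1e-4×–1× of
  `max |2 Hᵀ Phi|` — the data-term gradient magnitude at U = 0, the natural
  scale the TV subgradient must balance — with 9 points (half-decade
  steps).

Study sizes were chosen so the full default studies run in minutes on a
laptop: n = 800 nodes, 64 leads, 100-frame infarct sequences; the infarct
grid is 8 scar locations × 6 SNR levels (5–30 dB) × 3 methods.

## Known limitations and observed behaviour

* The k-sensitivity of graph TV on this phantom is larger than the
  near-zero spread the method aspires to: the TV penalty (as defined) has
  no per-node normalisation, so its effective strength grows with the edge
  count, and a `mu` tuned at k = 5 over-regularises at k ≥ 10. With `mu`
  retuned per k the quality is nearly flat in k. Users sweeping k should
  therefore co-sweep `mu`.
* The CC-optimal `mu` is not monotone in SNR here: at high SNR the
  trajectory graph built from a good initial estimate matches the true
  partition, and since CC is affine-invariant, very strong smoothing along
  a correct graph costs no correlation — the CC(mu) curve develops a second
  plateau at large `mu`. At low SNR the graph itself is noisy and large
  `mu` hurts. The classical "more noise, more regularisation" rule applies
  to a fixed operator, not to a noise-dependent graph.
* Condat–Vũ iterations on the severely ill-conditioned default phantom
  typically exhaust `max_iter = 500` before the 1e-5 relative-change
  criterion; the best-iterate policy makes the returned solution safe
  regardless.
* Activation-time maps from noisy reconstructions can contain spurious
  early nodes; the localization metric takes the global earliest node and
  inherits that sensitivity (it affects all methods equally in the
  comparisons).
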