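# Methods

## Problem and model

`fedsimhash` learns compact binary representations ("hash codes") of
patients whose electronic-health-record features are split across `M`
sites that cannot share patient-level data, and uses those codes for
privacy-preserving similar-patient search and κ-NN disease-incidence
prediction.

Each patient is described by `K` feature domains (demographics, lab
results, prescriptions, diagnoses, conditions, symptoms). Domain `k` of
site `i` is a matrix `P_k^i ∈ R^{d_k×N_i}` with patients as columns. The
model is one linear hash function per domain, `f_k(P) = W_k^T P` with
`W_k ∈ R^{d_k×b_k}`; codes are `H_k^i = sign(W_k^T P_k^i) ∈ {−1,+1}^{b_k×N_i}`.
Learning one function per domain (multi-hash) rather than one over the
concatenated features (uni-hash) keeps a per-domain similarity breakdown —
not only *how* similar two patients are but *why*.

### Objective

The sign function is non-differentiable, so each site keeps a real-valued
relaxation `Q_k^i ∈ R^{b_k×N_i}` passed through the smooth surrogate

    S_L(q) = q / sqrt(q² + ξ),   S_L(q) ∈ (−1, 1),

and the fit minimizes

    f(W, Q) =  Σ_{i,k} ‖W_k^T P_k^i − S_L(Q_k^i)‖_F²            (reconfiguration)
             + λ Σ_{i,k} tr( −S_L(Q_k^i) R^i S_L(Q_k^i)^T )      (supervised)
             + η Σ_{i,k} ‖Q_k^i‖_F²                              (regularizer)

where `R^i` is the ±1 label-agreement matrix of site `i` (`+1` same
label, `−1` different, `0` on the diagonal — self-pairs carry no
information and only add a constant pull, so they are excluded). The
supervised term rewards same-label patients for having aligned surrogate
codes and different-label patients for anti-aligned ones; the η term pins
down the otherwise non-unique `Q`.

Hooks for an unsupervised similarity term and for Frobenius/orthogonality
regularizers on `W` exist in the general framework but have no solver
support here by design.

### Optimization

Block coordinate descent with damped Newton steps:

* **W blocks.** Only the reconfiguration term involves `W_k`, so the
  update is a quadratic problem whose Hessian is block-diagonal across
  the `b_k` columns with identical `d_k×d_k` blocks `2 Σ_i P_k^i P_k^iᵀ`
  (this structure is exact, not an approximation). One `d_k×d_k` solve
  per domain per iteration.
* **Q blocks.** The gradient chain-rules through `S_L`; the Hessian is
  block-diagonal across bits with `N_i×N_i` blocks that couple patients
  only through `R^i`.
* **Damping.** Every Newton step gets a Tikhonov ridge
  (`hessian_ridge × mean diagonal`, default factor 1e-6) and a
  step-halving line search (≤ 20 halvings) that accepts a step only if
  the block's own objective contribution does not increase; if no step
  length helps, the block is left unchanged. This makes the objective
  trace non-increasing by construction even though the supervised term
  is non-convex.
* **Damping granularity.** Given `W`, the Q subproblem separates over
  connected components of the nonzero pattern of `R^i`. Step-halving is
  applied per component. Besides being the natural granularity, it makes
  the fit exactly decomposable: running the solver on sites concatenated
  into one dataset with a block-diagonal `R` reproduces the per-site run
  to floating-point noise (`features.concatenate_sites` builds exactly
  that pooled view, and a test pins the equivalence at 1e-8).
* **Stopping.** Relative objective change below `rel_tol` (default 1e-6)
  or `max_iter` (default 100) iterations. `rel_tol = ∞` returns the
  initialization untouched.

Initialization: `W_k ~ N(0, 0.1²)` (seeded), `Q_k^i = W_k^T P_k^i` —
consistent with the reconfiguration term, so the starting point is
already self-consistent. `sign(0) = +1` everywhere, documented and
tested.

### Federation

Sites never ship `P`, `Q`, `H`, or `R`. A W-update needs only the
per-site aggregates `G2 = P P^T` (`d_k×d_k`), `C = P S_L(Q)^T`
(`d_k×b_k`) and the scalar `‖S_L(Q)‖_F²`; these are summed over sites
(Hessians aggregated *before* inversion) and the coordinator takes the
identical damped Newton step a centralized fit would take — the
federated and centralized model sequences agree bit-for-bit, which the
test suite asserts. Q updates are entirely local. Every message is
logged with its payload shapes so the aggregate-only property can be
audited structurally. Only the synchronous schedule is implemented; the
asynchronous schedule is an interface stub (it would break the
centralized-equivalence anchor that the correctness tests rely on).

The aggregates are not protected cryptographically: with `N_i > d_k`
they are many-to-one in `P` and not invertible, which is the framework's
(non-cryptographic) privacy argument for the learning phase. Encryption
enters at search time.

### Similarity search

Per-domain similarity `s_k = h_u^T h_v / b_k ∈ [−1,1]`; the overall
score is the mean over domains (the normalized reading — the
unnormalized sum is not bounded by 1, so boundedness forces this
interpretation). Ranking for κ-NN uses hamming distance over the
concatenated `b = Σ b_k` bits, linked by `s = 1 − 2 d_H / b`; the
per-domain breakdown is reported alongside. Distance ties break by
reference id ascending, making results invariant to reference ordering.
The κ-NN vote probability is the positive fraction among the κ nearest
references.

### Encrypted distance protocol

A querier encrypts each ±1 bit of its code under its own Paillier public
key and ships `b` ciphertexts. The responder — constructed from the
public key only, so it structurally cannot decrypt — raises each
ciphertext to its own ±1 bit and multiplies, producing the single
ciphertext `Enc(Σ u_t v_t)`, and returns only that. The querier decrypts
and converts `d_H = (b − ⟨u,v⟩)/2`, with range and parity checks on the
decrypted value. The responder thus answers exactly one number per
comparison — the distance and nothing else — and the encrypted path
equals the plaintext hamming distance exactly for every pair (tested
exhaustively at protocol scale and on 200 random 52-bit pairs).

The Paillier implementation is self-contained (`n = pq`, `g = n+1`,
sympy primality testing, signed messages in `(−n/2, n/2]`). The
configurable key floor is 128 bits; tests use 256-bit keys for speed.
Both are far below the ≥2048 bits of modern Paillier practice, which is
the default for real use.

## Synthetic cohorts

The generator emulates the *structure* of a multi-site EHR study, not
any real database's marginals:

* 6 domains: static demographics (gender one-hot + raw age) and five
  coded domains with vocabularies of 30/30/30/20/20 codes;
* 1–5 admissions per patient, 80–120 coded events per patient dealt
  into admissions in temporal order, equal spacing assumed;
* label signal: 20% of each coded vocabulary is designated "signal";
  positives draw those codes with sampling weight multiplied by
  `exp(signal_strength)` (default 2.0, i.e. a log-odds enrichment);
* positives carry the target diagnosis code in exactly one admission,
  never the first, so every positive retains a usable pre-outcome
  history;
* partitioning across sites is exact in size; per-site positive counts
  are floored, with the remainder filled by negatives (if floor rounding
  exhausts negatives at the tail, the deficit is covered by positives
  with a warning).

Defaults were fixed once so that a raw-feature cosine κ-NN on the
time-decayed vectors reaches AUC ≥ 0.95 — a cohort separable enough that
hashing quality, not label noise, is what the evaluation measures.

What the generator does **not** emulate: realistic code frequencies or
dimensionalities, temporal irregularity (event spacing is uniform by
assumption), lab-value quantization, cross-site coding-system drift, or
admission-level correlation structure. Passing tests therefore
demonstrate correctness of the machinery and qualitative behavior of the
systems, not clinical-grade performance on real records.

## Feature construction

Events are flattened across admissions into one stream; the event `t`
steps back from the stream's end contributes `exp(−γ t)` (default
`γ = 0.01`) to its code's one-hot entry, so the most recent event has
weight 1 and older events decay — the orientation follows from wanting
recent events to dominate. Demographics are copied without decay, age
as-is. Whether decay should instead restart within each admission is
ambiguous; the flattened-stream reading is implemented. For patients in
whom the target disease occurs, the admission containing its first
occurrence and everything after are cut, and only prior admissions feed
the features (label 1); patients whose very first admission contains the
target have no history and are dropped with a logged count. Unknown
codes at transform time are dropped with a warning rather than raised,
so a frozen vocabulary can be applied to new cohorts.

## Evaluation design

Repeated stratified cross-validation (defaults: 5 folds × 10 repeats,
κ ∈ {1, 3, 9}); stratification keeps both classes in every desk-scale
fold even though plain random splitting would also be defensible. Fold
assignments depend only on labels and the seed, so every sharing regime
sees identical folds (paired comparison). Three regimes: *open* (sites
pool raw data, one central fit with relationships spanning all pairs),
*closed* (per-site fit and evaluation, unweighted mean over sites —
single-class sites are flagged undefined), and *federated* (shared hash
functions, local codes). Code modes: multi-hash, uni-hash
(`b = Σ b_k = 52` over concatenated features), and raw-feature distance
baselines (euclidean, cityblock, cosine, correlation) on the unscaled
concatenated vectors — their weakness relative to hashing is the
phenomenon of interest, not a defect. AUC is computed per repeat over
each patient's single out-of-fold vote probability; F1, sensitivity and
specificity use a 0.5 vote threshold (exposed as a flag; no canonical
value exists for κ-NN votes).

A noteworthy empirical property at the default operating point: the
federated fit consistently edges out the open fit (mean AUC ≈ 0.99 vs
0.97 over ten seeds). Pooling grows the supervised pair set quadratically
while the reconfiguration term grows linearly, so at fixed λ the pooled
objective over-weights pairwise attraction/repulsion and the fitted `W`
generalizes slightly worse. Both comfortably beat the closed system
(≈ 0.85). The package reports what it measures; on real, heterogeneous
data the open system's access to pooled raw records may well dominate.

## Configuration defaults

| parameter | default | meaning |
|---|---|---|
| `b_k` | 2 (demographics), 10 (coded) | bits per domain; 52 total over 6 domains |
| `λ` | 0.5 | weight of the supervised pairwise term |
| `η` | 1e-3 | Frobenius regularizer on Q |
| `ξ` | 0.5 | surrogate-sign smoothing; tests also exercise 1e-2 |
| `γ` | 0.01 | time-decay constant, per event step |
| `rel_tol`, `max_iter` | 1e-6, 100 | stopping rule |
| `hessian_ridge` | 1e-6 | ridge factor × mean Hessian diagonal |
| `M`, site size | 3, 125 | federation shape |
| folds × repeats, κ | 5 × 10, {1,3,9} | evaluation design |

ξ is not fixed by the framework itself; 0.5 keeps gradients informative
early in the fit while still approximating the sign well near ±1.

## Problem sizes used in tests

The test and acceptance suites run cohorts of 60–380 patients (2–3
sites of 30–125), 3 CV folds × 1 repeat for the multi-seed comparisons,
30 solver iterations, and 256-bit keys — sizes chosen so the full suite
completes in about a minute while still exercising every code path at
the study's structural scale (six domains, 52-bit codes, M=3).

## Known limitations

* The Q-update Hessian blocks are `N_i×N_i` per bit; cohorts beyond a
  few thousand patients per site would need the gradient-descent or
  parallelized variants discussed above rather than exact Newton solves.
* The derivative bundles are exchanged in the clear (no secure
  aggregation or differential privacy); their safety rests on the
  non-invertibility argument only.
* The encrypted protocol reveals exact distances to the querier, which
  over many adaptive queries leaks geometry; no query budget is
  enforced.
* Asynchronous/streaming updates are unimplemented stubs.
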