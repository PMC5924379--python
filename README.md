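# fedsimhash

Privacy-preserving patient-similarity learning across institutions.
`fedsimhash` learns per-feature-domain binary hash codes for patients
held at multiple sites **without sharing patient-level data**, searches
similar patients by hamming distance between codes — optionally under
additively homomorphic encryption so a responding site reveals exactly
one distance and nothing else — and evaluates κ-NN disease-incidence
prediction against open/closed-system and raw-distance baselines.

It is aimed at researchers prototyping federated patient-matching
pipelines (cohort construction, disease surveillance, trial recruitment)
and at anyone who wants a small, fully tested reference implementation
of supervised multi-modal hashing with federated Newton updates.

## The model in brief

Patients are described by `K` feature domains (demographics, labs,
prescriptions, diagnoses, conditions, symptoms), each a time-decayed
one-hot vector: an event `t` steps before the end of the record
contributes `exp(−γt)` to its code's entry. Site `i` holds matrices
`P_k^i ∈ R^{d_k×N_i}`. One linear hash function per domain,
`f_k(P) = W_k^T P`, yields codes `H_k^i = sign(W_k^T P_k^i) ∈ {−1,+1}^{b_k×N_i}`.
The coefficients and per-site relaxations minimize

    f(W,Q) = Σ_{i,k} ‖W_kᵀP_k^i − S_L(Q_k^i)‖_F²
           + λ Σ_{i,k} tr(−S_L(Q_k^i) R^i S_L(Q_k^i)ᵀ)
           + η Σ_{i,k} ‖Q_k^i‖_F²,      S_L(q) = q/√(q²+ξ),

where `R^i` is the ±1 label-agreement matrix. Optimization is block
coordinate descent with damped Newton steps; every statistic a site
emits for the shared `W_k` update is a `d_k×d_k` / `d_k×b_k` aggregate,
so the federated fit equals the centralized one bit-for-bit (a property
the test suite asserts). Similarity between patients u and v is
`s_k = h_uᵀh_v / b_k` per domain, averaged over domains, and is linked
to hamming distance by `s = 1 − 2·d_H/b`.

## Worked example

```python
import numpy as np
from fedsimhash import (
    CohortConfig, SitePartitionPlan, generate_cohort, partition_sites,
    build_domain_vocabulary, assemble_site, HashConfig, EvalConfig, run_experiment,
)
from fedsimhash.federation import FederationConfig, federated_fit
from fedsimhash.securesearch import Responder, encrypt_code, keygen, recover_hamming
from fedsimhash.hashcore import encode

# 150 synthetic patients, 3 sites of 50 — no real data leaves any "site"
cohort = generate_cohort(CohortConfig(n_patients=150, seed=0))
spec = build_domain_vocabulary(cohort)
parts = partition_sites(cohort, SitePartitionPlan(M=3, per_site_sizes=(50, 50, 50)), seed=0)
sites = [assemble_site(p, spec, gamma=0.01, target_code="d_TARGET", site_index=i)
         for i, p in enumerate(parts)]

cfg = HashConfig(seed=0, max_iter=30)          # b=(2,10,10,10,10,10), lambda=0.5, eta=1e-3
model, nodes, trace = federated_fit(sites, cfg, FederationConfig(M=3))
print(f"objective: {trace[0]:.1f} -> {trace[-1]:.1f} in {len(trace)-1} iterations")
print(f"code length: {model.total_bits} bits ({model.bits})")

report = run_experiment(sites, cfg, EvalConfig(system="federated", folds=5, repeats=3, seed=0),
                        kappa=3)
print(f"federated multi-hash kNN (kappa=3): AUC {report.auc_mean:.3f} (SD {report.auc_sd:.3f})")

keys = keygen(512, seed=0)                     # short key for the example; default is 2048
codes0 = encode(model, sites[0].P).codes
codes1 = encode(model, sites[1].P).codes
u = np.concatenate([codes0[t][:, 0] for t in model.spec.tags])
v = np.concatenate([codes1[t][:, 0] for t in model.spec.tags])
ct = Responder(keys.public).respond_distance(encrypt_code(u, keys.public), v)
print(f"encrypted hamming distance between first patients of sites 0 and 1: "
      f"{recover_hamming(ct, keys.private, 52)}/52 bits")
```

Output:

```
objective: -1234.1 -> -89076.5 in 30 iterations
code length: 52 bits ((2, 10, 10, 10, 10, 10))
federated multi-hash kNN (kappa=3): AUC 0.967 (SD 0.005)
encrypted hamming distance between first patients of sites 0 and 1: 27/52 bits
```

The objective trace is non-increasing by construction; the 52-bit code is
2 demographic bits plus 10 bits for each of five coded domains. The AUC
is the probability that a random positive patient receives a higher
κ-NN vote than a random negative, over repeated stratified CV. The last
line is the full encrypted protocol: the responding site computed over
ciphertexts only and returned a single encrypted value.

The same pipeline is scriptable from a shell:

```bash
fedsimhash generate --n-patients 375 --seed 0 --out cohort.jsonl
fedsimhash assemble --cohort cohort.jsonl --sites 3 --site-size 125 --out-dir work/
fedsimhash fit      --site-dir work/ --federated --seed 0 --out-dir work/model/
fedsimhash encode   --site-dir work/ --model-dir work/model/ --out-dir work/codes/
fedsimhash evaluate --site-dir work/ --system federated --kappa 3 --out report.json
```

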