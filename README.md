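# fedcaps

A desk-scale, fully testable federated pipeline for brain-tumor detection
on CT-like images.  Everything runs on one CPU in minutes, on synthetic
phantoms the package generates itself — no downloads, no GPU — while
keeping the real pipeline's moving parts intact and individually verified:

* **Phantom generator** — elliptical brain inside a bright skull ring,
  optional irregular tumor blob (three geometric "types"), Gaussian noise,
  and a deterministic monotone-remap pseudo-modality channel; per-client
  partitions emulating heterogeneous hospitals.
* **Preprocessing** — mutual-information rigid registration, morphological
  skull stripping, Perona–Malik anisotropic diffusion, min-max
  normalization, and an SSIM/PSNR quality gate.
* **Segmentation** — a residual/dense U-Net trained with soft Dice loss
  `L = 1 − 2Σpᵢgᵢ/(Σpᵢ² + Σgᵢ²)`, producing per-pixel tumor probabilities
  through a sigmoid head.
* **Features** — GLCM texture (contrast, energy, homogeneity, correlation
  over `P(i,j)`), first-order statistics (μ, SD, skewness, kurtosis with
  population normalization), pooled deep features, and weighted fusion.
* **HGBOA** — a hybrid Gorilla-Troops × Honey-Badger metaheuristic:
  follow-the-silverback moves `δ·rand·(|x − x_sb| + x)` with
  `δ = sin(2.5 − t/T)`, fight moves `x_sb + F·rand·α·(x_sb − x)` with
  `α = 2e^(−t/T)`, and a three-branch exploration rule — wrapped for
  feature selection with fitness
  `w·(1 − accuracy) + (1 − w)·(selected/total)` and the feature reduction
  rate `FRR = 100·(1 − selected/total)`.
* **Capsule classifier** — primary and digit capsules with the squashing
  nonlinearity `v = (‖s‖²/(1+‖s‖²))·s/‖s‖` and routing-by-agreement;
  capsule norms are per-class confidences.
* **Federated simulator** — FedAvg `w = Σ(nₖ/N)wₖ` over non-IID clients
  with dropout/poisoning injection and optional Gaussian-mechanism
  differential privacy; only weight vectors cross the client boundary.
* **Ledger** — an append-only SHA-256 hash chain of per-round global-model
  digests with a fixed validator set; any tampering is detectable.

The neural components are a compact pure-numpy layer stack with explicit
forward/backward passes, deterministic under a seed and verified against
numeric differentiation.

## Worked example

`examples/06_federated_with_ledger.py` trains five heterogeneous clients
(client 3 holds only glioma-like tumors) for eight rounds with 10% dropout
and 10% poisoning, then audits the ledger:

```
client-1: 16 samples, tumor share 0.50
...
round 0: accuracy=0.600
round 1: accuracy=0.850
round 2: accuracy=0.850 poisoned=['client-3']
round 3: accuracy=0.800 poisoned=['client-4']
round 4: accuracy=0.875 poisoned=['client-1', 'client-4']
...
round 7: accuracy=0.875
ledger verification: {'valid': True}
audit of round 7 against the final global weights: True
```

Each round the surviving clients' weight vectors are averaged by sample
count, the aggregate is SHA-256-digested into the hash chain, and held-out
accuracy is measured on phantoms no client ever sees.  The final audit
recomputes the digest of the returned weights and matches it against the
chain — the tamper-evidence the ledger exists for.

The other examples each demonstrate one capability (phantom generation,
preprocessing + registration, segmentation, feature selection, the capsule
classifier) and print what they compute:

```bash
python examples/04_select_features.py
# selected 15 of 50 features
# informative features recovered: 4/5 (indices [0, 2, 3, 4]), noise features kept: 11
# feature reduction rate: 70.0%
# cross-validated accuracy on the selected subset: 0.993
```

A thin CLI mirrors the library (`fedcaps simulate-data`, `preprocess`,
`select-features`, `verify-ledger`, `audit-round`, `evaluate`, `run-all`);
`fedcaps run-all --seed 1 --out demo` executes the whole chain from one
YAML config.

## Layout

```
src/fedcaps/        library (synthetic_data, preprocessing, segmentation,
                    features, hgboa, capsules, federated, ledger,
                    evaluation, experiments, pipeline, cli, nn/)
examples/           one narrative script per capability
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     models, defaults, design choices, limitations
```

Phantom results demonstrate that the machinery works and is reproducible;
they are not evidence of clinical-grade accuracy.  See `docs/methods.md`
for the models, parameter defaults and the honest list of what the
synthetic experiments do not show.
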