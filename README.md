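# veinverify

Palm-vein verification from near-infrared hand images: matched-filter
vessel enhancement, dual global/local feature extraction, locality
preserving projections, nearest-neighbour matching, and weighted-sum score
fusion with FAR/FRR/EER evaluation. The package targets researchers in
vascular biometrics who want a tested, fully reproducible reference
pipeline; because the palm-vein databases used in the literature are
license-gated, it ships a synthetic-image generator that emulates dark
curvilinear vessels with Gaussian cross-sections so every stage can be
exercised and benchmarked end to end.

## The method

**Enhancement.** Palm-vein cross-sections resemble inverted Gaussians, so
a bank of zero-sum matched filters

```
g_θ(x, y) = −exp(−x′² / σ²) − m,   |x′| ≤ 3σ, |y′| ≤ L/2
x′ = x cos θ + y sin θ,  y′ = −x sin θ + y cos θ
```

is applied at six orientations θ_j = jπ/6; `m` is the support mean of the
first term, making each kernel sum to zero (constant backgrounds give zero
response). The per-pixel maximum over orientations is the enhanced image.

**Global feature (WLPP).** Level-3 approximation (LL) coefficients of two
wavelets, db2 and sym2, each Z-normalized with enrollment statistics and
concatenated, then projected by LPP.

**Local feature (LBPV_LPP).** The local binary pattern code of a pixel is
`Σ_p s(g_p − g_c) 2^p` over P = 8 neighbours at radius R = 1; the LBPV
histogram accumulates the ring variance VAR_{P,R} into the bin of each
pixel's code. Three Z-normalized histograms (enhanced image, db2 LL,
sym2 LL) are concatenated and projected by LPP.

**LPP.** On a kNN neighbourhood graph with heat-kernel weights
`W_ij = exp(−‖x_i − x_j‖² / t)`, the projection directions solve
`X L Xᵀ a = λ X D Xᵀ a` with `D_ii = Σ_j W_ji` and `L = D − W` (PCA
pre-projection keeps the right-hand side nonsingular).

**Matching and fusion.** Test embeddings are compared to all enrolled
embeddings under Euclidean, Manhattan, cosine or correlation distance.
The two channel distance matrices are min-max normalized and fused as
`w·d₁ + (1−w)·d₂`, with `w` searched exhaustively on a 0.01 grid for the
smallest equal error rate (EER) — the crossing point of the false
acceptance and false rejection rate curves.

## Worked example

```python
from veinverify import SynthConfig, make_dataset, run_pipeline
from veinverify.evaluate import PipelineConfig

dataset = make_dataset(SynthConfig(seed=1))     # 50 subjects x 12 samples
report = run_pipeline(dataset, PipelineConfig())
row = report["experiments"]["full"]["per_metric"]["euclidean"]
print(f"WLPP EER      {row['wlpp_eer']:.4f}%")
print(f"LBPV_LPP EER  {row['lbpv_lpp_eer']:.4f}%")
print(f"fused EER     {row['fused_eer']:.4f}%  at w = {row['fusion_weight']:.2f}")
```

prints

```
WLPP EER      1.6667%
LBPV_LPP EER  39.2222%
fused EER     1.6667%  at w = 0.86
```

The global wavelet channel separates the 300 genuine from the 89 700
impostor comparisons almost perfectly (EER 1.67% under Euclidean distance,
0.06% under Manhattan); the local LBPV channel is much weaker on its own —
texture statistics of small noisy images discriminate poorly — and the
fused score is never worse than the better channel. Rank-1 identification
on this benchmark is 100%.

The same pipeline is available from the shell:

```
veinverify synth --out data/                 # generate a dataset
veinverify enhance --in data/ --out enh/     # matched-filter enhancement
veinverify run --data data/ --out report/    # full evaluation report
veinverify eval genuine.csv impostor.csv     # EER from score files
```

## Layout

- `veinverify.synthgen` — synthetic vein-image datasets with labelled
  enroll/test splits
- `veinverify.enhance` — zero-sum oriented matched-filter bank
- `veinverify.features_wavelet` — level-3 LL wavelet features, Z-norm
- `veinverify.features_lbpv` — LBP codes, ring variance, LBPV histograms
- `veinverify.lpp` — locality preserving projections
- `veinverify.matching` — distance matrices, nearest-neighbour identity
- `veinverify.evaluate` — FAR/FRR/EER, fusion search, end-to-end pipeline

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
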