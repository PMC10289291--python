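# lsmunet

Multi-regional lumbar skeletal-muscle segmentation and
cirrhotic-sarcopenia index analysis on L3-level abdominal CT.

## The problem

Sarcopenia — pathological loss of skeletal muscle — is routinely
diagnosed from abdominal CT via the **L3 skeletal-muscle index**
(L3SMI): the muscle cross-sectional area at the third lumbar vertebra
divided by squared body height, with sex-specific cut-offs of
50 cm²/m² (male) and 39 cm²/m² (female).  In cirrhotic patients with
severe ascites the abdominal wall is compressed and the total-muscle
measurement degrades, so it is useful to segment the L3 musculature
into four regions — **Rectus Abdominis** (anterior wall group),
**Right/Left Psoas**, **Paravertebral** — and analyse each region's
index (RAI, RPI, LPI, PI, and TPI = RPI + LPI) as a surrogate.

This package provides, for researchers in CT body-composition analysis:

* **LSMU-Net** — a hybrid 2.5D/3D residual U-Net.  The 8 L3-related
  axial slices are permuted into the batch axis of a 2-D residual
  encoder–decoder, while a 3-layer 3-D encoding branch with *texture
  attention enhancement* blocks (SE-style channel weights combined with
  a pixel weight `x(1−x)` that peaks at probability 0.5, i.e. on
  uncertain edges) injects volumetric context.  The fused feature holds
  152 channels = 32 (decoder) + 8 (projected skip) + 112 (3-D branch),
  followed by a 1×1 convolution onto the 5 classes.
* A composite loss `CE + Dice` with prior class weights
  `ω_c = 1 − N_c/(H·W·D) − 0.2·[c ∈ {1,4}]` that up-weight the scarce
  psoas regions.
* Evaluation metrics (DSC, Sensitivity, ASSD in millimetres) and a
  stratified cross-validation training harness (Adam, lr 0.001).
* A synthetic phantom generator producing L3-like slabs with
  ground-truth four-region labels, so the entire pipeline is testable
  without clinical data.
* The sarcopenia index pipeline: regional indices, L3SMI diagnosis,
  Pearson correlation tables and ROC/Youden cut-off derivation.

The implementation is pure scientific Python (numpy + autograd for the
differentiable network; no GPU framework required).

## Worked example: phantoms to sarcopenia indices

```python
from lsmunet.phantom import PhantomParams, generate_cohort
from lsmunet.indices import build_index_table

base = PhantomParams(grid_size=(8, 64, 64), spacing_mm=(5.0, 5.6, 5.6),
                     region_scale=(0.85,) * 4)
cases, manifest = generate_cohort(8, base_params=base, seed=42)
segs = {meta.patient_id: labels for _, labels, meta in cases}
table = build_index_table(segs, manifest)
print(table[["patient_id", "sex", "rai", "tpi", "l3smi", "diagnosis"]]
      .round(2).to_string(index=False))
```

prints

```
patient_id    sex   rai  tpi  l3smi      diagnosis
      p000 female 21.72 6.71  46.87 non-sarcopenia
      p001 female 21.41 6.78  41.32 non-sarcopenia
      p002 female 16.24 8.68  46.89 non-sarcopenia
      p003   male 11.53 7.05  35.74     sarcopenia
      p004   male 11.27 8.20  34.48     sarcopenia
      p005   male 20.37 7.74  44.48     sarcopenia
      p006   male 20.72 6.97  47.67     sarcopenia
      p007 female 17.80 8.22  41.23 non-sarcopenia
```

Each row is one synthetic patient: `rai`/`tpi` are the Rectus-Abdominis
and total-psoas indices (cm²/m², region area over the true L3 slices
divided by height²), `l3smi` the four-region total index, and
`diagnosis` applies the sex-specific L3SMI cut-off (male patients p003–
p006 fall below 50 cm²/m² and are flagged sarcopenic).

Training and segmentation run through the same library (or the CLI
below); a desk-scale study — 24 phantoms at 8×64×64, 3-fold stratified
cross-validation, 10 epochs, half-width network — reaches a mean
4-class test DSC of ≈ 0.85 and mean ASSD ≈ 1.8 mm (≈ 0.3 voxel) in a
few CPU-minutes; `scripts/acceptance.py` (below) reproduces this
end to end.

## Command-line interface

```bash
lsmunet simulate   --n 20 --out data/ --seed 7 [--config params.yaml]
lsmunet preprocess --in data/ --out prep/ [--slices 0:6]
lsmunet train      --data data/ --out runs/ --folds 5 --epochs 30 \
                   --ablation {full,no3d,noattn,nores,noweights,se}
lsmunet evaluate   --pred pred/ --gt data/ --out metrics.csv
lsmunet indices    --seg data/ --meta data/manifest.csv --out indices.csv
lsmunet cutoffs    --indices indices.csv --out cutoffs.csv
```

The `--ablation` switch maps to the internal architecture variants:
no 3-D branch, no attention, SE-only attention, no residual structure,
unweighted loss.

## Layout

| module | contents |
| --- | --- |
| `lsmunet.phantom` | synthetic L3 slab / cohort generator with ground truth |
| `lsmunet.ioprep` | `CTSlab`/`LabelVolume`, NIfTI I/O, normalization, depth padding |
| `lsmunet.network` | LSMU-Net, blocks, texture attention, config/ablations |
| `lsmunet.losses` | class weights, weighted CE + Dice |
| `lsmunet.metrics` | DSC / Sensitivity / ASSD, cohort aggregation |
| `lsmunet.training` | stratified splits, per-fold Adam training, selection |
| `lsmunet.indices` | regional indices, diagnosis, correlation, ROC cut-offs |
| `lsmunet.nn` | minimal autograd layer library (convs with custom VJPs, Adam) |

See `docs/methods.md` for the model details, parameter choices and
known limitations.
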