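# spinemorph

Vertebral morphometry and decision-level fusion for chronic vertebral
compression fracture (VCF) detection.

Chronic VCFs are usually screened on sagittal-reformatted CT by the Genant
semiquantitative method: the vertebral body height is measured at three
columns — anterior (Ha), middle (Hm) and posterior (Hp, the reference near
the pedicle) — and the **height loss ratio**

```
HLR = max(0, 1 − min(Ha, Hm) / Hp)
```

grades the body as normal (HLR < 20%), mild (20% ≤ HLR < 25%), moderate
(25% ≤ HLR < 40%) or severe (HLR ≥ 40%). The ratio has two well-known blind
spots: a body collapsed *uniformly* across all three columns keeps HLR ≈ 0,
and the same absolute height loss yields a smaller ratio on a taller body.
Contour-based fracture detectors see the cortical deformity the ratio
misses, so quantitative (HLR) and detector evidence can be fused per
vertebra:

| Method | Rule (positive call) |
|---|---|
| 1 — HLR only | HLR ≥ τ |
| 2 — detector only | confidence ≥ θ_pos |
| 3 — HLR + detector, positive override | HLR ≥ τ **or** confidence ≥ θ_pos |
| 4 — HLR + detector, negative override | HLR ≥ τ **and** confidence ≥ θ_neg |

Method 3's positives are a superset of Method 1's (sensitivity can only
rise), Method 4's a subset (specificity can only rise).

The package is aimed at researchers studying VCF decision pipelines without
access to clinical data: every stage runs on a built-in synthetic spine
phantom with exact per-vertebra ground truth, plus a mock detector whose
operating point is calibrated in closed form.

## What's inside

- `spinemorph.morphometry` — column-band height measurement from binary
  masks (endplate-leveling alignment), HLR, Genant grading.
- `spinemorph.contour` — contour bands (`dilate(mask) & ~mask`), the input
  representation for contour-based detectors.
- `spinemorph.detect_io` — YOLO-style detection records, IoU matching of
  boxes to vertebrae, per-vertebra confidence reduction.
- `spinemorph.fusion` — the four decision strategies with provenance and a
  fused score per method for ROC analysis.
- `spinemorph.metrics` — Dice/FND/FPD/IoU segmentation overlap,
  classification metrics with exact Clopper–Pearson 95% CIs, ROC/AUROC.
- `spinemorph.phantom` — the synthetic spine generator (wedge, biconcave
  and crush deformities; optional low-bone-density trabecular texture) and
  the calibrated mock detector.
- `spinemorph.cli` — a thin `spinemorph` command with `phantom`,
  `morphometry`, `contour`, `classify`, `evaluate` and `report`
  subcommands; `examples/` holds narrative scripts, one per capability.

## Worked example

```python
from spinemorph import (PhantomSpec, DeformityClass, VertebraMask,
                        analyze_mask, generate_spine)

spec = PhantomSpec(n_vertebrae=1, base_posterior_height_mm=15.0,
                   deformity_plan=((0, DeformityClass.WEDGE, 1/3),), seed=0)
labels, truth = generate_spine(spec)
record = analyze_mask(VertebraMask(labels == 1, truth.pixel_spacing_mm, "L1"))
print(f"{record.ha_mm:.0f} / {record.hm_mm:.0f} / {record.hp_mm:.0f} mm, "
      f"HLR {record.hlr:.1%}, grade {record.grade}")
```

prints

```
10 / 13 / 15 mm, HLR 33.3%, grade moderate
```

— a 5 mm anterior loss on a 15 mm body is a 33% ratio and a moderate VCF;
the same 5 mm on a 25 mm body would be 20% and grade normal. Running
`python examples/03_fusion_methods.py` shows the two fusion overrides in
action: a ratio-blind uniform collapse (HLR 10%, detector confidence 0.82)
is negative under Method 1 but positive under Method 3, while a
high-ratio vertebra with no supporting detection (HLR 32.05%, confidence 0)
is positive under Method 1 but negated by Method 4.

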