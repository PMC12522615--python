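# periopano

Automated periodontitis staging and grading from polygon-annotated
panoramic radiographs.

Periodontitis severity under the AAP/EFP 2017 classification is read off a
panoramic radiograph as **radiographic bone loss (RBL)**: for each tooth,
the distance from the cemento-enamel junction (CEJ) to the alveolar bone
crest (D1), over the distance from the CEJ to the root apex (D2),

    RBL(%) = D1 / D2 × 100

measured along the tooth's central axis. Per tooth, RBL < 15% is Stage I,
15–33% Stage II, > 33% Stage III–IV, and the most severe tooth sets the
patient stage. The progression **grade** comes from the bone-loss%/age
ratio (< 0.25 → A, 0.25–1.0 → B, > 1.0 → C), upgraded — never downgraded —
by smoking and diabetes (HbA1c) risk modifiers.

`periopano` implements everything downstream of segmentation: it consumes
LabelMe-style polygon annotations (one bone outline, two CEJ curves, up to
32 FDI-coded teeth), computes per-tooth axes from exact polygon moments,
measures RBL, applies the staging/grading rules, reproduces the
training-time augmentation and 75:15:10 dataset split, and evaluates
predicted against reference segmentations with seven pixel metrics and
image-level bootstrap 95% CIs. A synthetic panoramic-scene generator with
exact per-tooth bone-loss ground truth stands in for trained segmentation
networks, so the whole pipeline is testable without patient data. It is
aimed at researchers building or validating automated periodontal
assessment pipelines. See `docs/methods.md` for the model details.

## Worked example

```sh
periopano synth --n 2 --seed 7 --out demo          # scenes + ground truth
periopano measure --in-dir demo --out demo/measurements.csv
periopano diagnose --in-dir demo --age 44 --cigs-per-day 5
```

The `diagnose` step prints, for the first scene:

```
Periodontitis assessment (AAP 2017)
-----------------------------------
Patient: age 44, 5 cigarettes/day, no diabetes

Per-tooth radiographic bone loss:
  tooth 11: RBL  20.7%  -> Stage II
  tooth 12: RBL  52.6%  -> Stage III_IV
  tooth 13: RBL   6.2%  -> Stage I
  ...
  tooth 44: RBL  11.5%  -> Stage I

Patient stage: III_IV (worst tooth 21)
Bone loss / age ratio: 1.346 -> primary Grade C
Final grade: C
  - smoking < 10 cigarettes/day -> Grade B modifier
```

Tooth 21 has the worst measured bone loss (59.2% of its root length), so
the patient is Stage III–IV; 59.2 / 44 years ≈ 1.35 exceeds 1.0, giving
primary Grade C, which light smoking (a Grade B modifier) cannot raise
further. Every intermediate value is exposed so a clinician can override
borderline calls.

Other subcommands: `split` (75:15:10 manifest split), `convert` (LabelMe →
YOLO segmentation labels), `augment` (five annotation-consistent variants
per image), `evaluate` (metrics table with bootstrap CIs between a
prediction and a reference directory). Library functions mirror each
subcommand (`periopano.measure_scene`, `periopano.diagnose`,
`periopano.bootstrap_ci`, ...).

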