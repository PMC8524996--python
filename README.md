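# cadeval

Evaluation toolkit for multi-reader, multi-case (MRMC) studies of
lesion-detection CAD on chest radiographs.

## The problem

In a second-reader CAD workflow, a physician first reads a radiograph
unaided, then re-reads it with the CAD's suspected-nodule boxes visible and
may revise their call. Evaluating such a study requires four linked pieces
of machinery, which this package implements end to end:

1. **Localization correctness** — a reader's or the CAD's bounding box is
   correct when its intersection over union with the ground-truth nodule box
   satisfies IoU ≥ 0.3 (inclusive threshold; one-to-one matching when several
   boxes compete).
2. **Case-level classification** — a malignant image with a matching box is
   a TP case, without one an FN case; a normal image with no boxes is TN,
   with any box FP. Boxes not matched to a lesion are FP *lesions*, and
   mFPI = (total FP lesions) / (total images).
3. **Decision transitions** — per-reader 8-cell tables counting, for each
   discordant (CAD state, pre-CAD state) pair, how often the reader flipped
   the case state after seeing the CAD output (e.g. FN→TP given a correct
   CAD detection).
4. **Inference** — with-CAD vs without-CAD ratios of sensitivity,
   specificity, accuracy, PPV and NPV estimated by generalized estimating
   equations with a log link on the binary "correct" outcome
   (log μ = β₀ + β₁·arm, so exp(β₁) is a ratio of proportions), readers as
   clusters, independence or exchangeable working correlation, and robust
   sandwich variance A⁻¹BA⁻¹ for 95% Wald intervals at a two-sided 5% level.

Because per-reader clinical annotations are rarely public, the package ships
a calibrated synthetic-study generator (`cadeval.simulate`): a fixed
312-image cohort (59 malignant, 253 normal) with realistic nodule size /
location / vendor composition, a CAD operating at sensitivity 0.66 with
0.05 false positives per image, two groups of nine readers with baseline
sensitivities 0.47 and 0.51 at specificity 0.96, CAD-conditioned
decision-switching, and a shared per-nodule conspicuity term so that readers
and CAD miss the same hard cases. Every pipeline stage is testable without
any clinical data. See `docs/methods.md` for the model and its calibration.

## Worked example

```bash
cadeval simulate --seed 3 -o bundle
cadeval evaluate bundle -o reports
cadeval gee bundle --metric sensitivity
```

The `evaluate` step prints the pooled metric panel (readers micro-averaged
by summing confusion counts) with descriptive with/without ratios and the
standalone CAD column:

```
     metric  ..._without_cad  ..._with_cad  overall_without_cad  overall_with_cad  ratio  cad_standalone
sensitivity                                                0.48              0.59   1.24            0.68
specificity                                                0.95              0.96   1.00            0.94
   accuracy                                                0.86              0.89   1.03            0.89
        ppv                                                0.71              0.76   1.07            0.74
        npv                                                0.89              0.91   1.03            0.93
       mfpi                                                0.04              0.04           0.07
```

and the `gee` step prints the inferential version of the sensitivity row:

```
sensitivity: ratio 1.24 (95% CI 1.19-1.29), p < 0.001
```

Read: on this simulated study, referring to the CAD raised the readers'
pooled sensitivity from 0.48 to 0.59 — a 24% relative gain, statistically
significant — while specificity was essentially unchanged (ratio 1.00), the
CAD alone found 68% of the cancers, and readers placed ~0.04 false-positive
marks per image. `cadeval transitions` and `cadeval report` add the
decision-transition table and the full report directory. The same numbers
are available through the library API (`cadeval.evaluate_study`,
`cadeval.gee_frame`).

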