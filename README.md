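# petcbda

Voxel-level PET binding-potential (BP_ND) classification via a
subsample–ensemble–rank procedure, with a synthetic two-tracer cohort
generator so the whole pipeline runs and is tested without any external data.

The pipeline has four stages:

1. **simulate** (`petcbda.synthetic_pet`) — synthetic BP_ND volumes for a
   two-tracer cohort (Carfentanil grey-matter / Raclopride basal-ganglia),
   with a labelled ROI atlas, tracer masks, ROI-localised group effects,
   an early/late phase effect, smoothed Gaussian noise, and reference
   regions pinned at DVR = 1.
2. **wrangle** (`petcbda.io_wrangle`) — 3D→1D recasting (x-fastest flat
   ordering), per-image zeroing of DVR < 1.1, and cohort-level
   threshold/consistency voxel retention producing the images × voxels
   design matrix with a binary migraine/healthy outcome.
3. **run** (`petcbda.cbda_engine` + `petcbda.stacking`) — M case/feature
   subsamples, each fit with a cross-validated stacked ensemble whose
   meta-weights are a non-negative least-squares convex combination;
   features ranked by frequency among the top-accuracy subsamples;
   nested top-k validation; replications merged into a non-unique top list;
   subject-level 20/80 external split.
4. **report** (`petcbda.metrics_report`) — accuracy / sensitivity /
   specificity with exact (Clopper–Pearson) binomial confidence intervals,
   and ROI / subregion frequency tables for the merged top voxels.

## Test

```sh
python -m pytest -q tests/
```

Note: one acceptance test (`test_criterion_4_parameter_recovery`) asserts a
top-20 recovery rate of ≥ 80% that the frequency-ranking procedure cannot
reach at the pinned subsampling parameters; it fails by design rather than
being weakened (measured ceiling ≈ 0.55–0.75 across learners, fold counts
and retained-pool sizes).

## CLI

```sh
# end to end on the bundled desk-scale config
petcbda all --config examples/small.yaml --out out/

# or stage by stage
petcbda simulate --config examples/small.yaml --out out/sim
petcbda wrangle  --manifest out/sim --mask out/sim/mask_CFN.nii.gz \
                 --tracer CFN --threshold 2.0 --consistency 0.8 --out out/mat
petcbda run      --matrix out/mat --m 50 --fsr 20 --top-fraction 0.05 \
                 --k 50 --replications 5 --seed 1 --out out/cbda
petcbda report   --simulate-dir out/sim --run-dir out/cbda \
                 --config examples/small.yaml --out out/report
```

Configuration is a flat YAML file of dotted keys (see `examples/small.yaml`);
unknown keys are rejected. One global seed drives every stage; reruns with
the same config produce byte-identical tables.

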