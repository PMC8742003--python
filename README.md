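# datspect

Simulation study of how brain atrophy biases the specific binding ratio
(SBR) in dopamine-transporter SPECT ([123I]FP-CIT, "DaTscan").

The SBR is the standard semi-quantitative index for diagnosing
Parkinson's disease and dementia with Lewy bodies from DAT imaging
(Bolt/Southampton method):

    SBR = (Cs_total / Cr − Vs_VOI) / Vs

where `Cs_total` is the total count in a large striatal volume of interest
(VOI), `Cr` the mean count concentration of a nonspecific reference region,
`Vs_VOI` the VOI volume and `Vs` the assumed striatal volume. In atrophic
brains the enlarged CSF spaces (ventricles, sulci, fissures) contaminate
both regions with low counts; because the reference has no specific signal
to buffer it, `Cr` falls faster than `Cs` and the SBR is overestimated —
a confounder for exactly the elderly population the scan targets.

`datspect` implements the whole in-silico experiment as a reusable
pipeline, for imaging physicists and methodologists who want to probe SBR
analysis behaviour under controlled anatomy:

* `datspect.phantom` — labelled digital head phantoms: a deterministic
  synthetic generator (skull, folded parenchyma, ventricles, deep fissures,
  bilateral caudate + putamen) and a reader for the Zubal raw format;
* `datspect.atrophy` — graded atrophy by sub-voxel morphological erosion of
  the background (reference parenchyma) region, levels 1–3;
* `datspect.spect_sim` — simplified acquisition physics: attenuated
  parallel-beam projection, distance-dependent collimator response,
  effective scatter, Poisson counting (90 views, 128², 3.2 mm, 1.5e6 counts);
* `datspect.fbp_recon` — filtered back-projection with a Butterworth-
  windowed ramp (0.5 cycles/cm, order 8), no attenuation/scatter correction;
* `datspect.bolt_sbr` — Southampton analysis: fixed-volume striatal VOIs,
  threshold-grown reference region with inward margin and masked smoothing,
  per-side SBR averaged left/right;
* `datspect.experiment` — the factorial study (3 atrophy levels × uptake
  ratios 8:1/6:1/4:1 × 5 noise replicates) with rate-of-change tables,
  volume-trend fits, t-tests, CSV/JSON/figure reports.

See `docs/methods.md` for models, parameters and numerical choices.

## Worked example

```python
from datspect import (
    SyntheticHeadParams, generate_synthetic_head, extract_segments,
    bam_series, region_volume,
)

params = SyntheticHeadParams()          # 256 x 256 x 128 voxels, 1.1 x 1.1 x 1.4 mm
head = generate_synthetic_head(params)
segments = extract_segments(head)
print(f"background volume: {region_volume(segments.background, head.spacing):7.2f} cm3")
print(f"striatal volume:   {region_volume(segments.striatum, head.spacing):7.2f} cm3")

for model in bam_series(segments, levels=(1, 2, 3)):
    lvl = model.level
    print(f"level {lvl.level}: erosion {lvl.erosion_mm:.2f} mm -> "
          f"background {model.background_volume_cm3:.2f} cm3")
```

prints

```
background volume: 1393.55 cm3
striatal volume:     17.92 cm3
level 1: erosion 0.00 mm -> background 1393.55 cm3
level 2: erosion 0.55 mm -> background 1213.57 cm3
level 3: erosion 1.10 mm -> background 1175.14 cm3
```

The generator hit its anatomical targets (a 1387.41 cm3 whole-brain
reference region within 3 %, a 17.92 cm3 bilateral striatum), and each
atrophy level strips another sub-voxel shell off the background, enlarging
every CSF space. Running the full experiment on this series
(`datspect.experiment.run_grid`) then yields, per condition, the averaged
`Cs`, `Cr` and SBR; at seed 1 the level-3 rate-of-change against level 1 is
about 95–96 % for `Cs`, 92–94 % for `Cr`, and 106–109 % for the SBR — the
reference falls faster than the striatal VOI, so the SBR is overestimated
as atrophy progresses, at every uptake ratio.

A thin CLI wraps the same pipeline:

```sh
datspect phantom --out head.nii.gz          # generate + report volumes
datspect run --seed 1 --outdir results/run  # full experiment + report
datspect report --results results/run/results.csv --outdir results/again
```

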