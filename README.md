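# limbtherm

Bilateral infrared-thermography analysis of the acutely limping child's
lower limbs. When a child presents with an undifferentiated acute limp, the
unaffected leg provides an internal temperature reference: localised
pathology (a toddler's fracture, a soft-tissue injury, an irritable hip)
can show as a skin-surface "hotspot" relative to the mirror-image location
on the healthy side. `limbtherm` turns radiometric thermal video of both
legs into that comparison:

1. **Frame selection** — a recording's frames are scored by centred
   correlation with the pixelwise median frame (robust to a minority of
   motion-corrupted frames) and the best *K* (default 20) are kept.
2. **Paired-ROI averaging** — for each rectangular region of interest
   (hip, upper knee, knee, lower knee, ankle) on the affected leg, a
   size-identical ROI is mirrored onto the healthy leg about the image's
   vertical midline; pixel temperatures are averaged within each ROI per
   frame, then across the selected frames.
3. **Asymmetry statistic** — each ROI pair yields

   ```
   pct_diff = (T_affected − T_healthy) / T_affected × 100
   ```

   the affected-side elevation as a percentage of the affected-side mean
   temperature (°C).
4. **Cohort summaries** — after the study exclusion rules (symptom onset
   > 48 h, age ≥ 15 y, bilateral involvement, no diagnosis) and the mapping
   of each presenting-complaint region to its relevant ROIs, subgroups are
   summarised by the median (IQR) of per-subject affected and healthy
   means, with the group percentage difference computed from the two
   medians.

Because no patient recordings are publicly available, the package includes
a synthetic thermal-phantom simulator: two mirror-symmetric leg silhouettes
with a proximodistal temperature gradient, an optional Gaussian hotspot on
the affected leg, per-pixel sensor noise at the camera's NETD scale
(< 0.04 K), and a configurable fraction of motion-corrupted frames. Whole
cohorts with per-diagnosis hotspot magnitudes can be generated, pushed
through the full pipeline, and checked for parameter recovery.

## Worked example

Simulate the default 30-subject cohort (13 soft-tissue injuries, 9
irritable hips, 3 fractures, 4 other, 1 undiagnosed), measure every ROI
pair, and summarise by diagnosis group:

```python
import limbtherm as lt
from limbtherm.phantom import default_cohort_spec
from limbtherm.pipeline import subjects_frame
from limbtherm.summary import format_group_table

spec = default_cohort_spec(seed=7)
subjects = lt.generate_cohort(spec)
measurements = lt.measure_cohort(subjects, k=20)
groups = lt.group_summaries(measurements, subjects_frame([s.record for s in subjects]))
print(format_group_table(groups).head(8).to_string(index=False))
```

prints

```
   region   roi          position          diagnosis  n     affected      healthy pct_diff
    ankle ankle  anterior_sitting           fracture  2 33.28 (0.31) 31.36 (0.03)     5.76
    ankle ankle  anterior_sitting soft_tissue_injury  1  30.65 (n/a)  29.85 (n/a)     2.59
    ankle ankle anterior_standing           fracture  2 33.28 (0.31) 31.36 (0.03)     5.77
    ankle ankle anterior_standing soft_tissue_injury  1  30.65 (n/a)  29.85 (n/a)     2.59
hip_thigh   hip  anterior_sitting      irritable_hip  9 33.58 (0.68) 33.35 (0.67)     0.68
hip_thigh   hip  anterior_sitting soft_tissue_injury  3 34.35 (0.58) 33.88 (0.68)     1.35
hip_thigh   hip anterior_standing      irritable_hip  9 33.58 (0.68) 33.35 (0.67)     0.68
hip_thigh   hip anterior_standing soft_tissue_injury  3 34.35 (0.58) 33.88 (0.68)     1.35
```

Each row is one (complaint region, ROI, position, diagnosis) subgroup:
`affected`/`healthy` are the group median (IQR) mean ROI temperatures in
°C (IQR shown as `n/a` for single-subject groups), and `pct_diff` the
percentage difference of the two medians. The simulated fracture group
shows the largest asymmetry and the irritable-hip group the smallest,
mirroring the configured hotspot magnitudes.

The same run is available from the shell:

```sh
limbtherm run --out runs/demo --seed 7 --k 20
```

which writes the cohort tree, selected-frame indices, `measurements.tsv`,
`table_descriptive.tsv` and `table_groups.tsv` under `runs/demo/`, each
table headed by a comment line recording the seed. `simulate`,
`select-frames`, `measure` and `summarize` run the stages individually.

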