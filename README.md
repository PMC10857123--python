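# torsobaro

Posture analysis of dorsal torso pressure images from a capacitive sensor
mat. A recording (160 x 100 pressure frames at 10 Hz) is reduced to a
single medial frame, filtered, derotated and centred onto its mirror-symmetry
axis, masked to a torso-shaped region of interest, and parameterised:

- **Landmarks & distances** — torso start, thoracic maximum, thoracolumbar
  transition, lumbar minimum, lumbar end, sacral maximum along the sagittal
  mean-intensity profile; lateral reference positions at the waist notches;
  inclusive pixel distances (and mm at 5.1 mm/px).
- **Spinal shape** — frontal spine curve from the paraspinal intensity canal
  (FC1–FC7) and sagittal profile parameters (SC1–SC8).
- **Thoracic region** — shoulder contour (S0–S2), scapula position/intensity
  symmetry (SB0–SB5), torso symmetry (TS1–TS5).
- **Lumbar & sacral region** — waist contour symmetry (W0–W4), sacral slope
  (P1) and pelvic contour/intensity symmetry (P0, P2–P4).
- **Reliability** — ICC(1,1) with exact F-based 95% CI, mean within-subject
  SD and CV, and the standard classification bands, over a
  subjects x repetitions study.

A parametric phantom generator produces synthetic imprints (Gaussian bumps
on a torso-shaped support with a carved midline canal, waist concavities,
placement rotation/translation, sensor noise and fold artifacts) with full
ground truth, plus whole repeated-measurement studies.

## CLI

```bash
# generate a synthetic recording (CSV frames + JSON sidecar)
torsobaro phantom --spec spec.yaml --seed 1 --out rec/ --n-frames 10

# extract the posture parameter set from one recording directory
torsobaro analyze rec/ --config cfg.yaml --out params.json

# reliability table over a directory of recordings
# (one subdirectory per recording; subject/repetition labels in meta.json)
torsobaro study study_dir/ --out table.csv
```

Exit codes: 0 ok, 1 input error, 2 pipeline error.

Recordings are plain text: one `frame_NNN.csv` comma-separated matrix per
frame (rows cranial to caudal, columns subject-left to subject-right) and a
`meta.json` sidecar with `shape`, `pixel_mm`, `sample_rate_hz`,
`subject_id`, `repetition_id`.

## Library

```python
import torsobaro as tb

frame, truth = tb.generate_phantom(tb.PhantomSpec(rotation_deg=7), seed=0)
params = tb.analyze_frame(frame)          # ParameterSet
print(params.value("SC1"), params.transform)

recs = [rec for _, _, rec, _ in tb.generate_study(tb.StudySpec(n_subjects=10))]
table, _ = tb.analyze_study(recs)         # per-parameter reliability rows
```

## Conventions

Internally all indices are 0-based with the mirror axis at column 49.5
(between the two central columns); reported landmark positions use the
1-based convention of the clinical literature. Distances are inclusive
(`end - start + 1`). Max-ratio parameters are `max(x/y, y/x)` and equal 1
on a mirror-symmetric imprint.
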