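# cuporient

Measuring the 3D orientation of an acetabular cup — anatomic **inclination**
and **anteversion** — from 2D fluoroscopic images, together with everything
needed to validate that measurement against a 3D landmark reference method
on synthetic ground truth.

The package is aimed at researchers in hip-arthroplasty imaging who want to
study, stress-test or extend projected-ellipse cup measurement: it contains
the measurement method itself, the coordinate-measuring reference method, a
C-arm projection simulator with exact ground truth, and the agreement
statistics (ICC, bootstrap CIs, Bland–Altman) used to compare methods and
raters.

## The methods

**3D reference method** (`cuporient.geometry3d`). A pelvic anatomic frame is
built from digitized landmarks: the anterior axis is the normal of the
best-fit plane through points on the X-ray receiver, the lateral axis joins
the two teardrop landmarks, and cross products complete a right-handed
orthonormal (lateral, anterior, superior) frame. A best-fit 3D circle
through digitized rim points gives the cup-rim normal **n**, and the Murray
anatomic angles follow:

```
inclination  AI = arccos( n · superior )
anteversion  AV = angle in the transverse plane between lateral and the
                  projection of n onto that plane
```

**2D fluoroscopic method** (`cuporient.fluoro2d`). On a parallax-free AP
view the circular cup rim projects to an ellipse. Two images are digitized:
a full-pelvis view (inter-teardrop line + pelvic brim line) and a
cup-centered view (brim line + rim points). The brim line, visible in both,
transfers the medial–lateral axis into the cup view. With the radiographic
angles

```
RI = acute angle between the ellipse major axis and the medial–lateral axis
RA = asin(b / a)            (semi-minor over semi-major)
```

the orthographic projection model gives `tan RI = tan AI · cos AV` and
`sin RA = sin AI · sin AV`, inverted in closed form as

```
AV = atan( tan RA / sin RI )        AI = atan2( sin RI, cos RI · cos AV )
```

**Agreement statistics** (`cuporient.agreement`). ICC(2,1) — two-way random
effects, single measures, absolute agreement — with non-parametric
percentile bootstrap 95% CIs (resampling subjects), and Bland–Altman bias
with 95% limits of agreement (bias ± 1.96·sd of paired differences).

**Simulator** (`cuporient.simulator`). Regenerates the in vitro study
design: a 3 × 3 grid of target poses (20/40/60° inclination × 10/25/40°
anteversion, each realized within ±5° of target), three occlusion
conditions (cup only, 32 mm head, 36 mm head — modeled as reduced visible
rim arc and inflated rim digitization noise), two raters plus one repeat
session, with exact ground truth for every placement.

## Worked example

```python
import numpy as np
from cuporient import (CupPose, NoiseModel, simulate_radiograph_pair,
                       measure_cup)

pose = CupPose(inclination=40, anteversion=15, rim_radius=27.0,
               center=np.array([65.0, 0.0, 10.0]))
pair, truth = simulate_radiograph_pair(pose, noise=NoiseModel(), seed=7)
m = measure_cup(pair)
print(f"RI={m.radiographic.ri:.2f}  RA={m.radiographic.ra:.2f}")
print(f"inclination={m.pose.inclination:.2f}  anteversion={m.pose.anteversion:.2f}")
```

```
RI=39.40  RA=9.47
inclination=40.34  anteversion=14.72
```

The projected rim of a cup at (40°, 15°) makes a 39.3° major-axis angle
with the medial–lateral axis and has axis ratio sin 9.4°; inverting the
projection recovers the pose to a fraction of a degree under the default
0.5 mm digitization noise (with zero noise the recovery is exact to
1e-6 degrees).

The full experiment — simulate the 27-placement study, measure all 81
digitizations, run the interrater / intrarater / intermethod agreement
analyses — is one command:

```
cuporient validate --seed 42 --out run/
```

which prints a JSON summary and writes `agreement_report.csv` /
`agreement_report.txt`, e.g. (seed 42):

```
analysis    angle        condition         ICC   CI low  CI high     bias  LoA low LoA high
interrater  anteversion  cup_only        0.997    0.988    0.999    0.006   -2.058    2.070
...
intermethod inclination  cup_only        0.997    0.989    0.999   -0.659   -3.195    1.877
```

ICC > 0.75 is interpreted as excellent agreement; the limits of agreement
give the error envelope, in degrees, between two raters, two sessions, or
the 2D method and the 3D truth.

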