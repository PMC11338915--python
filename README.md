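# lungctr

Heart-segmentation-free cardiothoracic ratio (CTR) measurement from
lung-field masks of postero-anterior (P-A) chest radiographs.

## The problem

The CTR — the heart's maximum transverse diameter divided by the thoracic
maximum transverse diameter on a frontal chest film — is the standard
screening index for cardiac enlargement (values above ~0.5 are
suspicious). Automatic CTR tools usually need a heart segmentation, but
the cardiac silhouette is faint on P-A films and heart-segmentation
errors propagate straight into the ratio. The lung fields, by contrast,
segment reliably — and the heart *indents* the medial border of each
lung, so the cardiac silhouette's lateral extent is recoverable from the
lung masks alone.

`lungctr` consumes a binary lung-field mask (from any segmenter), keeps
the two largest connected components, traces each lung's boundary, and
locates the landmark points:

* **A1/A2** — lung apices; **B1/B2** — costophrenic angles,
* **C1/C2** — cardiophrenic angles: on the medial apex→costophrenic arc,
  the point farthest from the apex–costophrenic chord,
* **C1′/C2′** — superior termination of the cardiac-margin search,
* **D1** — right hemi-diaphragm top,
* **D2′/D3′** — thoracic inner-edge extremes,
* **E1/E2** — heart-border points: between the cardiophrenic angle and
  the termination point, the medial-edge point of maximum distance to the
  vertical midline O–O′ (a₀x + c₀ = 0).

The ratio is then

```
Δx1 = |x(E1) − x(E2)|        heart transverse diameter
Δx2 = |x(D2′) − x(D3′)|      thoracic transverse diameter
CTR = Δx1 / Δx2
```

Because all heart-border candidates lie strictly on one side of the
midline, the argmax is provably independent of the midline's exact
position — the midline is a reporting aid, not a tunable.

The package also ships a synthetic **phantom** generator (two lung-shaped
components with parametric cardiac indentations and raster-scan oracle
ground truth) so the entire pipeline is testable without clinical data,
and an **evaluation** module implementing the signed x/CTR error
arithmetic, their absolute-mean aggregation with deviation degree, and
the usual segmentation scores (accuracy, precision, recall, Dice, IoU,
HD95).

## Worked example

```sh
# make a phantom mask pair (512x512, 400 px thorax, 180 px heart):
lungctr phantom --n 1 --seed 1 --out-dir demo
# measure it:
lungctr compute demo/phantom_0001.png --out-dir demo
# render the annotated overlay:
lungctr overlay demo/phantom_0001.png demo/phantom_0001.json demo/overlay.png
```

`demo/phantom_0001.json` (abridged):

```json
{
  "D2p": [56, 244],
  "D3p": [456, 244],
  "E1":  [196, 356],
  "E2":  [376, 350],
  "dx1": 180,
  "dx2": 400,
  "ctr": 0.45
}
```

The thoracic inner edges sit at columns 56 and 456 (Δx2 = 400 px), the
cardiac indentation extremes at 196 and 376 (Δx1 = 180 px), giving
CTR = 180/400 = 0.45 — matching the phantom's constructed truth exactly.
The same `compute` subcommand takes a directory of per-frame masks and
emits one CSV row per frame, which is how a dynamic radiograph sequence
is processed.

Library use mirrors the CLI:

```python
from lungctr import read_mask, run_pipeline
kp, res = run_pipeline(read_mask("mask.png"))
print(kp.E1, kp.E2, res.ctr)
```

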