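"""Published benchmark tables for the aggregation arithmetic.

Reported key-point and CTR errors for four lung-field segmentation
backbones (SegNet, U-Net, ResU-Net++, AttU-Net) evaluated on two
chest-radiograph test sets: T1 (21 static postero-anterior frames) and
T2 (13 dynamic frames), plus a heart-segmentation-based CardioNet
baseline for the CTR comparison.  These are the leaf values from which
the per-model, per-set and grand aggregates are derived; they serve as
fixed inputs for validating :mod:`lungctr.evaluation`'s aggregation
arithmetic, not as outputs of this package.
"""

#: per-model, per-set mean |x|-errors (pixels) of the four CTR key points,
#: in the order (D2', D3', E1, E2)
KEYPOINT_MEAN_ERRORS = {
    ("SegNet", "T1"): (4.333, 5.857, 2.095, 3.000),
    ("U-Net", "T1"): (4.810, 6.048, 2.381, 3.476),
    ("ResU-Net++", "T1"): (4.476, 6.571, 2.095, 4.381),
    ("AttU-Net", "T1"): (4.762, 6.333, 2.143, 3.095),
    ("SegNet", "T2"): (3.615, 3.154, 1.923, 5.077),
    ("U-Net", "T2"): (3.308, 2.615, 3.154, 1.769),
    ("ResU-Net++", "T2"): (3.462, 2.385, 1.769, 3.308),
    ("AttU-Net", "T2"): (4.769, 2.846, 1.385, 6.846),
}

#: image width (pixels) of the benchmark radiographs
IMAGE_WIDTH = 512

#: mean CTR error per model and test set
CTR_MEAN_ERRORS = {
    "CardioNet": {"T1": 0.030, "T2": 0.031},
    "SegNet": {"T1": 0.022, "T2": 0.024},
    "U-Net": {"T1": 0.019, "T2": 0.002},
    "ResU-Net++": {"T1": 0.024, "T2": 0.012},
    "AttU-Net": {"T1": 0.018, "T2": 0.034},
}

#: published derived aggregates (for cross-checking the arithmetic)
PUBLISHED_MODEL_MEANS = {
    ("SegNet", "T1"): 3.8213,
    ("U-Net", "T1"): 4.1788,
    ("ResU-Net++", "T1"): 4.3808,
    ("AttU-Net", "T1"): 4.0833,
    ("SegNet", "T2"): 3.4423,
    ("U-Net", "T2"): 2.7115,
    ("ResU-Net++", "T2"): 2.7310,
    ("AttU-Net", "T2"): 3.9615,
}
PUBLISHED_SET_MEANS = {"T1": 4.1161, "T2": 3.2116}
PUBLISHED_GRAND_MEAN = 3.6639
PUBLISHED_DEVIATION_DEGREE = 0.72
PUBLISHED_COMBINED_CTR_ERRORS = {
    "CardioNet": 0.0305,
    "SegNet": 0.0230,
    "U-Net": 0.0105,
    "ResU-Net++": 0.0180,
    "AttU-Net": 0.0260,
}
#: per-set mean CTR error over the four lung-field models
PUBLISHED_SET_CTR_ERRORS = {"T1": 0.0208, "T2": 0.0180}
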