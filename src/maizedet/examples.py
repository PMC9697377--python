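"""Worked-example numbers for the metric aggregation utilities.

Per-class recall and average precision (percent, IoU > 0.5) reported on a
ten-class field corn-pest detection benchmark, for a plain feature-pyramid
(FPN) Faster R-CNN detector and for the deformable-backbone +
attention-pyramid detector this package implements.  Class keys are the
conventional abbreviations of the pests' scientific names.  The values are
published summary statistics, used here as inputs to demonstrate and test
the class-mean aggregation — not outputs of this package.
"""

from __future__ import annotations

__all__ = [
    "PEST_CLASSES",
    "FPN_RECALL",
    "FPN_AP",
    "OURS_RECALL",
    "OURS_AP",
    "TABLE1_INSTANCE_COUNTS",
    "TABLE1_RELATIVE_SIZES",
]

PEST_CLASSES = ["LLD", "OF", "AY", "SLF", "DP", "HA", "LS", "SEH", "RP", "SF"]

FPN_RECALL = {
    "LLD": 83.3, "OF": 60.6, "AY": 88.2, "SLF": 56.0, "DP": 48.8,
    "HA": 85.9, "LS": 100.0, "SEH": 60.0, "RP": 61.1, "SF": 69.4,
}
FPN_AP = {
    "LLD": 81.8, "OF": 56.4, "AY": 74.5, "SLF": 49.7, "DP": 45.5,
    "HA": 79.4, "LS": 100.0, "SEH": 54.5, "RP": 48.9, "SF": 61.4,
}
OURS_RECALL = {
    "LLD": 100.0, "OF": 69.0, "AY": 83.3, "SLF": 64.1, "DP": 46.3,
    "HA": 82.6, "LS": 100.0, "SEH": 58.8, "RP": 70.1, "SF": 69.1,
}
OURS_AP = {
    "LLD": 100.0, "OF": 60.0, "AY": 81.8, "SLF": 58.1, "DP": 44.0,
    "HA": 79.6, "LS": 100.0, "SEH": 53.6, "RP": 61.7, "SF": 62.5,
}

# Dataset-level statistics of the same benchmark: number of annotated
# instances per class (strongly imbalanced) and the mean bounding-box area
# relative to the whole image (spanning 0.007-0.306).  These parameterise
# the "imbalanced-table1" synthetic-scene preset.
TABLE1_INSTANCE_COUNTS = {
    "LLD": 55, "OF": 650, "AY": 174, "SLF": 7976, "DP": 849,
    "HA": 919, "LS": 140, "SEH": 141, "RP": 3875, "SF": 1970,
}
TABLE1_RELATIVE_SIZES = {
    "LLD": 0.192, "OF": 0.042, "AY": 0.153, "SLF": 0.306, "DP": 0.038,
    "HA": 0.094, "LS": 0.061, "SEH": 0.048, "RP": 0.007, "SF": 0.057,
}
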