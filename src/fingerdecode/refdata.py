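"""Per-subject summary tables reported by the original finger-movement EEG
study this pipeline reimplements.

The recordings themselves were never deposited; these printed per-subject
counts and pairwise decoding accuracies are the only quantitative anchors
available, and are used to check report arithmetic (column means and sample
standard deviations).
"""
from __future__ import annotations

import numpy as np

SUBJECTS = tuple(f"S{i}" for i in range(1, 11))

#: Experimental trial count per subject.
TRIALS = np.array([400, 400, 300, 400, 400, 400, 400, 400, 400, 400])

#: Total detected finger movements per subject.
MOVEMENTS = np.array([409, 485, 380, 435, 396, 396, 394, 394, 395, 394])

#: Detected movements per subject, per finger.
MOVEMENTS_BY_FINGER = {
    "thumb": np.array([93, 87, 74, 83, 68, 80, 79, 80, 80, 80]),
    "index": np.array([79, 97, 59, 77, 105, 79, 77, 80, 80, 79]),
    "middle": np.array([80, 117, 84, 86, 88, 80, 80, 79, 75, 80]),
    "ring": np.array([78, 97, 81, 80, 71, 79, 79, 75, 80, 75]),
    "little": np.array([79, 87, 82, 109, 64, 78, 79, 80, 80, 80]),
}

#: Reported pairwise decoding accuracies (%) per subject, ten finger pairs.
PAIRWISE_DA = {
    ("thumb", "index"): np.array(
        [68.89, 67.36, 75.12, 66.77, 63.06, 56.65, 71.50, 56.88, 99.16, 87.29]),
    ("thumb", "middle"): np.array(
        [69.82, 70.62, 75.73, 67.61, 76.40, 66.72, 73.65, 57.48, 98.77, 86.56]),
    ("thumb", "ring"): np.array(
        [83.21, 71.11, 87.57, 70.03, 72.00, 74.32, 58.20, 67.58, 99.09, 92.39]),
    ("thumb", "little"): np.array(
        [93.33, 63.03, 76.63, 82.86, 78.00, 95.87, 75.50, 59.13, 94.06, 63.25]),
    ("index", "middle"): np.array(
        [62.97, 72.74, 89.74, 57.53, 67.37, 62.00, 55.13, 65.13, 62.61, 96.29]),
    ("index", "ring"): np.array(
        [77.03, 69.95, 87.22, 63.84, 70.86, 63.40, 64.67, 71.29, 81.25, 85.33]),
    ("index", "little"): np.array(
        [94.50, 78.14, 80.04, 92.39, 76.12, 95.70, 57.97, 58.22, 83.06, 80.23]),
    ("middle", "ring"): np.array(
        [64.23, 63.14, 94.91, 64.67, 81.87, 55.16, 69.26, 62.03, 71.97, 84.23]),
    ("middle", "little"): np.array(
        [91.87, 68.23, 71.19, 94.13, 75.86, 96.97, 55.71, 62.32, 76.39, 86.78]),
    ("ring", "little"): np.array(
        [91.47, 71.92, 90.34, 86.95, 70.62, 97.77, 72.90, 67.97, 70.44, 81.74]),
}

#: Mean / Std rows as printed in the study's pairwise-accuracy table.
PAIRWISE_DA_MEAN_ROW = {
    ("thumb", "index"): 71.27, ("thumb", "middle"): 74.34,
    ("thumb", "ring"): 77.55, ("thumb", "little"): 78.16,
    ("index", "middle"): 69.15, ("index", "ring"): 73.48,
    ("index", "little"): 79.64, ("middle", "ring"): 71.15,
    ("middle", "little"): 77.94, ("ring", "little"): 80.21,
}
PAIRWISE_DA_STD_ROW = {
    ("thumb", "index"): 13.25, ("thumb", "middle"): 11.43,
    ("thumb", "ring"): 12.60, ("thumb", "little"): 13.51,
    ("index", "middle"): 13.57, ("index", "ring"): 8.81,
    ("index", "little"): 13.32, ("middle", "ring"): 12.24,
    ("middle", "little"): 14.07, ("ring", "little"): 10.78,
}

#: Printed per-subject column averages of the counts table.
COUNTS_AVERAGE_ROW = {
    "trials": 390.0, "movements": 407.8, "thumb": 80.4, "index": 81.2,
    "middle": 84.9, "ring": 79.5, "little": 81.8,
}
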