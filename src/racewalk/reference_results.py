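"""Published benchmark tables from the original eight-athlete study.

The study this package re-implements reported, for 108 classifier-dataset
combinations (9 classifiers x 4 body segments x 3 signal combinations), the
across-athlete mean overall accuracy; for the 30 models that passed the
accuracy criterion, the per-condition mean recalls; and for the 14 models
that also passed the recall criterion, the overall and per-condition mean
precisions.  Those printed values are embedded here so that the selection
funnel can be validated against its published pass/fail pattern (30 -> 14
-> 14 -> 7 survivors) without access to the undeposited athlete recordings.

Model names follow ``<classifier><combo><segment>`` with combos ``a``
(accelerations), ``w`` (angular velocities), ``aw`` (both); recalls and
precisions are NaN where the source table prints none (model already
rejected at an earlier stage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CLASSIFIER_NAMES

_SEGMENTS = ("PL", "TH", "SH", "FT")

# mean overall accuracy, rows (combo, segment), columns CLASSIFIER_NAMES
_ACCURACY = {
    ("a", "PL"): (0.70, 0.79, 0.76, 0.75, 0.73, 0.73, 0.73, 0.73, 0.75),
    ("a", "TH"): (0.75, 0.83, 0.83, 0.83, 0.77, 0.77, 0.76, 0.78, 0.79),
    ("a", "SH"): (0.77, 0.84, 0.90, 0.88, 0.80, 0.79, 0.79, 0.81, 0.79),
    ("a", "FT"): (0.74, 0.86, 0.87, 0.87, 0.83, 0.82, 0.79, 0.82, 0.86),
    ("w", "PL"): (0.66, 0.72, 0.76, 0.75, 0.73, 0.73, 0.72, 0.74, 0.69),
    ("w", "TH"): (0.70, 0.79, 0.79, 0.79, 0.75, 0.76, 0.73, 0.76, 0.72),
    ("w", "SH"): (0.69, 0.73, 0.74, 0.74, 0.73, 0.73, 0.70, 0.74, 0.71),
    ("w", "FT"): (0.71, 0.76, 0.75, 0.74, 0.73, 0.74, 0.70, 0.74, 0.73),
    ("aw", "PL"): (0.72, 0.80, 0.81, 0.79, 0.78, 0.77, 0.75, 0.78, 0.74),
    ("aw", "TH"): (0.76, 0.81, 0.82, 0.80, 0.79, 0.79, 0.74, 0.79, 0.76),
    ("aw", "SH"): (0.78, 0.80, 0.88, 0.87, 0.79, 0.79, 0.78, 0.81, 0.78),
    ("aw", "FT"): (0.71, 0.85, 0.83, 0.83, 0.79, 0.80, 0.75, 0.81, 0.80),
}

# per-condition mean recall (regular, LC, KB) for stage-1 survivors
_RECALL = {
    "SVMlawPL": (0.81, 0.82, 0.78),
    "SVMqawPL": (0.78, 0.84, 0.80),
    "SVMlaTH": (0.87, 0.90, 0.71),
    "SVMqaTH": (0.86, 0.90, 0.72),
    "SVMcaTH": (0.87, 0.89, 0.73),
    "SVMlawTH": (0.79, 0.91, 0.74),
    "SVMqawTH": (0.81, 0.90, 0.75),
    "SVMcawTH": (0.83, 0.83, 0.74),
    "SVMlaSH": (0.80, 0.85, 0.88),
    "SVMqaSH": (0.91, 0.89, 0.90),
    "SVMcaSH": (0.90, 0.88, 0.88),
    "kNNfaSH": (0.79, 0.81, 0.81),
    "kNNwaSH": (0.77, 0.82, 0.83),
    "SVMlawSH": (0.71, 0.85, 0.83),
    "SVMqawSH": (0.86, 0.90, 0.86),
    "SVMcawSH": (0.86, 0.89, 0.86),
    "kNNwawSH": (0.81, 0.81, 0.81),
    "SVMlaFT": (0.86, 0.85, 0.88),
    "SVMqaFT": (0.87, 0.87, 0.86),
    "SVMcaFT": (0.89, 0.87, 0.85),
    "kNNfaFT": (0.90, 0.75, 0.81),
    "kNNcoaFT": (0.85, 0.83, 0.80),
    "kNNwaFT": (0.89, 0.76, 0.82),
    "ANNaFT": (0.85, 0.85, 0.88),
    "SVMlawFT": (0.81, 0.84, 0.89),
    "SVMqawFT": (0.80, 0.87, 0.81),
    "SVMcawFT": (0.81, 0.84, 0.84),
    "kNNcoawFT": (0.82, 0.82, 0.76),
    "kNNwawFT": (0.85, 0.76, 0.82),
    "ANNawFT": (0.82, 0.83, 0.76),
}

# (overall, regular, LC, KB) mean precision for stage-2 survivors
_PRECISION = {
    "SVMlaSH": (0.85, 0.79, 0.93, 0.82),
    "SVMqaSH": (0.90, 0.89, 0.92, 0.89),
    "SVMcaSH": (0.90, 0.89, 0.92, 0.89),
    "SVMqawSH": (0.89, 0.88, 0.91, 0.90),
    "SVMcawSH": (0.89, 0.87, 0.91, 0.89),
    "kNNwawSH": (0.85, 0.79, 0.94, 0.82),
    "SVMlaFT": (0.88, 0.84, 0.95, 0.85),
    "SVMqaFT": (0.89, 0.86, 0.94, 0.87),
    "SVMcaFT": (0.89, 0.86, 0.93, 0.88),
    "kNNcoaFT": (0.85, 0.79, 0.89, 0.85),
    "ANNaFT": (0.83, 0.82, 0.79, 0.88),
    "SVMlawFT": (0.86, 0.79, 0.93, 0.84),
    "SVMqawFT": (0.83, 0.78, 0.88, 0.82),
    "SVMcawFT": (0.84, 0.79, 0.89, 0.84),
}


def published_results() -> pd.DataFrame:
    """The 108 published across-athlete mean metrics as one aggregated table.

    Layout matches :func:`racewalk.evaluate.aggregate` (metric means only),
    so it can be fed directly to :func:`racewalk.evaluate.selection_funnel`.
    """
    rows = []
    for (combo, segment), values in _ACCURACY.items():
        for classifier, acc in zip(CLASSIFIER_NAMES, values):
            name = f"{classifier}{combo}{segment}"
            recall = _RECALL.get(name, (np.nan,) * 3)
            precision = _PRECISION.get(name, (np.nan,) * 4)
            rows.append(
                {
                    "name": name,
                    "classifier": classifier,
                    "segment": segment,
                    "combo": combo,
                    "A": acc,
                    "R_regular": recall[0],
                    "R_LC": recall[1],
                    "R_KB": recall[2],
                    "P_overall": precision[0],
                    "P_regular": precision[1],
                    "P_LC": precision[2],
                    "P_KB": precision[3],
                }
            )
    return pd.DataFrame(rows).set_index("name")
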