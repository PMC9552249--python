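"""Published benchmark scores for the model-selection ranking procedure.

Eight candidate segmentation models, each optimized with a different
per-image selection metric (mIoU, mRecall, mPrecision, and five
precision/recall mixes), were scored on a validation set for intact-
eosinophil quantification (mean absolute count error) and slide-level
activity classification (percentages).  ``rank_models`` applied to this
table reproduces the published per-metric competition ranks and the
selection of the m(0.5P+0.5R) model as the best overall (final rank 1).
"""

from __future__ import annotations

import pandas as pd

#: columns: count_error (eosinophils), classification metrics (%)
MODEL_SELECTION_SCORES = pd.DataFrame(
    {
        "count_error": [0.669, 1.686, 1.561, 1.263, 0.651, 0.611, 0.907, 1.561],
        "accuracy": [98.42, 97.22, 94.94, 97.22, 98.23, 98.48, 98.42, 96.33],
        "f1": [96.09, 93.39, 85.82, 93.39, 95.72, 96.30, 96.04, 90.10],
        "fnr": [4.66, 3.42, 24.84, 3.42, 2.80, 3.11, 5.90, 18.01],
        "fpr": [0.79, 2.62, 0.00, 2.62, 1.51, 1.11, 0.48, 0.00],
        "tnr": [99.21, 97.38, 100.00, 97.38, 98.49, 98.89, 99.52, 100.00],
        "tpr": [95.34, 96.58, 75.16, 96.58, 97.20, 96.89, 94.10, 81.99],
    },
    index=pd.Index(
        ["miou", "mrecall", "mprecision", "m(0.3P+0.7R)",
         "m(0.4P+0.6R)", "m(0.5P+0.5R)", "m(0.6P+0.4R)", "m(0.7P+0.3R)"],
        name="model",
    ),
)

#: Published per-metric competition ranks for the same table.
PUBLISHED_RANKS = pd.DataFrame(
    {
        "rank_count_error": [3, 8, 6, 5, 2, 1, 4, 6],
        "rank_accuracy": [2, 5, 8, 5, 4, 1, 2, 7],
        "rank_f1": [2, 5, 8, 5, 4, 1, 3, 7],
        "rank_fnr": [5, 3, 8, 3, 1, 2, 6, 7],
        "rank_fpr": [4, 7, 1, 7, 6, 5, 3, 1],
        "rank_tnr": [4, 7, 1, 7, 6, 5, 3, 1],
        "rank_tpr": [5, 3, 8, 3, 1, 2, 6, 7],
        "mean_rank": [3.67, 5.00, 5.67, 5.00, 3.67, 2.67, 3.83, 5.00],
        "final_rank": [2, 5, 8, 5, 2, 1, 4, 5],
    },
    index=MODEL_SELECTION_SCORES.index,
)
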