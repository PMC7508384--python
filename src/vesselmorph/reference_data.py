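"""Published summary dimensions of the field-study vessels.

Means and coefficients of variation (percent, ``100 * SD / mean``) of the
final-vessel dimensions — height (cm), maximal diameter (cm) and exterior
surface area (cm^2) — across the five trials each of seven expert Indian
potters threw per traditional vessel type.  Four potters (GA, KA, BA, AR)
belong to a stick-wheel workshop ("PR") and three (KD, NA, YA) to a
kick-wheel workshop ("MK"); the money-bank was thrown by all seven, the
other types by one community each.

These printed summaries are the only machine-readable record of the study
assemblage and serve as inputs to the summary-statistic ANOVA
reconstructions; raw outlines were never deposited.
"""

from __future__ import annotations

import pandas as pd

MONEYBANK_POTTERS = ["GA", "KA", "BA", "AR", "KD", "NA", "YA"]
MONEYBANK_COMMUNITIES = ["PR", "PR", "PR", "PR", "MK", "MK", "MK"]
N_TRIALS = 5

# (mean, CV%) per potter, order as MONEYBANK_POTTERS
MONEYBANK_SUMMARY = {
    "height_cm": {
        "mean": [16.3, 18.4, 14.5, 15.2, 15.9, 12.9, 17.7],
        "cv": [5.4, 2.3, 5.9, 2.0, 2.7, 4.8, 3.1],
    },
    "max_diameter_cm": {
        "mean": [14.3, 13.9, 12.3, 12.8, 14.2, 11.1, 17.4],
        "cv": [4.2, 2.4, 8.7, 4.5, 3.4, 1.3, 2.1],
    },
    "esa_cm2": {
        "mean": [543.3, 596.9, 422.8, 466.9, 500.6, 330.9, 745.8],
        "cv": [8.3, 4.6, 13.2, 8.5, 5.5, 6.2, 4.1],
    },
}


def moneybank_summary_frame() -> pd.DataFrame:
    """Tidy frame: potter, community, metric, mean, cv."""
    rows = []
    for metric, d in MONEYBANK_SUMMARY.items():
        for potter, comm, m, cv in zip(
            MONEYBANK_POTTERS, MONEYBANK_COMMUNITIES, d["mean"], d["cv"]
        ):
            rows.append(
                {"potter_id": potter, "community": comm, "metric": metric,
                 "mean": m, "cv": cv}
            )
    return pd.DataFrame(rows)
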