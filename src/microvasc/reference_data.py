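"""Published pilot-study characterisation table for the worked example.

A pilot light-sheet study of upper-tract urothelial carcinoma characterised
four cleared, CD34-immunolabelled punch biopsies — two low-grade superficial
(TaG1) and two high-grade invasive (T3G3) tumors — by per-sample CD34
density heterogeneity features and mean vessel radius, alongside a normal
urothelium reference.  The raw image volumes were never deposited, so these
per-sample feature vectors are the only quantitative record; they serve
here as input fixtures for the summarise/aggregate/report path (group-mean
rows are recomputed from them, not copied).

Conventions matching this package: CD34 density on the percent scale,
variance on the density-as-fraction scale, skewness g1, excess (Fisher)
kurtosis, mean vessel radius in µm.
"""

from __future__ import annotations

import pandas as pd

from .density import (
    HeterogeneityFeatures,
    SampleSummary,
    SUMMARY_COLUMNS,
    summarize_sample,
)

__all__ = [
    "UTUC_PILOT_ROWS",
    "NORMAL_UROTHELIUM_ROW",
    "load_utuc_pilot_features",
    "utuc_pilot_summaries",
]

#: (sample_id, label, cd34_density, variance, kurtosis, skewness,
#:  vessel_radius_um, n_sections)
UTUC_PILOT_ROWS = [
    ("1", "TaG1", 25.67, 0.001135, 2.870, 1.657, 3.579, 483),
    ("2", "TaG1", 13.96, 0.02158, 4.865, 0.5529, 3.118, 377),
    ("3", "T3G3", 22.51, 0.006638, 16.09, 3.734, 3.197, 506),
    ("4", "T3G3", 21.65, 0.01466, 23.01, 3.845, 2.733, 414),
]

#: group-mean reference row for normal urothelium (no per-sample rows
#: were published for it); section count unknown
NORMAL_UROTHELIUM_ROW = (
    "mean_normal",
    "normal",
    17.27,
    0.000638,
    -0.2058,
    0.3302,
    2.998,
    None,
)


def load_utuc_pilot_features() -> pd.DataFrame:
    """The four per-sample rows as a DataFrame in canonical column order."""
    return pd.DataFrame(UTUC_PILOT_ROWS, columns=SUMMARY_COLUMNS)


def utuc_pilot_summaries() -> list[SampleSummary]:
    """The four per-sample rows as :class:`SampleSummary` objects."""
    out = []
    for sid, label, dens, var, kurt, skew, radius, n in UTUC_PILOT_ROWS:
        features = HeterogeneityFeatures(
            mean_density=dens,
            variance=var,
            kurtosis=kurt,
            skewness=skew,
            n_sections=n,
        )
        out.append(summarize_sample(sid, label, features, radius))
    return out
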