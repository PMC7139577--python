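"""Published reference counts for the four *Eucalyptus* species.

The bundled table holds the expert-annotation gene counts of the 11 ROS
families in *E. camaldulensis*, *E. globulus*, *E. grandis* and *E. gunnii*,
split by data source (genomic database vs targeted PCR detection) and
completeness status.  The per-organism source totals and automatic-
prediction counts below are the totals as printed in the published summary
table (the printed *E. gunnii* PCR total, 19, is one below the sum of its
per-family cells; the printed totals are what the derived percentages use).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

ORGANISMS = ("camaldulensis", "globulus", "grandis", "gunnii")

#: printed per-organism totals: organism -> (n_database, n_pcr)
PUBLISHED_SOURCE_TOTALS = {
    "camaldulensis": (214, 19),
    "globulus": (232, 4),
    "grandis": (229, 15),
    "gunnii": (209, 19),
}

#: automatically-predicted-correctly counts: organism -> (n_correct, n_total)
PUBLISHED_PREDICTION_COUNTS = {
    "camaldulensis": (82, 233),
    "grandis": (92, 244),
}

#: chromosomal placement of the E. grandis ROS network
PUBLISHED_CHROMOSOME_COUNTS = {
    "chr1_all": (61, 218),  # genes on chromosome 1 / placed network genes
    "chr4_all": (5, 218),
    "chr1_ciii_prx": (56, 174),  # CIII Prx on chromosome 1 / placed CIII Prx
}


def load_published_counts() -> pd.DataFrame:
    """The per-(organism, family, source) status counts as a DataFrame."""
    with resources.files("rosfam.data").joinpath(
        "eucalyptus_ros_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
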