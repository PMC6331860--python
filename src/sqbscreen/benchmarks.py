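"""Published benchmark recall tables, shipped as package data.

The virtual-screening literature evaluates similarity methods on MDDR
(three class sets: DS1 mixed, DS2 homogeneous, DS3 heterogeneous), MUV and
DUD, reporting per-activity-class recall percentages at top-1% and top-5%
cutoffs for the Tanimoto benchmark and the four quantum-projection
variants.  Those published class x method matrices are inputs here: the
aggregation (:func:`sqbscreen.screening.summarize_table`) and concordance
(:func:`sqbscreen.concordance.kendall_w`) statistics are recomputed from
them directly, since the underlying commercial/large-scale libraries and
the original random reference draws are not available.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["DATASETS", "CUTOFFS", "published_recall_table"]

DATASETS = ("mddr_ds1", "mddr_ds2", "mddr_ds3", "muv", "dud")
CUTOFFS = ("top1", "top5")


def published_recall_table(dataset: str, cutoff: str) -> pd.DataFrame:
    """Load one published recall matrix (rows: activity classes, cols: methods).

    ``dataset`` is one of ``mddr_ds1 | mddr_ds2 | mddr_ds3 | muv | dud``;
    ``cutoff`` is ``top1`` or ``top5``.  Values are recall percentages.
    """
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}; expected one of {DATASETS}")
    if cutoff not in CUTOFFS:
        raise ValueError(f"unknown cutoff {cutoff!r}; expected one of {CUTOFFS}")
    ref = resources.files("sqbscreen").joinpath(
        "data", f"recall_{dataset}_{cutoff}.csv"
    )
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, dtype={"activity_class": str})
    return table.set_index("activity_class")
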