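"""Published Yangtze River Delta comparison, shipped as a fixture.

The December-2020 study of medical-services price levels across Shanghai,
Jiangsu, Zhejiang and Anhui published its bilateral Fisher matrix (base-100,
row = compared region, column = reference region) but not the underlying
schedules, weights, Laspeyres/Paasche matrices or PLS values. The Fisher
matrix is packaged here so the multilateral stage can be re-run end to end
from printed inputs.

The spanning tree used by the study's MST comparison cannot be derived
without the unpublished PLS values; the tree shipped here is *inferred* —
it is the unique tree under which chained Fisher links reproduce the
published MST table — and is flagged as inferred wherever it is reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

YRD_REGIONS: tuple[str, ...] = ("Shanghai", "Jiangsu", "Zhejiang", "Anhui")

# base-100 entries as published; row j, column k = level of j with base k
_FISHER_100 = [
    [100.00, 136.58, 128.11, 123.66],
    [73.22, 100.00, 93.43, 88.27],
    [78.06, 107.03, 100.00, 97.85],
    [80.86, 113.29, 102.20, 100.00],
]

#: Inferred spanning tree consistent with the published MST table.
YRD_INFERRED_TREE: tuple[tuple[str, str], ...] = (
    ("Jiangsu", "Shanghai"),
    ("Shanghai", "Zhejiang"),
    ("Anhui", "Zhejiang"),
)


def yrd_fisher_matrix() -> pd.DataFrame:
    """Published bilateral Fisher matrix on ratio scale (base 1)."""
    df = pd.DataFrame(np.asarray(_FISHER_100) / 100.0,
                      index=list(YRD_REGIONS), columns=list(YRD_REGIONS))
    df.attrs["tree_provenance"] = "inferred"
    return df
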