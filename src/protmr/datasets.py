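"""Bundled example data.

``load_example_evidence`` returns the worked-example evidence table for a
published proteome-wide diabetic-retinopathy (DR) / proliferative-DR (PDR)
protein screen: one row per discovered protein-outcome pair with discovery
FDR, replication p, heterogeneity and pleiotropy p, colocalization PPH4,
and the published 95% log-odds CIs for the discovery and replication
effects.  It exercises the tier rule and the OR/CI arithmetic without any
external download.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd


def load_example_evidence() -> pd.DataFrame:
    path = files("protmr.data").joinpath("example_evidence.tsv")
    with path.open("rb") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
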