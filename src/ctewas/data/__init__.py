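"""Packaged reference tables.

Two small TSVs excerpt the top-ranked rows of the published meta-analysis
result tables of a sorted-neuron/glia cortex EWAS (aging and Braak-stage
analyses): per row the meta-analysis rank, the Fisher-combined p, the two
component p-values (neuron, glia), probe annotation and the published
FDR.  They serve as worked examples for validating the Fisher combination
and the BH adjustment (the published family size is 478,416 probes).
"""

from importlib import resources

import pandas as pd

#: number of CpGs in the published combined sorted dataset (the BH family size)
PUBLISHED_M = 478_416

_FILES = {
    "aging": "aging_meta_top25.tsv",
    "braak": "braak_meta_top.tsv",
}


def load_published_meta_table(which: str) -> pd.DataFrame:
    """Load a published top-ranked meta-analysis excerpt ("aging" or "braak")."""
    if which not in _FILES:
        raise KeyError(f"unknown table {which!r}; choose from {sorted(_FILES)}")
    with resources.files(__package__).joinpath(_FILES[which]).open() as fh:
        return pd.read_csv(fh, sep="\t")
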