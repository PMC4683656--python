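"""Packaged reference fixture: the published CRM2-TD marker table.

The table records, for each of the 40 B-centromere transposon-display
markers, its band name (selective-base triplets + gel size), its TD
pseudonym, presence/absence across the misdivision derivative series
(TB-9Sb, PI, Telo2-1(-), Iso3(-), Telo2-2(-)), and two independent
attributes: whether the marker interacts with CENH3 by ChIP-seq and
whether it was converted to a simple junction-junction PCR marker.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Derivative columns of the marker table, in main-pedigree-chain order.
DERIVATIVE_COLUMNS = ["TB9Sb", "PI", "Telo2_1", "Iso3", "Telo2_2"]

#: Parent of each derivative along the pedigree (root maps to None).
PEDIGREE = {
    "TB9Sb": None,
    "PI": "TB9Sb",
    "Telo2_1": "PI",
    "Iso3": "Telo2_1",
    "Telo2_2": "Iso3",
}


def load_marker_table() -> pd.DataFrame:
    """Load the packaged marker table as a DataFrame indexed by TD id.

    Columns: ``name`` (band name), the five derivative presence columns
    (bool), ``cenh3`` (bool, CENH3-interacting by ChIP-seq), ``pcr``
    (bool, converted to a junction-junction PCR marker).
    """
    ref = resources.files("bcenmap").joinpath("data/published_markers.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df = df.set_index("td")
    for col in DERIVATIVE_COLUMNS:
        df[col] = df[col] == "+"
    df["cenh3"] = df["cenh3"] == "1"
    df["pcr"] = df["pcr"] == "1"
    return df


def marker_sizes() -> list[int]:
    """Printed band sizes (bp) of the 40 markers, in TD order."""
    df = load_marker_table()
    return [int(name.rsplit("-", 1)[1]) for name in df["name"]]
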