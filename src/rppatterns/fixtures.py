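"""Packaged transcriptions of the study's published summary tables.

Five plain-text fixtures ship with the package:

* ``table1`` — the nine pairwise group comparison definitions;
* ``table2`` — published up/down response counts per region x fraction x
  comparison;
* ``table3`` — per-protein percent differences for the hippocampus nuclear
  (73 proteins) and cytosolic (66 proteins) fractions across seven
  comparisons, with a significance flag per cell (bold in the printed
  source); a ``note`` column marks cells whose printed flag is doubtful;
* ``table4`` / ``table5`` — the published compensation-pattern rosters
  (memantine not required / required), with the printed <=10% / >10%
  residual-band split.

Percent values are stored to one decimal place, the precision of the print.
Raw array data were never deposited, so these transcriptions are the only
real-data anchor the test-suite has; everything else is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_FILES = {
    "table1": ("table1_comparisons.tsv", "pairwise group comparison definitions"),
    "table2": ("table2_counts.tsv", "protein response counts per fraction and comparison"),
    "table3": ("table3_hippocampus.tsv", "per-protein percent differences, hippocampus"),
    "table4": ("table4_roster.tsv", "pattern roster: memantine not required"),
    "table5": ("table5_roster.tsv", "pattern roster: memantine required"),
}

#: Comparison columns of the table3 fixture, in printed order.
TABLE3_COMPARISONS = ("NL", "FL", "B", "RL", "B-tm", "B-tm-cs", "RL-NL")


@dataclass
class FixtureTable:
    table_id: str
    caption: str
    data: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("rppatterns.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])


def load_fixture(table_id: str) -> FixtureTable:
    """Load one packaged table by id (``table1`` .. ``table5``)."""
    if table_id not in _FILES:
        raise KeyError(f"unknown fixture {table_id!r}; available: {sorted(_FILES)}")
    fname, caption = _FILES[table_id]
    df = _read(fname)
    if table_id == "table3":
        df["note"] = df["note"].astype(str)
    return FixtureTable(table_id, caption, df)


def table3_results() -> pd.DataFrame:
    """The table3 fixture in long comparison-results form.

    Columns: protein, region, fraction, comparison, percent_difference,
    significant — directly consumable by the counts summariser and (for the
    five classifier comparisons) the pattern classifier.
    """
    wide = load_fixture("table3").data
    blocks = []
    for comp in TABLE3_COMPARISONS:
        sub = wide[["protein", "region", "fraction", comp, comp + "_sig"]].copy()
        sub.columns = ["protein", "region", "fraction", "percent_difference", "significant"]
        sub.insert(3, "comparison", comp)
        blocks.append(sub)
    out = pd.concat(blocks, ignore_index=True)
    out["significant"] = out["significant"].astype(bool)
    return out
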