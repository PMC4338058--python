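"""Bundled reference tables for *B. animalis* subsp. *lactis* KLDS 2.0603.

Two small published tables ship with the package:

* the catalogue of the 11 high-confidence intergenic sRNAs (as printed,
  including the two repeated rows, so that deduplication is exercisable);
* the 11 x 3 matrix of sRNA expression fold changes (treatment / control)
  under acid, bile-salt and simulated gastrointestinal (GIT) stress.

Coordinates in the catalogue are strand-polarized exactly as published:
minus-strand rows print start > end.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CONDITIONS = ("acid", "bile", "git")


def _read(name: str) -> pd.DataFrame:
    with resources.files("srna_seeker.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_published_catalogue(deduplicate: bool = False) -> pd.DataFrame:
    """The published KLDS 2.0603 sRNA catalogue (13 printed rows).

    With ``deduplicate=True``, repeated sRNA ids collapse to their first
    occurrence (11 distinct sRNAs).
    """
    df = _read("klds_srna_catalogue.tsv")
    if deduplicate:
        df = df.drop_duplicates(subset="srna_id", keep="first").reset_index(drop=True)
    return df


def load_published_fold_changes() -> pd.DataFrame:
    """The published sRNA fold-change matrix, indexed by sRNA id.

    Columns: acid, bile, git; values are treatment/control expression ratios.
    """
    return _read("klds_srna_fold_changes.tsv").set_index("srna_id")
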