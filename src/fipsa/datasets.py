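"""Bundled reference data used in worked examples and validation arithmetic."""

from __future__ import annotations

import pandas as pd

from .simeval import ConfusionTable

#: Columns: supervised super-population assignments (ADMIX = admixed
#: individuals that no discrete cluster can legitimately claim).
_VALIDATION_COLUMNS = ["ADMIX", "AFR", "AMR", "CSA", "EAS", "EUR", "MDE"]

#: Rows: the six clusters found at K = 6 on 162,997 SNVs from 11,257
#: deeply sequenced human genomes, in an independent validation of the
#: method against supervised ancestry labels.
_VALIDATION_ROWS = {
    1: ("EAS", [22, 0, 0, 0, 236, 0, 0]),
    2: ("AFR", [385, 1234, 0, 0, 0, 0, 0]),
    3: ("CSA", [104, 0, 0, 280, 0, 0, 0]),
    4: ("MDE", [777, 0, 0, 0, 0, 77, 265]),
    5: ("AMR", [435, 0, 132, 0, 0, 0, 0]),
    6: ("EUR", [662, 0, 0, 0, 0, 6648, 0]),
}


def validation_confusion() -> ConfusionTable:
    """Cluster x super-population confusion table of the 11,257-genome run.

    Six clusters against seven supervised classes; excluding the 2,385
    ADMIX individuals, 8,795 of the remaining 8,872 fall in the column
    matching their cluster's majority name (99.1% concordance).
    """
    counts = pd.DataFrame(
        {row_id: cells for row_id, (_, cells) in _VALIDATION_ROWS.items()},
        index=_VALIDATION_COLUMNS,
    ).T
    counts.index.name = "cluster"
    counts.columns.name = "reference"
    names = {row_id: name for row_id, (name, _) in _VALIDATION_ROWS.items()}
    return ConfusionTable(counts, names)
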