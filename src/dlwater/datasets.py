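"""Packaged reference dataset.

The reference cohort is the published measurement table for 34
Daasanach adults from three northern-Kenyan communities (El Bokoch,
Illeret, Roto): anthropometrics, the four DLW kinetic quantities, the
derived TEE / FFM / fat% / water turnover, and accelerometry means for
the ten participants who wore a device.  It is the package's golden
surface: the pipeline must reproduce the derived columns from the
kinetic ones.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_reference_table",
    "load_reference_cohort",
    "internally_consistent_rows",
]


def load_reference_table() -> pd.DataFrame:
    """Full reference table, printed derived columns included."""
    with resources.files("dlwater.data").joinpath("daasanach_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(participants, isotopes) input tables for :func:`~dlwater.core.process_cohort`."""
    t = load_reference_table()
    participants = t[["participant_id", "community", "age_y", "sex", "body_mass_kg"]]
    isotopes = t[["participant_id", "ND_mol", "NO_mol", "kD_perday", "kO_perday"]]
    return participants.copy(), isotopes.copy()


def internally_consistent_rows(table: pd.DataFrame, tol: float = 0.002) -> pd.Series:
    """Flag rows whose ND and NO columns agree with the printed ND/NO ratio.

    One Roto row fails this self-check (its dilution-space columns give
    a ratio of 1.026 against a printed 1.041), a transcription defect
    in the published table: its derived values cannot be reproduced
    from its kinetic columns and it is excluded from row-by-row golden
    comparisons.  All aggregate summaries keep every row.
    """
    ratio = table["ND_mol"] / table["NO_mol"]
    return pd.Series(
        np.abs(ratio - table["ND_NO_ratio"]) <= tol, index=table.index, name="consistent"
    )
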