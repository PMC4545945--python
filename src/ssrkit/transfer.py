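"""Cross-species marker transferability summaries.

Markers developed in one species are scored for PCR amplification in a
panel of related species. Cells are three-state — amplified / not
amplified / not tested — so partial panels are summarised correctly; a
plain 1/0 matrix is the two-state special case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class NoDataError(ValueError):
    """A species (or marker) has no tested cell."""


@dataclass
class AmplificationMatrix:
    """Markers x species amplification outcomes.

    ``data`` holds 1.0 (amplified), 0.0 (not amplified) or NaN (not
    tested), markers as index, species as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("need at least one marker and one species")
        values = self.data.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | (values == 0.0) | (values == 1.0))
        if bad.any():
            raise ValueError("cells must be 1 (amplified), 0 (not) or NA (not tested)")

    @property
    def markers(self) -> list[str]:
        return [str(m) for m in self.data.index]

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @classmethod
    def from_tsv(cls, path) -> "AmplificationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.apply(pd.to_numeric, errors="coerce"))

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "marker"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def species_transferability(matrix: AmplificationMatrix) -> pd.Series:
    """Per-species transferability: 100 x amplified / tested, as whole
    percent (round-half-even), matching the granularity these panels are
    reported at."""
    tested = matrix.data.notna().sum(axis=0)
    if (tested == 0).any():
        missing = [s for s, t in tested.items() if t == 0]
        raise NoDataError(f"species with no tested marker: {missing}")
    amplified = (matrix.data == 1.0).sum(axis=0)
    return (100.0 * amplified / tested).round(0).astype(int)


def marker_breadth(matrix: AmplificationMatrix) -> pd.Series:
    """Per-marker count of species with successful amplification
    (not_tested cells excluded)."""
    return (matrix.data == 1.0).sum(axis=1).astype(int)


def fully_transferable(matrix: AmplificationMatrix) -> list[str]:
    """Markers amplifying in every species in which they were tested
    (markers with no tested species do not qualify)."""
    out = []
    for marker, row in matrix.data.iterrows():
        tested = row.notna()
        if tested.any() and (row[tested] == 1.0).all():
            out.append(str(marker))
    return out
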