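"""The molecule band library: IR band centers of minor milk components.

The packaged library transcribes second-derivative band centers observed
for minor milk components in spiked milk samples (medium ``milk``) and in
aqueous solutions of the same molecules (medium ``aqueous``).  These are
the reference positions against which high-loading wavenumbers of a
treatment-significant principal component are assigned.  The library is a
plain CSV (``molecule, medium, center_cm1``) and user-extensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["BandLibrary", "load_band_library"]


@dataclass
class BandLibrary:
    """Molecule -> IR band centers, by medium (milk or aqueous)."""

    table: pd.DataFrame  # columns: molecule, medium, center_cm1

    def __post_init__(self):
        required = {"molecule", "medium", "center_cm1"}
        if not required.issubset(self.table.columns):
            raise InvalidArgumentError(f"band library needs columns {sorted(required)}")
        if self.table.empty:
            raise InvalidArgumentError("band library is empty")
        bad = ~self.table["center_cm1"].between(900, 3100)
        if bad.any():
            raise InvalidArgumentError(
                f"band centers outside 900-3100 cm^-1: "
                f"{self.table.loc[bad, 'center_cm1'].tolist()}"
            )

    @property
    def molecules(self) -> list[str]:
        return sorted(self.table["molecule"].unique())

    def centers(self, molecule: str, medium: str = "milk") -> list[float]:
        sel = self.table[(self.table["molecule"] == molecule)
                         & (self.table["medium"] == medium)]
        if sel.empty:
            raise InvalidArgumentError(f"no {medium} bands for {molecule!r}")
        return sorted(float(c) for c in sel["center_cm1"])


def load_band_library(path=None) -> BandLibrary:
    """Load the packaged band library, or a user CSV with the same columns."""
    if path is not None:
        return BandLibrary(pd.read_csv(path))
    with resources.files("milkmir.data").joinpath("band_library.csv").open() as fh:
        return BandLibrary(pd.read_csv(fh))
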