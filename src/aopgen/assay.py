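"""Radical-scavenging assay arithmetic.

Both the DPPH and the hydroxyl-radical assays report activity as the relative
absorbance drop against a negative control:

    scavenging % = (A0 - A1) / A0 * 100

where A0 is the absorbance of the negative control and A1 that of the
sample.  Readings with A1 > A0 (pro-oxidant direction) come back negative and
are returned as-is with a warning rather than clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class AssayMeasurement:
    a0: float  # negative-control absorbance (OD)
    a1: float  # sample absorbance (OD)
    assay: str = "DPPH"
    wavelength_note: str = ""

    def __post_init__(self):
        if self.a0 <= 0:
            raise ValueError("negative-control absorbance a0 must be positive")
        if self.a1 < 0:
            raise ValueError("sample absorbance a1 must be non-negative")


def scavenging_percent(m: AssayMeasurement | None = None, *, a0: float | None = None,
                       a1: float | None = None) -> float:
    """(A0 - A1) / A0 * 100; accepts a measurement or raw a0/a1 keywords."""
    if m is None:
        m = AssayMeasurement(a0=a0, a1=a1)
    pct = (m.a0 - m.a1) / m.a0 * 100.0
    if pct < 0:
        warnings.warn(
            f"{m.assay}: sample absorbance exceeds control (activity {pct:.1f}%)",
            stacklevel=2,
        )
    return pct


def annotate_csv(path_in: str, path_out: str) -> str:
    """Add a scavenging_percent column to a CSV with a0/a1 columns."""
    import pandas as pd

    df = pd.read_csv(path_in)
    for col in ("a0", "a1"):
        if col not in df.columns:
            raise ValueError(f"{path_in}: missing column {col!r}")
    df["scavenging_percent"] = [
        scavenging_percent(a0=row.a0, a1=row.a1) for row in df.itertuples()
    ]
    df.to_csv(path_out, index=False)
    return path_out
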