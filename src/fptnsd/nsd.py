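"""Net squared displacement (NSD) from two reference anchors.

NSD is the squared straight-line distance of every relocation from a fixed
reference fix, in km². Plateaus in the year-start series signal a shift to
a new range; the winter-start series (anchored once winter behavior has
been located) makes the return leg of a there-and-back migration explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .telemetry import CaribouYear

__all__ = ["DisplacementSeries", "compute_nsd"]


@dataclass
class DisplacementSeries:
    """Per-fix squared displacement (km²) from the two anchors."""

    nsd_year_start: np.ndarray
    nsd_winter_start: np.ndarray | None = None


def compute_nsd(cy: CaribouYear, reference_fix_index: int = 0) -> np.ndarray:
    """Squared planar distance (km²) of each fix from a reference fix."""
    df = cy.df
    if "x" not in df.columns:
        raise ValueError("projected coordinates required")
    n = len(df)
    if not (-n <= reference_fix_index < n):
        raise IndexError(f"reference index {reference_fix_index} out of range")
    x = df["x"].to_numpy(float) / 1000.0
    y = df["y"].to_numpy(float) / 1000.0
    return (x - x[reference_fix_index]) ** 2 + (y - y[reference_fix_index]) ** 2
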