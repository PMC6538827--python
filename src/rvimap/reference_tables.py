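"""Benchmark vulnerable-region tables for consistency reporting.

These are the published vulnerable-region sizes (RVI < 50 ms) and lowest RVI
values for the two reference infarct models of the original RVI mapping
characterization study — the idealized 2D sheet used in this package and an
anatomically realistic rabbit biventricular (BiV) scar model — indexed by
interpolation method and search radius R.  They serve as *inputs* to the
reporting path: the consistency report recomputes the minimum-interpolation
fold changes of the vulnerable region under radius enlargement from these
table values (8.6 for the 2D model, R 4 -> 16 mm; 6.7 for the BiV model,
R 2 -> 8 mm).

Absolute sizes and lowest values depend on the detailed biophysical ionic
model used in that study and are not reproduced by the phenomenological
simulator here; only the tabulated fold changes are consumed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "VULNERABLE_REGION_2D_MM2",
    "LOWEST_RVI_2D_MS",
    "VULNERABLE_REGION_BIV_MM3",
    "LOWEST_RVI_BIV_MS",
    "fold_change",
    "consistency_report",
]

#: Vulnerable-region size (mm^2), idealized 2D infarct model: (method, R_mm).
VULNERABLE_REGION_2D_MM2 = {
    ("nearest_neighbor", 4): 13.8, ("nearest_neighbor", 8): 28.0,
    ("nearest_neighbor", 16): 48.7,
    ("average", 4): 16.0, ("average", 8): 26.4, ("average", 16): 8.2,
    ("minimum", 4): 49.9, ("minimum", 8): 122.6, ("minimum", 16): 429.0,
}

#: Lowest RVI value (ms), idealized 2D infarct model.
LOWEST_RVI_2D_MS = {
    ("nearest_neighbor", 4): -99.0, ("nearest_neighbor", 8): -81.0,
    ("nearest_neighbor", 16): -60.0,
    ("average", 4): -96.0, ("average", 8): -58.0, ("average", 16): 15.0,
    ("minimum", 4): -128.0, ("minimum", 8): -128.0, ("minimum", 16): -128.0,
}

#: Vulnerable-region size (mm^3), rabbit BiV scar anatomy model.
VULNERABLE_REGION_BIV_MM3 = {
    ("nearest_neighbor", 2): 1.8, ("nearest_neighbor", 8): 5.0,
    ("average", 2): 1.3, ("average", 8): 0.1,
    ("minimum", 2): 13.4, ("minimum", 8): 89.2,
}

#: Lowest RVI value (ms), rabbit BiV scar anatomy model.
LOWEST_RVI_BIV_MS = {
    ("nearest_neighbor", 2): -41.0, ("nearest_neighbor", 8): -6.0,
    ("average", 2): -27.0, ("average", 8): 34.0,
    ("minimum", 2): -104.0, ("minimum", 8): -208.0,
}


def fold_change(table: dict, method: str, r_small: float, r_large: float) -> float:
    """Vulnerable-region fold change when the search radius is enlarged."""
    return table[(method, r_large)] / table[(method, r_small)]


def consistency_report() -> pd.DataFrame:
    """Minimum-interpolation radius-enlargement fold changes from the tables."""
    rows = [
        {"model": "2D_idealized", "method": "minimum", "r_small_mm": 4,
         "r_large_mm": 16,
         "fold_change": fold_change(VULNERABLE_REGION_2D_MM2, "minimum", 4, 16)},
        {"model": "BiV", "method": "minimum", "r_small_mm": 2, "r_large_mm": 8,
         "fold_change": fold_change(VULNERABLE_REGION_BIV_MM3, "minimum", 2, 8)},
    ]
    return pd.DataFrame(rows)
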