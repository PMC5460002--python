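"""Spring-table I/O.

Schema: one row per spring with columns
``spring_id,B_m,alpha_rad,A_m2,k0_m_per_y,n_e,R_mm_per_y`` and optional
``D_m`` and ``p`` columns overriding the aquifer-thickness and linearization
defaults. Recharge is carried in mm/y in files and converted at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("spring_id", "B_m", "alpha_rad", "A_m2",
                    "k0_m_per_y", "n_e", "R_mm_per_y")


def read_spring_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"spring table missing columns: {sorted(missing)}")
    return table


def write_spring_table(path, table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"spring table missing columns: {sorted(missing)}")
    table.to_csv(path, index=False)
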