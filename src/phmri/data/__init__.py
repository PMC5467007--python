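"""Bundled example data: published volume-of-activation comparison tables.

Each CSV holds the region rows of one treatment-vs-vehicle VOA comparison
(positive BOLD, three post-treatment windows) as reported in the emulated
four-arm awake-rat phMRI study: region name, representative activated-voxel
count per arm, and the Kruskal-Wallis p-value.  They serve as ready-made
inputs for :func:`phmri.roi_stats.significant_region_table`.
"""

from importlib import resources

import pandas as pd

__all__ = ["reported_voa_table", "REPORTED_COMPARISONS"]

REPORTED_COMPARISONS = ("idalopirdine", "donepezil", "combination")


def reported_voa_table(treatment: str) -> pd.DataFrame:
    """Published VOA comparison table for one treatment arm vs vehicle.

    Columns: ``window`` (15-25 / 25-35 / 35-45 min), ``region_name``,
    ``count_vehicle``, ``count_treatment``, ``p_value``.
    """
    if treatment not in REPORTED_COMPARISONS:
        raise KeyError(
            f"unknown comparison {treatment!r}; choose from {REPORTED_COMPARISONS}"
        )
    ref = resources.files(__package__) / "reported_voa" / f"{treatment}_vs_vehicle.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
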