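"""Segmented brain atlas: label volume, region table, and named circuits.

The atlas is a 3D integer label grid in which 0 marks background (non-brain)
and every positive integer is a region id listed in the region table.  Named
networks ("circuits", e.g. an extended-amygdala or septo-hippocampal system)
are sets of region ids and may overlap, since anatomical circuits share
structures.  Region ids are arbitrary positive integers and need not be
contiguous, so a subset of a larger parcellation can be used without
renumbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["Atlas", "load_atlas", "region_voxel_counts", "save_atlas"]


@dataclass(frozen=True)
class Atlas:
    """A validated label atlas.

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Region id per voxel; 0 is background.
    voxel_size : tuple of float
        Physical voxel edge lengths in mm, one per axis; strictly positive.
    regions : DataFrame with columns ``region_id``, ``region_name``
        One row per region; ids unique and positive.
    networks : mapping str -> frozenset of int
        Circuit definitions; every member id must appear in ``regions``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    regions: pd.DataFrame
    networks: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"label volume must be integer, got dtype {labels.dtype}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if list(self.regions.columns[:2]) != ["region_id", "region_name"]:
            raise ValueError("region table must have columns region_id, region_name")
        ids = self.regions["region_id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate region_id in region table")
        if np.any(ids <= 0):
            raise ValueError("region ids must be positive (0 is reserved for background)")
        table_ids = set(int(i) for i in ids)
        grid_ids = set(int(i) for i in np.unique(labels)) - {0}
        if grid_ids - table_ids:
            raise ValueError(
                f"unregistered region: labels {sorted(grid_ids - table_ids)} "
                "appear in the volume but not in the region table"
            )
        if table_ids - grid_ids:
            raise ValueError(
                f"unregistered region: ids {sorted(table_ids - grid_ids)} "
                "are listed in the region table but absent from the volume"
            )
        for name, members in self.networks.items():
            dangling = set(members) - table_ids
            if dangling:
                raise ValueError(
                    f"dangling network member: network {name!r} references "
                    f"region ids {sorted(dangling)} absent from the region table"
                )
        # normalise network values to frozensets of int
        object.__setattr__(
            self,
            "networks",
            {str(k): frozenset(int(i) for i in v) for k, v in self.networks.items()},
        )

    # -- convenience ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def region_ids(self) -> list[int]:
        return [int(i) for i in self.regions["region_id"]]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def brain_mask(self) -> np.ndarray:
        """Boolean mask of in-brain voxels (label > 0)."""
        return self.labels > 0

    def region_name(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["region_id"] == region_id, "region_name"]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row.iloc[0])

    def network_regions(self, network: str) -> frozenset[int]:
        if network not in self.networks:
            raise KeyError(f"unknown network {network!r}")
        return self.networks[network]


def region_voxel_counts(atlas: Atlas) -> dict[int, int]:
    """Number of voxels per region id; conserves the total nonzero voxel count."""
    ids, counts = np.unique(atlas.labels[atlas.labels > 0], return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def _nifti_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_atlas(
    atlas: Atlas,
    label_volume_path: str | Path,
    region_table_path: str | Path,
    network_table_path: str | Path | None = None,
) -> None:
    """Write the atlas as a NIfTI-1 label volume plus CSV tables.

    The network table has one row per (network, region) membership with
    header ``network_name,region_id``.
    """
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), _nifti_affine(atlas.voxel_size))
    nib.save(img, str(label_volume_path))
    atlas.regions.to_csv(region_table_path, index=False)
    if network_table_path is not None:
        rows = [
            {"network_name": name, "region_id": rid}
            for name, members in atlas.networks.items()
            for rid in sorted(members)
        ]
        pd.DataFrame(rows, columns=["network_name", "region_id"]).to_csv(
            network_table_path, index=False
        )


def load_atlas(
    label_volume_path: str | Path,
    region_table_path: str | Path,
    network_table_path: str | Path | None = None,
) -> Atlas:
    """Load and validate an atlas from a NIfTI label volume and CSV tables.

    Raises
    ------
    ValueError
        "unregistered region" if grid labels and region table disagree;
        "dangling network member" if a network references an unknown region.
    """
    img = nib.load(str(label_volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError("label volume contains non-integer values")
        data = rounded.astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    regions = pd.read_csv(region_table_path)
    networks: dict[str, frozenset[int]] = {}
    if network_table_path is not None:
        net = pd.read_csv(network_table_path)
        if not net.empty:
            networks = {
                str(name): frozenset(int(i) for i in grp["region_id"])
                for name, grp in net.groupby("network_name")
            }
    return Atlas(labels=data, voxel_size=voxel_size, regions=regions, networks=networks)
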