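"""Affine resampling into atlas space and label propagation.

Transform *estimation* is out of scope by design — in the emulated workflow
the affine bringing a subject into atlas space comes from an interactive
alignment and is supplied by the user (here, as a 9-parameter file).  This
module only applies such a transform and propagates atlas labels onto the
resampled grid.  The transform is translation + rotation + anisotropic
scaling; rotations are applied in x -> y -> z order, right-handed, about
the volume centre, and functional data are resampled with nearest-neighbour
interpolation by default (trilinear by flag) so intensities are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import Atlas
from .session import BoldSession

__all__ = ["AffineTransform", "apply_affine", "propagate_labels"]


@dataclass(frozen=True)
class AffineTransform:
    """9-parameter affine: translation (mm), rotation (degrees), scale.

    Rotations are about the volume centre, applied in x -> y -> z axis
    order (right-handed); scaling is per-axis and strictly positive.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scale factors must be positive, got {self.scale}")

    @property
    def is_identity(self) -> bool:
        return (
            self.translation == (0.0, 0.0, 0.0)
            and self.rotation_deg == (0.0, 0.0, 0.0)
            and self.scale == (1.0, 1.0, 1.0)
        )

    def matrix_mm(self) -> np.ndarray:
        """4x4 homogeneous matrix in physical (mm) coordinates, centre-free."""
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        Rx = np.array(
            [[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]]
        )
        Ry = np.array(
            [[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]]
        )
        Rz = np.array(
            [[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]]
        )
        R = Rz @ Ry @ Rx
        S = np.diag(self.scale)
        M = np.eye(4)
        M[:3, :3] = R @ S
        M[:3, 3] = self.translation
        return M

    def matrix_index(
        self, shape: tuple[int, int, int], voxel_size: tuple[float, float, float]
    ) -> np.ndarray:
        """4x4 matrix acting on 0-based voxel indices for a given grid.

        Physical coordinates are centred on the volume: the rotation/scale
        pivot is the grid centre ( (n-1)/2 per axis ).
        """
        V = np.diag([*voxel_size, 1.0])
        centre_mm = np.array(
            [(s - 1) / 2.0 * v for s, v in zip(shape, voxel_size)] + [0.0]
        )
        Tc = np.eye(4)
        Tc[:3, 3] = centre_mm[:3]
        Tc_inv = np.eye(4)
        Tc_inv[:3, 3] = -centre_mm[:3]
        P = Tc @ self.matrix_mm() @ Tc_inv
        A = np.linalg.inv(V) @ P @ V
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise ValueError("affine transform is not invertible")
        return A

    # -- file format ---------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                dict(
                    zip(
                        ["tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz"],
                        [*self.translation, *self.rotation_deg, *self.scale],
                    )
                )
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AffineTransform":
        row = pd.read_csv(path).iloc[0]
        return cls(
            translation=(float(row.tx), float(row.ty), float(row.tz)),
            rotation_deg=(float(row.rx), float(row.ry), float(row.rz)),
            scale=(float(row.sx), float(row.sy), float(row.sz)),
        )


def apply_affine(
    session: BoldSession, xf: AffineTransform, trilinear: bool = False
) -> BoldSession:
    """Resample each acquisition volume through the affine transform.

    The transform maps session coordinates into atlas coordinates; each
    output voxel is pulled from the inverse-mapped input location with
    nearest-neighbour (default) or trilinear interpolation.  Voxels mapped
    from outside the input grid become 0 (background).  The identity
    transform returns the session unchanged, bit-exactly.
    """
    if xf.is_identity:
        return session
    A = xf.matrix_index(session.grid_shape, session.voxel_size)
    A_inv = np.linalg.inv(A)
    # snap inversion round-off so exact voxel-aligned transforms (integer
    # translations, quarter turns) index the grid exactly under NN resampling
    near_int = np.abs(A_inv - np.rint(A_inv)) < 1e-9
    A_inv[near_int] = np.rint(A_inv[near_int])
    order = 1 if trilinear else 0
    out = np.empty_like(session.data)
    for t in range(session.n_acquisitions):
        out[..., t] = ndimage.affine_transform(
            session.data[..., t],
            matrix=A_inv[:3, :3],
            offset=A_inv[:3, 3],
            order=order,
            mode="constant",
            cval=0.0,
        )
    return session.with_data(out)


def propagate_labels(session: BoldSession, atlas: Atlas) -> np.ndarray:
    """Per-voxel region-id grid for a session already in atlas space.

    One-to-one correspondence with atlas voxels: the session grid must
    match the atlas grid exactly; every session voxel receives exactly one
    label (possibly 0 = background).
    """
    if session.grid_shape != atlas.shape:
        raise ValueError(
            f"session grid {session.grid_shape} does not match atlas grid {atlas.shape}"
        )
    return atlas.labels.copy()
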