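"""Rigid-body pose handling for pelvic and caudal lumbar gait kinematics.

Each bone's pose is six numbers: three rotations in degrees (rx axial, about
the craniocaudal axis; ry lateral, about the ventrodorsal axis; rz sagittal,
about the laterolateral axis) and three translations in centimetres (tx
craniocaudal, ty ventrodorsal, tz laterolateral).  Vertebral motion is
expressed relative to the adjoining caudal bone: L6 in the frame of L7, L7 in
the frame of the sacrum/pelvis (the sacrum is treated as rigidly attached to
the pelvis, so the pelvis carries it), and the pelvis in the world (treadmill)
frame.

Euler convention: intrinsic rz -> ry -> rx (sagittal, then lateral, then
axial).  The rig that produced the original recordings does not document its
order; at the sub-15-degree amplitudes seen in symmetrical gaits the choice
only matters at second order (see docs/methods.md), so it is fixed here and
centralised in :data:`EULER_ORDER`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

#: Bones handled by the pipeline, cranial to caudal reading order.
BONES = ("pelvis", "L7", "L6")

#: Caudal neighbor used as the reference frame for each vertebra.
CAUDAL_NEIGHBOR = {"L7": "pelvis", "L6": "L7"}

ROTATION_DOFS = ("rx", "ry", "rz")
TRANSLATION_DOFS = ("tx", "ty", "tz")
DOFS = ROTATION_DOFS + TRANSLATION_DOFS

#: Intrinsic Euler sequence (scipy convention: uppercase = intrinsic),
#: applied to the angle triple (rz, ry, rx).
EULER_ORDER = "ZYX"

#: |ry| above this is treated as gimbal-degenerate and rejected.  The gaits
#: analysed here stay below ~15 deg peak-to-peak, two orders of magnitude away.
GIMBAL_LIMIT_DEG = 89.0

#: Rotations beyond this are flagged as outside the physiological range.
PHYSIOLOGICAL_LIMIT_DEG = 45.0

_ORTHONORMAL_TOL = 1e-9


class InvalidPoseError(ValueError):
    """A pose contained non-finite or out-of-range components."""


class DegenerateOrientationError(ValueError):
    """Orientation too close to the gimbal singularity of the Euler chart."""


class AlignmentError(ValueError):
    """Trajectories that should share a frame grid do not."""


@dataclass(frozen=True)
class Pose6DOF:
    """One bone's pose at one instant.

    Rotations in degrees, reported in (-180, 180]; translations in cm.
    """

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.rx, self.ry, self.rz, self.tx, self.ty, self.tz)
        if not np.all(np.isfinite(vals)):
            raise InvalidPoseError(f"non-finite pose components: {vals}")
        for name in ROTATION_DOFS:
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise InvalidPoseError(
                    f"{name}={a} deg outside the reporting range (-180, 180]"
                )

    @property
    def exceeds_physiological_range(self) -> bool:
        """True when any rotation exceeds 45 deg (far beyond gait amplitudes)."""
        return any(
            abs(getattr(self, name)) > PHYSIOLOGICAL_LIMIT_DEG
            for name in ROTATION_DOFS
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.rx, self.ry, self.rz, self.tx, self.ty, self.tz], dtype=float
        )

    @classmethod
    def from_array(cls, a) -> "Pose6DOF":
        rx, ry, rz, tx, ty, tz = (float(v) for v in a)
        return cls(rx=rx, ry=ry, rz=rz, tx=tx, ty=ty, tz=tz)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation matrix (orthonormal, det +1) plus translation vector in cm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation matrix determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply *other* first, then *self*)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def _rotation_from_angles(rx, ry, rz) -> Rotation:
    """Batchable intrinsic rz->ry->rx rotation from degree angles."""
    angles = np.stack(
        [np.asarray(rz, float), np.asarray(ry, float), np.asarray(rx, float)],
        axis=-1,
    )
    return Rotation.from_euler(EULER_ORDER, angles, degrees=True)


def pose_to_transform(pose: Pose6DOF) -> RigidTransform:
    """Build the rigid transform for a pose (intrinsic rz->ry->rx)."""
    R = _rotation_from_angles(pose.rx, pose.ry, pose.rz).as_matrix()
    return RigidTransform(R, np.array([pose.tx, pose.ty, pose.tz]))


def transform_to_pose(transform: RigidTransform) -> Pose6DOF:
    """Extract the Euler-angle pose; rejects gimbal-proximal orientations."""
    rz, ry, rx = Rotation.from_matrix(transform.rotation).as_euler(
        EULER_ORDER, degrees=True
    )
    if abs(ry) >= GIMBAL_LIMIT_DEG:
        raise DegenerateOrientationError(
            f"|ry| = {abs(ry):.2f} deg is within "
            f"{90 - GIMBAL_LIMIT_DEG:.1f} deg of the gimbal singularity"
        )
    tx, ty, tz = transform.translation
    return Pose6DOF(rx=float(rx), ry=float(ry), rz=float(rz),
                    tx=float(tx), ty=float(ty), tz=float(tz))


def relative_pose(bone_world: Pose6DOF, caudal_neighbor_world: Pose6DOF) -> Pose6DOF:
    """Pose of a bone expressed in its caudal neighbor's frame.

    Equivalent to ``transform_to_pose(inverse(T_neighbor) ∘ T_bone)``.
    ``relative_pose(a, a)`` is the zero pose for any valid ``a``.
    """
    Tb = pose_to_transform(bone_world)
    Tn = pose_to_transform(caudal_neighbor_world)
    return transform_to_pose(Tn.inverse().compose(Tb))


def compose_pose(neighbor_world: Pose6DOF, relative: Pose6DOF) -> Pose6DOF:
    """Inverse of :func:`relative_pose`: world pose from neighbor + offset."""
    Tn = pose_to_transform(neighbor_world)
    Tr = pose_to_transform(relative)
    return transform_to_pose(Tn.compose(Tr))


@dataclass
class BoneChain:
    """World-frame pose trajectories of pelvis (carrying the sacrum), L7, L6.

    ``poses`` maps bone name to a DataFrame with a ``time_s`` column plus the
    six DOF columns; all bones must share the same frame grid.
    """

    frame_rate: float
    poses: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        unknown = set(self.poses) - set(BONES)
        if unknown:
            raise AlignmentError(f"unknown bones: {sorted(unknown)}")
        lengths = {b: len(df) for b, df in self.poses.items()}
        if len(set(lengths.values())) > 1:
            raise AlignmentError(f"bones differ in frame count: {lengths}")
        times = None
        for bone, df in self.poses.items():
            missing = [c for c in ("time_s", *DOFS) if c not in df.columns]
            if missing:
                raise AlignmentError(f"{bone}: missing columns {missing}")
            t = df["time_s"].to_numpy()
            if times is None:
                times = t
            elif not np.allclose(t, times, atol=1e-9):
                raise AlignmentError(f"{bone}: time grid differs from other bones")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.poses.values()))) if self.poses else 0

    @property
    def time_s(self) -> np.ndarray:
        return next(iter(self.poses.values()))["time_s"].to_numpy()


def _relative_trajectory(bone_df: pd.DataFrame, ref_df: pd.DataFrame) -> pd.DataFrame:
    """Frame-wise relative pose of one trajectory w.r.t. another (vectorised)."""
    Rb = _rotation_from_angles(
        bone_df["rx"].to_numpy(), bone_df["ry"].to_numpy(), bone_df["rz"].to_numpy()
    )
    Rr = _rotation_from_angles(
        ref_df["rx"].to_numpy(), ref_df["ry"].to_numpy(), ref_df["rz"].to_numpy()
    )
    Rr_inv = Rr.inv()
    rel = Rr_inv * Rb
    angles = rel.as_euler(EULER_ORDER, degrees=True)  # columns rz, ry, rx
    if np.any(np.abs(angles[:, 1]) >= GIMBAL_LIMIT_DEG):
        bad = int(np.argmax(np.abs(angles[:, 1]) >= GIMBAL_LIMIT_DEG))
        raise DegenerateOrientationError(
            f"relative orientation gimbal-degenerate at frame {bad}"
        )
    tb = bone_df[list(TRANSLATION_DOFS)].to_numpy()
    tr = ref_df[list(TRANSLATION_DOFS)].to_numpy()
    t_rel = Rr_inv.apply(tb - tr)
    out = pd.DataFrame({"time_s": bone_df["time_s"].to_numpy()})
    out["rx"] = angles[:, 2]
    out["ry"] = angles[:, 1]
    out["rz"] = angles[:, 0]
    out[["tx", "ty", "tz"]] = t_rel
    return out


def chain_to_relative(chain: BoneChain) -> dict[str, pd.DataFrame]:
    """Express each vertebra relative to its adjoining caudal bone.

    The pelvis stays in the world/treadmill frame; L7 is returned relative to
    the pelvis (standing in for the rigidly attached sacrum) and L6 relative
    to L7.
    """
    out: dict[str, pd.DataFrame] = {}
    for bone in BONES:
        if bone not in chain.poses:
            continue
        if bone == "pelvis":
            out[bone] = chain.poses[bone].copy()
            continue
        ref = CAUDAL_NEIGHBOR[bone]
        if ref not in chain.poses:
            raise AlignmentError(f"{bone} present but caudal neighbor {ref} missing")
        out[bone] = _relative_trajectory(chain.poses[bone], chain.poses[ref])
    return out


def compose_chain(
    pelvis_world: pd.DataFrame, relative: dict[str, pd.DataFrame], frame_rate: float
) -> BoneChain:
    """Build world trajectories from a pelvis trajectory and relative offsets."""
    world = {"pelvis": pelvis_world.copy()}
    for bone in ("L7", "L6"):
        if bone not in relative:
            continue
        ref_df = world[CAUDAL_NEIGHBOR[bone]]
        rel_df = relative[bone]
        Rr = _rotation_from_angles(
            ref_df["rx"].to_numpy(), ref_df["ry"].to_numpy(), ref_df["rz"].to_numpy()
        )
        Rl = _rotation_from_angles(
            rel_df["rx"].to_numpy(), rel_df["ry"].to_numpy(), rel_df["rz"].to_numpy()
        )
        Rw = Rr * Rl
        angles = Rw.as_euler(EULER_ORDER, degrees=True)
        tw = Rr.apply(rel_df[list(TRANSLATION_DOFS)].to_numpy()) + ref_df[
            list(TRANSLATION_DOFS)
        ].to_numpy()
        df = pd.DataFrame({"time_s": ref_df["time_s"].to_numpy()})
        df["rx"] = angles[:, 2]
        df["ry"] = angles[:, 1]
        df["rz"] = angles[:, 0]
        df[["tx", "ty", "tz"]] = tw
        world[bone] = df
    return BoneChain(frame_rate=frame_rate, poses=world)
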