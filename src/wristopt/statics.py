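"""Planar single-DOF static load case and the moment-equilibrium contract.

The wrist is approximated as a hinge; one external load at a lever arm from
the rotation center produces one joint moment, which the agonist muscle group
must balance: M = sum(d_i * F_i).  With more than one muscle crossing the
joint the single equation is statically indeterminate and a redundancy
criterion (see :mod:`wristopt.solvers`) selects the force distribution.

Units: N, mm, N*mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .anatomy import MOTIONS
from .exceptions import InfeasibleInstanceError, InvalidParameterError

DEFAULT_RESIDUAL_RTOL = 1e-6


def external_moment(force: float, lever_arm: float) -> float:
    """Joint moment (N*mm) of an external force (N) at a lever arm (mm)."""
    if force < 0 or lever_arm < 0:
        raise InvalidParameterError("force and lever arm must be >= 0")
    return force * lever_arm


@dataclass(frozen=True)
class LoadCase:
    """External load applied to the hand: force, lever arm, motion direction.

    ``moment`` is derived (force x lever arm) and exposed in N*mm.
    """

    external_force: float  # N
    lever_arm: float  # mm, load application point to rotation center
    direction: str = "flexion"

    def __post_init__(self) -> None:
        if self.direction not in MOTIONS:
            raise InvalidParameterError(f"unknown direction {self.direction!r}")
        external_moment(self.external_force, self.lever_arm)  # validates signs

    @property
    def moment(self) -> float:
        return external_moment(self.external_force, self.lever_arm)


@dataclass(frozen=True)
class JointInstance:
    """A solvable planar joint: muscles (PCSA, moment arm) and a target moment.

    Arms are non-negative agonist magnitudes for the active direction;
    at least one must be strictly positive for equilibrium to be attainable.
    """

    names: tuple[str, ...]
    pcsa: tuple[float, ...]  # mm^2, all > 0
    arms: tuple[float, ...]  # mm, all >= 0
    moment: float  # N*mm
    direction: str = "flexion"

    def __post_init__(self) -> None:
        m = len(self.names)
        if m < 1:
            raise InvalidParameterError("instance needs at least one muscle")
        if len(self.pcsa) != m or len(self.arms) != m:
            raise InvalidParameterError("names, pcsa and arms must have equal length")
        if any(a <= 0 for a in self.pcsa):
            raise InvalidParameterError("all PCSAs must be > 0")
        if any(d < 0 for d in self.arms):
            raise InvalidParameterError("moment arms must be >= 0")
        if self.moment < 0:
            raise InvalidParameterError("target moment must be >= 0")
        if self.moment > 0 and not any(d > 0 for d in self.arms):
            raise InfeasibleInstanceError(
                "no muscle has a positive moment arm; moment cannot be balanced"
            )

    @property
    def m(self) -> int:
        return len(self.names)

    def pcsa_array(self) -> np.ndarray:
        return np.asarray(self.pcsa, dtype=float)

    def arm_array(self) -> np.ndarray:
        return np.asarray(self.arms, dtype=float)


def equilibrium_residual(forces: Sequence[float], instance: JointInstance) -> float:
    """Signed moment residual M - sum(d_i * F_i), in N*mm."""
    f = np.asarray(forces, dtype=float)
    if f.shape != (instance.m,):
        raise InvalidParameterError(
            f"expected {instance.m} forces, got shape {f.shape}"
        )
    return float(instance.moment - instance.arm_array() @ f)


def residual_tolerance(instance: JointInstance, rtol: float = DEFAULT_RESIDUAL_RTOL) -> float:
    """Default 'equilibrium satisfied' tolerance: rtol * max(1, M)."""
    return rtol * max(1.0, instance.moment)


def is_statically_indeterminate(instance: JointInstance) -> bool:
    """True iff more than one muscle carries a nonzero arm in the single moment equation."""
    return int(np.count_nonzero(instance.arm_array())) > 1
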