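"""Core data containers shared across modules."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

VALID_DIRECTIONS = ("pulling", "relaxing")


@dataclass
class ForceExtensionBranch:
    """One pulling or relaxing sweep: ordered (force, extension) points.

    Parameters
    ----------
    condition
        Experimental condition label, e.g. ``"ssDNA"`` or ``"+SSB"``.
    salt_mM, mg_mM
        Monovalent and divalent salt concentrations.
    direction
        ``"pulling"`` (increasing force) or ``"relaxing"`` (decreasing force).
    force_pN, extension_nm
        Point arrays in sweep order.  Forces must be strictly monotone
        along the sweep (increasing for pulling, decreasing for relaxing).
    completion_error_bound_pNnm
        Worst-case work uncertainty introduced by branch completion
        (0 for branches measured to the full force range).
    """

    condition: str
    salt_mM: float
    direction: str
    force_pN: np.ndarray
    extension_nm: np.ndarray
    mg_mM: float = 0.0
    completion_error_bound_pNnm: float = 0.0

    def __post_init__(self) -> None:
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(
                f"direction must be one of {VALID_DIRECTIONS}, got {self.direction!r}"
            )
        if self.force_pN.shape != self.extension_nm.shape:
            raise ValueError("force and extension arrays must have equal length")
        if self.force_pN.ndim != 1:
            raise ValueError("branch points must be one-dimensional arrays")
        d = np.diff(self.force_pN)
        if self.direction == "pulling" and np.any(d <= 0):
            raise ValueError("pulling branch requires strictly increasing forces")
        if self.direction == "relaxing" and np.any(d >= 0):
            raise ValueError("relaxing branch requires strictly decreasing forces")
        if np.any(self.force_pN < 0):
            raise ValueError("forces must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.force_pN.size)

    @property
    def max_force_pN(self) -> float:
        return float(self.force_pN.max())

    def sorted_by_force(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (force, extension) with force ascending."""
        order = np.argsort(self.force_pN, kind="stable")
        return self.force_pN[order], self.extension_nm[order]

    def key(self) -> tuple[str, float, str]:
        return (self.condition, float(self.salt_mM), self.direction)


@dataclass
class TimeTrace:
    """Extension vs time under a piecewise-constant force schedule."""

    time_s: np.ndarray
    extension_nm: np.ndarray
    force_pN: np.ndarray  # one value per sample, piecewise constant

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if not (self.time_s.shape == self.extension_nm.shape == self.force_pN.shape):
            raise ValueError("time, extension and force arrays must align")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    def segments(self) -> list["TimeTrace"]:
        """Split at force steps; each segment holds a single force."""
        breaks = np.flatnonzero(np.diff(self.force_pN) != 0) + 1
        out = []
        for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, self.force_pN.size]):
            out.append(
                TimeTrace(self.time_s[lo:hi], self.extension_nm[lo:hi], self.force_pN[lo:hi])
            )
        return out


@dataclass
class SyntheticTruth:
    """Ground-truth record attached to every generated dataset.

    ``params`` holds every generator argument (including the seed) needed
    to regenerate the dataset bit-identically; ``derived`` holds analytic
    quantities (per-branch works, hysteresis areas, schedules).
    """

    generator: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    derived: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o: Any) -> Any:
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), default=default, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            generator=d["generator"],
            seed=int(d["seed"]),
            params=d.get("params", {}),
            derived=d.get("derived", {}),
        )
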