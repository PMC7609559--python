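"""Velocity-encoded measurement planes.

A :class:`PlaneVelocityField` mimics one 4D VEC MRI measurement plane: the
three velocity components sampled on a regular 2-D grid across the vessel
cross-section, with a circular lumen mask. ``vz`` is the through-plane
component (along the vessel axis), ``vx``/``vy`` the in-plane components.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np


@dataclass
class PlaneVelocityField:
    x: np.ndarray        # in-plane coordinates, m, shape (n, n)
    y: np.ndarray
    vx: np.ndarray       # in-plane velocity, m/s
    vy: np.ndarray
    vz: np.ndarray       # through-plane velocity, m/s
    mask: np.ndarray     # boolean lumen mask
    center: tuple[float, float] = (0.0, 0.0)   # lumen center, m
    radius: float = 0.0                        # lumen radius, m

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.x, self.y, self.vx, self.vy, self.vz, self.mask)}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent plane array shapes: {shapes}")
        if not self.mask.any():
            raise ValueError("empty lumen mask")
        if not self.radius > 0:
            raise ValueError("lumen radius must be positive")

    @property
    def pixel_area(self) -> float:
        dx = float(self.x[0, 1] - self.x[0, 0])
        dy = float(self.y[1, 0] - self.y[0, 0])
        return abs(dx * dy)

    @property
    def grid_spacing(self) -> float:
        return float(abs(self.x[0, 1] - self.x[0, 0]))

    def integrated_flow(self) -> float:
        """Through-plane volume flow over the lumen, ml/s."""
        q_m3 = float(self.vz[self.mask].sum()) * self.pixel_area
        return q_m3 * 1e6

    # -- plain-text serialization (one CSV per plane) -----------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "vx", "vy", "vz", "mask"])
            for xi, yi, ui, vi, wi, mi in zip(
                self.x.ravel(), self.y.ravel(), self.vx.ravel(),
                self.vy.ravel(), self.vz.ravel(), self.mask.ravel(),
            ):
                w.writerow([repr(float(xi)), repr(float(yi)), repr(float(ui)),
                            repr(float(vi)), repr(float(wi)), int(mi)])
        meta = {"n": self.x.shape[0], "center": list(self.center), "radius": self.radius}
        Path(str(path) + ".json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PlaneVelocityField":
        meta = json.loads(Path(str(path) + ".json").read_text(encoding="utf-8"))
        n = meta["n"]
        data = np.genfromtxt(path, delimiter=",", names=True)
        arrs = {k: np.asarray(data[k], dtype=float).reshape(n, n)
                for k in ("x", "y", "vx", "vy", "vz")}
        mask = np.asarray(data["mask"], dtype=float).reshape(n, n) > 0.5
        return cls(mask=mask, center=tuple(meta["center"]), radius=meta["radius"], **arrs)


def make_circular_grid(radius: float, n: int = 64,
                       center: tuple[float, float] = (0.0, 0.0)) -> PlaneVelocityField:
    """Zero-velocity plane on an n x n grid over the lumen bounding square."""
    cx, cy = center
    # pixel centers spanning the bounding square of the lumen
    edges = np.linspace(-radius, radius, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    x, y = np.meshgrid(mids + cx, mids + cy)
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2
    zero = np.zeros_like(x)
    return PlaneVelocityField(x=x, y=y, vx=zero.copy(), vy=zero.copy(),
                              vz=zero.copy(), mask=mask, center=center, radius=radius)
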