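"""Two-dimensional model potentials with metastable wells.

Each potential is a sum of an even-degree polynomial confinement
``W (x^d + y^d)`` and signed, separable Gaussian terms
``sign * G(x, cx) * G(y, cy)`` with ``G(x, x0) = exp(-(x - x0)^2 / (2 sigma^2))``.
Attractive terms (sign = -1) carve metastable wells; a repulsive term
(sign = +1) can raise a central barrier.  Three built-in parameterizations
are provided: a linear 3-state system, a triangular 3-state system, and a
4-state system with a central bump.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianTerm",
    "ModelPotential",
    "builtin_potential",
    "BUILTIN_NAMES",
]

DEFAULT_SIGMA = 0.8
DEFAULT_CONFINEMENT_WEIGHT = 1e-4


@dataclass(frozen=True)
class GaussianTerm:
    """One separable 2-D Gaussian, ``sign * G(x, cx) * G(y, cy)``."""

    center_x: float
    center_y: float
    sign: int = -1
    width: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"Gaussian width must be positive, got {self.width}")
        if self.sign not in (-1, 1):
            raise ValueError(f"Gaussian sign must be +1 or -1, got {self.sign}")

    def g(self, v: np.ndarray | float, center: float) -> np.ndarray | float:
        return np.exp(-((np.asarray(v, dtype=float) - center) ** 2) / (2.0 * self.width**2))


@dataclass(frozen=True)
class ModelPotential:
    """Polynomial confinement plus signed Gaussian wells/bumps.

    ``U(x, y) = W (x^d + y^d) + sum_i sign_i G(x, cx_i) G(y, cy_i)``.
    """

    confinement_weight: float
    confinement_degree: int
    gaussians: tuple[GaussianTerm, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.confinement_weight <= 0:
            raise ValueError("confinement_weight must be positive")
        if self.confinement_degree % 2 != 0 or self.confinement_degree < 2:
            raise ValueError("confinement_degree must be a positive even integer")
        n_wells = sum(1 for g in self.gaussians if g.sign == -1)
        if n_wells < 2:
            raise ValueError("potential needs at least 2 attractive Gaussians (wells)")
        object.__setattr__(self, "gaussians", tuple(self.gaussians))

    # -- evaluation ---------------------------------------------------------

    def energy(self, x, y):
        """Potential energy U(x, y); vectorizes over array input."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = self.confinement_degree
        u = self.confinement_weight * (x**d + y**d)
        for g in self.gaussians:
            u = u + g.sign * g.g(x, g.center_x) * g.g(y, g.center_y)
        return u if u.ndim else float(u)

    def gradient(self, x, y):
        """Analytic (dU/dx, dU/dy); vectorizes over array input."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = self.confinement_degree
        w = self.confinement_weight
        gx = d * w * x ** (d - 1)
        gy = d * w * y ** (d - 1)
        for g in self.gaussians:
            ex = g.g(x, g.center_x)
            ey = g.g(y, g.center_y)
            s2 = g.width**2
            gx = gx + g.sign * ex * ey * (-(x - g.center_x) / s2)
            gy = gy + g.sign * ex * ey * (-(y - g.center_y) / s2)
        if gx.ndim:
            return gx, gy
        return float(gx), float(gy)

    # -- introspection ------------------------------------------------------

    @property
    def well_centers(self) -> np.ndarray:
        """(n_wells, 2) array of attractive-Gaussian centers, in input order."""
        return np.array(
            [[g.center_x, g.center_y] for g in self.gaussians if g.sign == -1]
        )

    def well_projections(self, axis: str = "x") -> np.ndarray:
        """Well-center coordinates projected on one axis (the order parameter)."""
        col = {"x": 0, "y": 1}[axis]
        return self.well_centers[:, col]

    def deepest_well(self) -> tuple[float, float]:
        """Well center with the lowest energy (the default simulation start)."""
        centers = self.well_centers
        energies = [self.energy(cx, cy) for cx, cy in centers]
        cx, cy = centers[int(np.argmin(energies))]
        return float(cx), float(cy)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelPotential":
        """Build from a config mapping with keys ``confinement_weight``,
        ``confinement_degree``, ``gaussians`` (list of {center_x, center_y,
        sign, [width]}), and optional ``name``."""
        terms = tuple(
            GaussianTerm(
                center_x=float(g["center_x"]),
                center_y=float(g["center_y"]),
                sign=int(g.get("sign", -1)),
                width=float(g.get("width", DEFAULT_SIGMA)),
            )
            for g in cfg["gaussians"]
        )
        return cls(
            confinement_weight=float(cfg["confinement_weight"]),
            confinement_degree=int(cfg["confinement_degree"]),
            gaussians=terms,
            name=str(cfg.get("name", "custom")),
        )


def _three_state(name: str, centers: list[tuple[float, float]]) -> ModelPotential:
    return ModelPotential(
        confinement_weight=DEFAULT_CONFINEMENT_WEIGHT,
        confinement_degree=6,
        gaussians=tuple(GaussianTerm(cx, cy, -1) for cx, cy in centers),
        name=name,
    )


# Well placements for the two 3-state layouts: collinear A-B-C for the linear
# system, an equilateral triangle for the triangular one so that every pair
# of states is kinetically equidistant while the x-projection (A at -1.1,
# B at +1.1, C at 0) suggests otherwise.  Side 2.2 keeps barriers comparable
# to the linear system's adjacent-well spacing of 2, so both systems show
# abundant transitions at the study temperatures.  The 4-state geometry
# (central bump, four wells) is fixed; the 3-state coordinates are a package
# convention.
_BUILTINS = {
    "linear3": lambda: _three_state("linear3", [(-2.0, 0.0), (0.0, 0.0), (2.0, 0.0)]),
    "triangular3": lambda: _three_state(
        "triangular3", [(-1.1, 0.0), (1.1, 0.0), (0.0, 1.9052558883257653)]
    ),
    "four_state": lambda: ModelPotential(
        confinement_weight=DEFAULT_CONFINEMENT_WEIGHT,
        confinement_degree=4,
        gaussians=(
            GaussianTerm(0.0, 0.0, +1),
            GaussianTerm(2.0, -1.0, -1),
            GaussianTerm(0.5, 2.0, -1),
            GaussianTerm(-0.5, -2.0, -1),
            GaussianTerm(-2.0, 1.0, -1),
        ),
        name="four_state",
    ),
}

BUILTIN_NAMES = tuple(_BUILTINS)


def builtin_potential(name: str) -> ModelPotential:
    """Return one of the built-in model potentials by name.

    Parameters
    ----------
    name : {"linear3", "triangular3", "four_state"}
    """
    try:
        return _BUILTINS[name]()
    except KeyError:
        raise ValueError(
            f"unknown potential {name!r}; choose from {sorted(_BUILTINS)}"
        ) from None
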