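"""Model parameters and bead configurations.

The model is a set of ``n_beads`` point beads in ``dim`` dimensions subject to
three deterministic forces (linear confinement toward the origin, Gaussian
excluded-volume repulsion, and harmonic springs for transiently bound pairs)
plus isotropic thermal noise of strength ``epsilon``.  Pairwise bonds form and
break as a continuous-time Markov chain whose rates are modulated by
``timescale`` and, for asymptotic scaling studies, by ``epsilon**(-q)`` with
``q = scaling_exponent``.

Two presets are shipped:

``table1-3bead``
    The dimensionless 2-D three-bead system used for all landscape and
    escape-time analysis.

``table1-361``
    The dimensional 3-D nucleolus model (lengths in nm, rates in 1/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

import numpy as np

__all__ = [
    "ModelParams",
    "preset",
    "reduced_many_bead",
    "PRESET_NAMES",
    "as_configuration",
    "flatten",
    "unflatten",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical and kinetic constants of the switching bead model.

    Parameters
    ----------
    n_beads : int
        Number of beads.
    dim : int
        Spatial dimension, 2 or 3.
    eta : float
        Confinement strength; the confinement force on bead *i* is ``-eta * x_i``.
    a_ev : float
        Excluded-volume amplitude.
    c_ev : float
        Excluded-volume squared length scale (the Gaussian kernel is
        ``exp(-r**2 / c_ev)``).
    kappa : float
        Spring constant of an active bond.
    c_break : float
        Bond breaking rate (before timescale/epsilon scaling).
    affinity_amplitude, affinity_steepness, affinity_midpoint : float
        Parameters of the binding-rate (affinity) function
        ``a(r) = amplitude / (1 + exp(steepness * (r - midpoint)))``.
    timescale : float
        Multiplier of the whole transition-rate matrix (the binding-timescale
        knob: alpha for the 3-bead model, beta for the many-bead model).
    epsilon : float
        Thermal-noise strength; per-coordinate diffusion is ``epsilon``
        (noise increments have variance ``2 * epsilon * dt``).
    scaling_exponent : int
        Power q in the rate multiplier ``timescale * epsilon**(-q)`` applied in
        simulation; q = 0, 1, 2 select the amorphic, flexible, and rigid
        asymptotic regimes respectively.
    """

    n_beads: int
    dim: int
    eta: float
    a_ev: float
    c_ev: float
    kappa: float
    c_break: float
    affinity_amplitude: float = 2.0
    affinity_steepness: float = 20.0
    affinity_midpoint: float = 0.75
    timescale: float = 1.0
    epsilon: float = 0.05
    scaling_exponent: int = 1

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be a positive integer")
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if self.scaling_exponent not in (0, 1, 2):
            raise ValueError("scaling_exponent must be 0, 1 or 2")
        for name in ("eta", "a_ev", "kappa", "c_break", "affinity_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("c_ev", "timescale", "epsilon", "affinity_steepness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.affinity_midpoint < 0:
            raise ValueError("affinity_midpoint must be nonnegative")

    # -- derived quantities -------------------------------------------------

    @property
    def n_coords(self) -> int:
        """Length of the concatenated coordinate vector (bead-major order)."""
        return self.n_beads * self.dim

    @property
    def rate_multiplier(self) -> float:
        """Effective CTMC rate multiplier ``timescale * epsilon**(-q)``."""
        return self.timescale * self.epsilon ** (-self.scaling_exponent)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        return cls(**d)

    def with_(self, **kw: Any) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return replace(self, **kw)


_PRESETS: dict[str, dict[str, Any]] = {
    # Dimensional nucleolus model: nm, 1/s.  epsilon (nm^2/s) is not a
    # published constant; the default is of the order of the excluded-volume
    # pair-potential amplitude a_ev*c_ev/2 (= 900 nm^2/s), the regime in which
    # thermal motion can carry beads across the soft-core repulsion into
    # binding range at a density of ~0.5 beads per binding volume.  Far below
    # this, binding encounters never occur and no timescale produces any
    # clustering; see docs/methods.md.
    # c_ev stores the kernel denominator exp(-r^2 / c_ev).  The published
    # constants for this model (30,000 nm^2 / 0.5) are Gaussian variances
    # sigma^2 (kernel exp(-r^2 / 2 sigma^2)), so the presets carry twice the
    # tabulated value; with the tabulated value used directly as the
    # denominator, the averaged force field loses the 2-bead-cluster and
    # unbound-triangle fixed points entirely (the residual binding attraction
    # overwhelms excluded volume at the balance distance).
    "table1-361": dict(
        n_beads=361, dim=3, eta=0.002, a_ev=0.03, c_ev=60000.0, kappa=10.0,
        c_break=0.01, affinity_amplitude=2.0, affinity_steepness=20.0,
        affinity_midpoint=75.0, timescale=1.0, epsilon=300.0, scaling_exponent=0,
    ),
    # Dimensionless 2-D analysis model.
    "table1-3bead": dict(
        n_beads=3, dim=2, eta=1.0, a_ev=2.0, c_ev=1.0, kappa=5.0,
        c_break=0.5, affinity_amplitude=2.0, affinity_steepness=20.0,
        affinity_midpoint=0.75, timescale=1.0, epsilon=0.05, scaling_exponent=1,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides: Any) -> ModelParams:
    """Return a named parameter preset, optionally overriding fields.

    >>> p = preset("table1-3bead", timescale=10.0)
    >>> p.kappa
    5.0
    """
    try:
        base = dict(_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        ) from None
    base.update(overrides)
    return ModelParams(**base)


def reduced_many_bead(n_beads: int, **overrides: Any) -> ModelParams:
    """Reduced n-bead version of the dimensional nucleolus model.

    Keeps the full model's local bead density (beads per binding volume): the
    confinement cloud radius scales as sqrt(epsilon/eta), so eta is raised by
    (361 / n_beads)**(2/3) to shrink the cloud as n**(1/3).  All other
    constants are unchanged.  Without this rescaling a smaller system is
    dilute and binding-driven clustering disappears for every timescale.
    """
    p = preset("table1-361")
    eta = p.eta * (p.n_beads / n_beads) ** (2.0 / 3.0)
    return p.with_(n_beads=n_beads, eta=eta, **overrides)


# -- configuration helpers ----------------------------------------------------
#
# A configuration is simply an (n_beads, dim) float array.  The concatenated
# coordinate vector uses bead-major, axis-minor order, i.e. C-order flattening.


def as_configuration(positions: np.ndarray, params: ModelParams) -> np.ndarray:
    """Validate and return positions as an (n_beads, dim) float array."""
    x = np.asarray(positions, dtype=float)
    if x.shape != (params.n_beads, params.dim):
        raise ValueError(
            f"positions shape {x.shape} inconsistent with "
            f"({params.n_beads}, {params.dim})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("positions contain non-finite entries")
    return x


def flatten(positions: np.ndarray) -> np.ndarray:
    """Concatenated coordinate vector (bead-major order)."""
    return np.asarray(positions, dtype=float).reshape(-1)


def unflatten(vec: np.ndarray, params: ModelParams) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    return np.asarray(vec, dtype=float).reshape(params.n_beads, params.dim)
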