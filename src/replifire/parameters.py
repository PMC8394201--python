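"""Model parameters for the origin-firing lattice models MM1--MM5.

The replicating genome is a one-dimensional lattice of 1-kb blocks.  Origin
firing requires the encounter of an unreplicated, origin-eligible block with
one of a pool of rate-limiting trans-acting factors whose number grows
linearly in time, ``N(t) = N0 + J*t``.  The nested model variants are

* ``MM1`` -- mean-field: every potential origin fires with probability
  ``Pout`` per round.
* ``MM2`` -- MM1 with a variable fork speed, redrawn per fork per round.
* ``MM3`` -- MM1 plus a fork-proximal firing probability ``Plocal`` acting
  over a distance ``d`` downstream (ahead) of every active fork.
* ``MM4`` -- the genome is segmented into a fraction ``theta`` with firing
  probability ``Pin`` and a fraction ``1-theta`` with probability ``Pout``.
* ``MM5`` -- MM3 and MM4 combined.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable

import yaml

VARIANTS = ("MM1", "MM2", "MM3", "MM4", "MM5")

#: Fitting bounds for the adjustable variables (lower, upper).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "N0": (1.0, 2000.0),
    "J": (0.0, 4000.0),
    "Pout": (0.0, 1.0),
    "Pin": (0.0, 1.0),
    "Plocal": (0.0, 1.0),
    "theta": (0.0, 1.0),
    "d": (0.0, 1000.0),
}

#: Adjustable parameters that are active (fitted) under each variant.
ACTIVE_PARAMETERS: dict[str, tuple[str, ...]] = {
    "MM1": ("N0", "J", "Pout"),
    "MM2": ("N0", "J", "Pout"),
    "MM3": ("N0", "J", "Pout", "Plocal", "d"),
    "MM4": ("N0", "J", "Pout", "Pin", "theta"),
    "MM5": ("N0", "J", "Pout", "Pin", "theta", "Plocal", "d"),
}

_PROBABILITIES = ("Pout", "Pin", "Plocal", "theta")


@dataclass(frozen=True)
class ModelParameters:
    """Parameter set for one simulation of S phase.

    Parameters
    ----------
    N0 : int
        Initial number of limiting factors (dimensionless count).
    J : float
        Rate at which the limiting-factor pool grows, in factors per
        Monte Carlo round (see the package methods note on units).
    Pout : float
        Per-candidate, per-round firing probability in the low-probability
        (checkpoint-sensitive) genome fraction.
    Pin : float
        Firing probability inside the high-probability fraction ``theta``.
    Plocal : float
        Firing probability inside the fork-proximal zone (MM3/MM5).
    theta : float
        Genome fraction carrying ``Pin``.
    d : float
        Width of the fork-proximal zone, in kb (integer blocks).
    v : float
        Fork speed in kb/min; 0.5 by default so one round advances each
        fork by one block.
    variant : str
        One of ``MM1`` .. ``MM5``.
    origin_layout : str
        ``"continuous"`` (every block is a potential origin) or
        ``"discrete"`` (potential origins are sparse point objects).
    mean_origin_spacing : float
        Mean spacing of potential origins in kb for the discrete layout.
    round_minutes : float
        Wall-clock minutes represented by one Monte Carlo round.
    speed_choices : tuple of float
        Per-round fork-speed values (kb/min) drawn uniformly in MM2.
    """

    N0: int = 100
    J: float = 10.0
    Pout: float = 1e-3
    Pin: float = 0.0
    Plocal: float = 0.0
    theta: float = 0.0
    d: float = 0.0
    v: float = 0.5
    variant: str = "MM1"
    origin_layout: str = "continuous"
    mean_origin_spacing: float = 2.3
    round_minutes: float = 2.0
    speed_choices: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

    @property
    def active(self) -> tuple[str, ...]:
        return ACTIVE_PARAMETERS[self.variant]

    @property
    def blocks_per_round(self) -> float:
        """Fork displacement per round, in blocks (1 block = 1 kb)."""
        return self.v * self.round_minutes

    def factors_available(self, t: int, bound: float) -> int:
        """Free factors Nf(t) = N0 + J*t - Nb at round ``t``."""
        return max(0, int(self.N0 + self.J * t - bound))

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        if "speed_choices" in d:
            d["speed_choices"] = tuple(d["speed_choices"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class ParameterError(ValueError):
    """Raised when a parameter violates its bounds; names the field."""


def validate_parameters(p: ModelParameters) -> ModelParameters:
    """Check all invariants of ``p`` and return it unchanged.

    Raises
    ------
    ParameterError
        Naming the offending field when a bound is violated.
    """
    if p.variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {p.variant!r}")
    if p.origin_layout not in ("continuous", "discrete"):
        raise ParameterError(f"origin_layout invalid: {p.origin_layout!r}")
    for name in _PROBABILITIES:
        val = getattr(p, name)
        if not 0.0 <= val <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {val}")
    if p.N0 < 0:
        raise ParameterError(f"N0 must be >= 0, got {p.N0}")
    if p.J < 0:
        raise ParameterError(f"J must be >= 0, got {p.J}")
    if p.d < 0:
        raise ParameterError(f"d must be >= 0, got {p.d}")
    if p.v < 0:
        raise ParameterError(f"v must be >= 0, got {p.v}")
    if p.mean_origin_spacing < 1:
        raise ParameterError(
            f"mean_origin_spacing must be >= 1 kb, got {p.mean_origin_spacing}"
        )
    if p.round_minutes <= 0:
        raise ParameterError(f"round_minutes must be > 0, got {p.round_minutes}")
    if any(s < 0 for s in p.speed_choices) or not p.speed_choices:
        raise ParameterError(f"speed_choices must be non-negative, got {p.speed_choices}")
    return p


def check_fitting_bounds(p: ModelParameters) -> ModelParameters:
    """Additionally enforce the fitting bounds on the active parameters."""
    validate_parameters(p)
    for name in p.active:
        lo, hi = PARAM_BOUNDS[name]
        val = getattr(p, name)
        if not lo <= val <= hi:
            raise ParameterError(f"{name}={val} outside fitting bounds [{lo}, {hi}]")
    return p


def canonicalize(p: ModelParameters) -> ModelParameters:
    """Resolve the IN/OUT labelling degeneracy.

    The genome segmentation is symmetric under
    ``(theta, Pin, Pout) -> (1 - theta, Pout, Pin)``; by definition ``Pin``
    is the *high* firing probability, so parameter sets with
    ``Pin < Pout`` are mapped to the equivalent canonical form.
    """
    if p.variant in ("MM4", "MM5") and p.Pin < p.Pout:
        return p.replace(Pin=p.Pout, Pout=p.Pin, theta=1.0 - p.theta)
    return p


def params_from_vector(
    x: Iterable[float], variant: str, template: ModelParameters | None = None
) -> ModelParameters:
    """Build a parameter set from a flat vector over the variant's active genes.

    ``N0`` and ``d`` are rounded to integer counts/blocks; probabilities are
    clipped to [0, 1] to absorb floating-point noise.  The result is
    canonicalized so that ``Pin >= Pout`` (see :func:`canonicalize`).
    """
    names = ACTIVE_PARAMETERS[variant]
    x = list(x)
    if len(x) != len(names):
        raise ValueError(f"expected {len(names)} genes for {variant}, got {len(x)}")
    base = template if template is not None else ModelParameters(variant=variant)
    kw: dict = {"variant": variant}
    for name, val in zip(names, x):
        if name == "N0":
            kw[name] = int(round(val))
        elif name == "d":
            kw[name] = float(round(val))
        elif name in _PROBABILITIES:
            kw[name] = float(min(1.0, max(0.0, val)))
        else:
            kw[name] = float(val)
    return canonicalize(base.replace(**kw))
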