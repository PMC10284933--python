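"""Kinetic rate law for thermal degradation of biologics.

The observed degradation extent alpha in [0, 1] evolves as a weighted sum of
(at most) two independent single-step reactions, each with Arrhenius
temperature dependence, a reaction order ``n``, an optional autocatalytic
exponent ``m`` and an optional protein-concentration exponent ``p``::

    dalpha/dt = v * k1(T) * (1-a1)^n1 * a1^m1 * C^p1
              + (1-v) * k2(T) * (1-a2)^n2 * a2^m2 * C^p2

with ``k_i(T) = exp(lnA_i - Ea_i / (R*T))`` and the observed extent
``alpha = v*a1 + (1-v)*a2``.  Each sub-extent ``a_i`` follows its own step
(``da_i/dt = r_i``), which is the only reading under which the combined rate
equals the sum above at all times.  Setting ``v = 1`` recovers a one-step
model; ``m = 0`` removes the autocatalytic contribution; ``p = 0`` removes
the concentration dependence.

Rates are per day, temperatures in Kelvin, activation energies in J/mol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import yaml

from .errors import DomainError

#: Universal gas constant, J/(mol*K).
GAS_CONSTANT = 8.314462618

#: Canonical parameter order used throughout fitting and serialization.
PARAM_NAMES = (
    "lnA1", "Ea1", "n1", "m1",
    "lnA2", "Ea2", "n2", "m2",
    "v", "p1", "p2",
)

#: Default box constraints for free parameters (lnA dimensionless-log per day,
#: Ea in J/mol).  lnA range is wide enough to contain any rate constant
#: reachable from Ea in [10, 300] kJ/mol with k(40 C) in [1e-8, 10]/day.
DEFAULT_BOUNDS = {
    "lnA1": (-40.0, 140.0),
    "Ea1": (10_000.0, 300_000.0),
    "n1": (0.0, 3.0),
    "m1": (0.0, 2.0),
    "lnA2": (-40.0, 140.0),
    "Ea2": (10_000.0, 300_000.0),
    "n2": (0.0, 3.0),
    "m2": (0.0, 2.0),
    "v": (0.0, 1.0),
    "p1": (-2.0, 3.0),
    "p2": (-2.0, 3.0),
}

#: Sub-extents are started at this value instead of exactly zero so that
#: autocatalytic steps (m > 0, rate proportional to alpha^m) can ignite.
ALPHA0_DEFAULT = 1e-8


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector of the two-step competitive rate law.

    ``lnA`` is the natural log of the pre-exponential factor (per day);
    ``Ea`` the activation energy (J/mol); ``n`` the reaction order; ``m``
    the autocatalytic exponent; ``v`` the weight of step 1; ``p`` the
    concentration exponent of each step.
    """

    lnA1: float
    Ea1: float
    n1: float = 1.0
    m1: float = 0.0
    lnA2: float = 0.0
    Ea2: float = 0.0
    n2: float = 1.0
    m2: float = 0.0
    v: float = 1.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.v <= 1.0:
            raise DomainError(f"v must lie in [0, 1], got {self.v}")
        if self.Ea1 < 0 or self.Ea2 < 0:
            raise DomainError("activation energies must be non-negative")
        if self.m1 < 0 or self.m2 < 0:
            raise DomainError("autocatalytic exponents must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])

    def replace(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParameters":
        return cls(**{k: float(v) for k, v in d.items()})


def arrhenius_k(lnA, Ea, T):
    """Arrhenius rate constant ``exp(lnA - Ea/(R*T))`` in per day.

    Vectorized over any argument; raises :class:`DomainError` for
    non-positive absolute temperatures.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("absolute temperature must be positive")
    out = np.exp(np.asarray(lnA, dtype=float) - np.asarray(Ea, dtype=float) / (GAS_CONSTANT * T))
    return out if out.ndim else float(out)


def _step_factor(alpha, n, m):
    """(1-alpha)^n * alpha^m with the conventions 0^0 = 1 and domain checks."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha < 0) | (alpha > 1)):
        raise DomainError("extent must lie in [0, 1]")
    if (n < 0 and np.any(alpha == 1)) or (m < 0 and np.any(alpha == 0)):
        raise DomainError("0 raised to a negative exponent in the rate law")
    one_minus = 1.0 - alpha
    # 0^0 -> 1 by convention (numpy already follows it)
    return one_minus**n * alpha**m


def rate(params: KineticParameters, alpha1, alpha2, T, C: float = 1.0):
    """Instantaneous rates ``(da1/dt, da2/dt, dalpha/dt)`` at one state.

    ``dalpha/dt = v*r1 + (1-v)*r2`` with ``r_i = k_i(T) f_i(a_i) C^p_i``.
    """
    if C <= 0 and (params.p1 != 0 or params.p2 != 0):
        raise DomainError("concentration must be positive when p != 0")
    r1 = arrhenius_k(params.lnA1, params.Ea1, T) * _step_factor(alpha1, params.n1, params.m1)
    r2 = arrhenius_k(params.lnA2, params.Ea2, T) * _step_factor(alpha2, params.n2, params.m2)
    if params.p1 != 0:
        r1 = r1 * C**params.p1
    if params.p2 != 0:
        r2 = r2 * C**params.p2
    total = params.v * r1 + (1.0 - params.v) * r2
    return r1, r2, total


@dataclass(frozen=True)
class ModelSpec:
    """One entry of the screening catalog.

    Every parameter of :class:`KineticParameters` is either pinned in
    ``fixed`` or listed in ``free`` with finite bounds.
    """

    name: str
    structure: str  # "one-step" | "two-step"
    fixed: dict = field(default_factory=dict)
    free: tuple = ()
    bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "free", tuple(self.free))
        covered = set(self.fixed) | set(self.free)
        missing = [p for p in PARAM_NAMES if p not in covered]
        if missing:
            raise ValueError(f"model '{self.name}': parameters neither fixed nor free: {missing}")
        dup = set(self.fixed) & set(self.free)
        if dup:
            raise ValueError(f"model '{self.name}': parameters both fixed and free: {sorted(dup)}")
        if len(self.free) < 1:
            raise ValueError(f"model '{self.name}': at least one free parameter required")
        for p in self.free:
            lo, hi = self.bounds_for(p)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"model '{self.name}': free parameter {p} needs finite bounds")

    @property
    def k_free(self) -> int:
        return len(self.free)

    def bounds_for(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, DEFAULT_BOUNDS[name]))

    def build_params(self, x) -> KineticParameters:
        """Assemble a full parameter vector from free values ``x``."""
        d = dict(self.fixed)
        for name, val in zip(self.free, x):
            d[name] = float(val)
        return KineticParameters(**d)

    def with_free(self, *names: str) -> "ModelSpec":
        """Copy of this spec with additional parameters freed."""
        fixed = {k: v for k, v in self.fixed.items() if k not in names}
        free = self.free + tuple(n for n in names if n not in self.free)
        return ModelSpec(self.name + "+" + "+".join(names), self.structure, fixed, free, dict(self.bounds))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "structure": self.structure,
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "free": list(self.free),
            "bounds": {k: [float(lo), float(hi)] for k, (lo, hi) in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            name=d["name"],
            structure=d["structure"],
            fixed=dict(d.get("fixed", {})),
            free=tuple(d.get("free", ())),
            bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
        )


_STEP2_OFF = {"lnA2": 0.0, "Ea2": 0.0, "n2": 1.0, "m2": 0.0}
_NO_CONC = {"p1": 0.0, "p2": 0.0}


def _one_step(name: str, fixed_extra: dict, free: tuple) -> ModelSpec:
    fixed = {"v": 1.0, **_STEP2_OFF, **_NO_CONC, **fixed_extra}
    return ModelSpec(name, "one-step", fixed, free, {})


def zero_order_spec() -> ModelSpec:
    return _one_step("zero-order", {"n1": 0.0, "m1": 0.0}, ("lnA1", "Ea1"))


def first_order_spec() -> ModelSpec:
    return _one_step("first-order", {"n1": 1.0, "m1": 0.0}, ("lnA1", "Ea1"))


def nth_order_spec() -> ModelSpec:
    return _one_step("nth-order", {"m1": 0.0}, ("lnA1", "Ea1", "n1"))


def autocatalytic_spec() -> ModelSpec:
    """Prout-Tompkins-type step: both n and m free, giving S-shaped kinetics."""
    return _one_step("autocatalytic", {}, ("lnA1", "Ea1", "n1", "m1"))


def two_step_spec() -> ModelSpec:
    """Competitive two-step model: both steps fully free plus the weight v."""
    return ModelSpec(
        "two-step",
        "two-step",
        dict(_NO_CONC),
        ("lnA1", "Ea1", "n1", "m1", "lnA2", "Ea2", "n2", "m2", "v"),
        {},
    )


@dataclass
class ModelCatalog:
    """Ordered list of candidate models screened against a dataset."""

    specs: list

    def __iter__(self) -> Iterator[ModelSpec]:
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def get(self, name: str) -> ModelSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps([s.to_dict() for s in self.specs], indent=2)

    def to_yaml(self) -> str:
        return yaml.safe_dump([s.to_dict() for s in self.specs], sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "ModelCatalog":
        return cls([ModelSpec.from_dict(d) for d in json.loads(text)])

    @classmethod
    def from_yaml(cls, text: str) -> "ModelCatalog":
        return cls([ModelSpec.from_dict(d) for d in yaml.safe_load(text)])


def default_catalog(concentration_dependent: bool = False) -> ModelCatalog:
    """The standard screening catalog, simplest model first.

    With ``concentration_dependent=True`` every entry additionally frees the
    step-1 concentration exponent ``p1`` (and ``p2`` for the two-step model)
    for joint fits across protein concentrations.
    """
    specs = [
        zero_order_spec(),
        first_order_spec(),
        nth_order_spec(),
        autocatalytic_spec(),
        two_step_spec(),
    ]
    if concentration_dependent:
        out = []
        for s in specs:
            names = ("p1", "p2") if s.structure == "two-step" else ("p1",)
            out.append(s.with_free(*names))
        specs = out
    return ModelCatalog(specs)
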