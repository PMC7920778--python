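"""Parameter and state containers for the two-species mating/competition model.

The community couples two ecologically neutral species (labelled ``X`` and
``Y``) through resource competition and through reproductive interference
mediated by a two-stage mating decision tree: a virgin female accepts a male
of species *j* with probability ``p_{i|j}``, a once-mated female with
probability ``q_{i|j}``.  Conspecific sperm precedence (CSP) means a female
realises full conspecific fecundity as soon as she has mated with at least
one conspecific male, regardless of mating order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "MatingProbabilities",
    "CommunityParams",
    "CommunityState",
    "FIG3_PROBS",
    "load_params",
    "params_from_dict",
]

_PROB_FIELDS = ("pXX", "pXY", "pYX", "pYY", "qXX", "qYY", "qXY", "qYX")


def _check_unit_interval(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class MatingProbabilities:
    """Acceptance probabilities of the mating decision tree.

    ``pXX`` is the probability that a virgin X-female accepts an X-male,
    ``pXY`` that she accepts a Y-male; ``qXX`` the probability that a
    once-mated X-female accepts a further X-male.  Mirror fields for Y.
    The heterospecific remating probabilities ``qXY``/``qYX`` do not enter
    the expected-fecundity formula (under CSP they are fecundity-neutral
    once a conspecific mating occurred, and irrelevant otherwise); they are
    used by the stochastic simulator and the many-matings chain, and default
    to the conspecific remating probability of the same female.
    """

    pXX: float = 0.4
    pXY: float = 0.8
    pYX: float = 0.4
    pYY: float = 0.8
    qXX: float = 0.4
    qYY: float = 0.8
    qXY: float | None = None
    qYX: float | None = None

    def __post_init__(self) -> None:
        if self.qXY is None:
            object.__setattr__(self, "qXY", self.qXX)
        if self.qYX is None:
            object.__setattr__(self, "qYX", self.qYY)
        for name in _PROB_FIELDS:
            _check_unit_interval(name, getattr(self, name))

    def for_female(self, focal: str) -> tuple[float, float, float, float]:
        """Return (p_con, p_het, q_con, q_het) for a female of ``focal`` species."""
        if focal == "X":
            return self.pXX, self.pXY, self.qXX, self.qXY
        if focal == "Y":
            return self.pYY, self.pYX, self.qYY, self.qYX
        raise ValueError(f"species label must be 'X' or 'Y', got {focal!r}")


#: The probability set used for the model's worked phase portraits
#: (pXX=0.4, qXX=0.4, pXY=0.8, pYY=0.8, pYX=0.4, qYY=0.8): species Y is the
#: superior reproductive interferer.
FIG3_PROBS = MatingProbabilities()


@dataclass(frozen=True)
class CommunityParams:
    """Demographic and interaction parameters of the community model.

    Parameters
    ----------
    c:
        Niche overlap in [0, 1]: the probability that a female is subject to
        the interspecific mating decision tree at all.
    r:
        Per-capita egg production (>= 1).  Default 25.
    v:
        Density-dependence coefficient of resource competition (> 0).
        Default 1.
    b:
        Relative strength of interspecific resource competition in [0, 1].
        Default 0.3.
    probs:
        Acceptance probabilities of the decision tree.
    aX, aY:
        Male encounter-activity weights (> 0).  Encounters are conspecific
        with probability aX*NX / (aX*NX + aY*NY) for an X-female's
        perspective of X-males, so activity biases encounter rates relative
        to raw frequency.  Default 1 (unbiased).
    """

    c: float
    r: float = 25.0
    v: float = 1.0
    b: float = 0.3
    probs: MatingProbabilities = field(default_factory=MatingProbabilities)
    aX: float = 1.0
    aY: float = 1.0

    def __post_init__(self) -> None:
        if self.r < 1.0:
            raise ValueError(f"r must be >= 1, got {self.r!r}")
        if self.v <= 0.0:
            raise ValueError(f"v must be > 0, got {self.v!r}")
        _check_unit_interval("b", self.b)
        _check_unit_interval("c", self.c)
        if self.aX <= 0.0 or self.aY <= 0.0:
            raise ValueError("activity weights aX, aY must be > 0")

    @property
    def carrying_density(self) -> float:
        """Single-species equilibrium density r/v."""
        return self.r / self.v

    def swapped(self) -> "CommunityParams":
        """Parameters with the species labels X and Y exchanged."""
        p = self.probs
        return replace(
            self,
            probs=MatingProbabilities(
                pXX=p.pYY, pXY=p.pYX, pYX=p.pXY, pYY=p.pXX,
                qXX=p.qYY, qYY=p.qXX, qXY=p.qYX, qYX=p.qXY,
            ),
            aX=self.aY,
            aY=self.aX,
        )


@dataclass(frozen=True)
class CommunityState:
    """Population densities (NX, NY), dimensionless and non-negative."""

    NX: float
    NY: float

    def __post_init__(self) -> None:
        if self.NX < 0.0 or self.NY < 0.0:
            raise ValueError(
                f"densities must be non-negative, got ({self.NX!r}, {self.NY!r})"
            )

    @property
    def total(self) -> float:
        return self.NX + self.NY

    @property
    def fX(self) -> float:
        """Frequency of species X; undefined at the origin."""
        if self.total == 0.0:
            raise ValueError("species frequency is undefined at the origin")
        return self.NX / self.total

    def as_array(self):
        import numpy as np

        return np.array([self.NX, self.NY], dtype=float)


def params_from_dict(config: Mapping[str, float]) -> CommunityParams:
    """Build :class:`CommunityParams` from a flat key/value mapping.

    Recognised keys: ``r, v, b, c, pXX, pXY, pYX, pYY, qXX, qYY, qXY, qYX,
    aX, aY``.  Unspecified demographic keys take the model defaults
    (r=25, v=1, b=0.3, activities 1); unspecified acceptance probabilities
    take the worked-example set (:data:`FIG3_PROBS`).  ``c`` has no default
    and must be present.
    """
    known = {"r", "v", "b", "c", "aX", "aY", *_PROB_FIELDS}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "c" not in config:
        raise ValueError("config must specify the niche overlap 'c'")
    prob_kwargs = {k: float(config[k]) for k in _PROB_FIELDS if k in config}
    other = {
        k: float(config[k]) for k in ("r", "v", "b", "c", "aX", "aY") if k in config
    }
    return CommunityParams(probs=MatingProbabilities(**prob_kwargs), **other)


def load_params(path: str | Path) -> CommunityParams:
    """Read model parameters from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return params_from_dict(config)
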