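"""Parameter containers shared across the forward model, inversion and simulator.

The model world is a population of couples.  Family size ``N`` is Poisson
with mean ``lam`` (children per couple); each birth is a girl with the
natural propensity ``p`` unless a sex-selective intervention forces it male.
The intervention rule is described by a :class:`ModelSpec`: either a
*universal threshold* (sonless families intervene at birth order ``n``) or
the *stopping rule* (sonless families intervene at their last birth,
provided the family has at least ``n`` children).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "NaturalBirthParams",
    "Variant",
    "ModelSpec",
    "PopulationRates",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True)
class NaturalBirthParams:
    """Natural probability ``p`` that a birth is female absent intervention.

    The default 0.486 corresponds to the commonly cited natural sex ratio
    at birth of roughly 946 girls per 1000 boys (105.8 boys per 100 girls),
    i.e. it satisfies p/(1-p) ~= 0.946.
    """

    p: float = 0.486

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie strictly inside (0, 1), got {self.p}")

    @property
    def boys_per_100_girls(self) -> float:
        """Natural benchmark SRB expressed as boys per 100 girls."""
        return 100.0 * (1.0 - self.p) / self.p

    @property
    def girls_per_1000_boys(self) -> float:
        """Natural benchmark SRB expressed as girls per 1000 boys."""
        return 1000.0 * self.p / (1.0 - self.p)


class Variant(str, enum.Enum):
    """Which behavioural rule triggers a sex-selective intervention."""

    UNIVERSAL = "universal"
    STOPPING_RULE = "stopping_rule"

    @classmethod
    def coerce(cls, value: "Variant | str") -> "Variant":
        if isinstance(value, cls):
            return value
        key = str(value).lower().replace("-", "_")
        aliases = {"stopping": cls.STOPPING_RULE, "stopping_rule": cls.STOPPING_RULE,
                   "universal": cls.UNIVERSAL}
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(
                f"unknown variant {value!r}; expected 'universal' or 'stopping_rule'"
            ) from None


@dataclass(frozen=True)
class ModelSpec:
    """Intervention variant plus the birth-order threshold ``n``.

    Under ``universal``, sonless families with at least ``n`` children force
    birth ``n`` male.  Under ``stopping_rule``, sonless families of size
    ``N >= n`` force their *last* birth male; ``n`` is then the minimum
    family size at which anyone intervenes.
    """

    variant: Variant
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant.coerce(self.variant))
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"threshold n must be an integer >= 1, got {self.n}")
        object.__setattr__(self, "n", int(self.n))


@dataclass(frozen=True)
class PopulationRates:
    """Mean number of children per couple (the Poisson mean, children/couple)."""

    lam: float

    def __post_init__(self) -> None:
        if not (self.lam >= 0.0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be finite and >= 0, got {self.lam}")


DEFAULT_PARAMS = NaturalBirthParams()
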