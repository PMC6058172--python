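"""Model-object facade over the closed forms and the simulator.

:class:`SexSelectionModel` bundles an intervention rule (variant + threshold
n) with the natural girl-birth propensity p, and exposes prediction, λ-scans,
peak finding and cohort simulation as methods.  The heavy lifting lives in
:mod:`srbsel.forward` and :mod:`srbsel.simulate`.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from . import forward
from .params import ModelSpec, NaturalBirthParams, Variant
from .simulate import CohortResult, simulate_abortion_variant, simulate_cohort

__all__ = ["SexSelectionModel"]


class SexSelectionModel:
    """Family-composition model with a sex-selective intervention rule.

    Parameters
    ----------
    n : int
        Intervention threshold: birth order of intervention (universal) or
        minimum family size at which sonless couples intervene (stopping
        rule).
    variant : {"stopping_rule", "universal"}
    p : float
        Natural probability of a female birth, default 0.486.
    """

    def __init__(self, n: int, variant: Variant | str = Variant.STOPPING_RULE,
                 p: float = 0.486):
        self.spec = ModelSpec(Variant.coerce(variant), n)
        self.params = NaturalBirthParams(p)

    @property
    def n(self) -> int:
        return self.spec.n

    @property
    def variant(self) -> Variant:
        return self.spec.variant

    @property
    def p(self) -> float:
        return self.params.p

    @property
    def apfb(self) -> float:
        """Acceptable proportion of female births implied by n, percent."""
        return forward.apfb(self.spec.n)

    def predict(self, lam: float) -> forward.ModelPrediction:
        """Expected per-couple composition and SRB at mean family size lam."""
        return forward.predict(lam, self.spec, self.params)

    def scan(self, lams: Iterable[float]) -> pd.DataFrame:
        """Forward predictions over a λ grid (plot-ready data frame)."""
        lams = np.asarray(list(lams), dtype=float)
        rows = [self.predict(l) for l in lams]
        return pd.DataFrame(
            {
                "lam": lams,
                "e_boys": [r.e_boys for r in rows],
                "e_girls": [r.e_girls for r in rows],
                "r_prop": [r.r_prop for r in rows],
                "r_b100g": [r.r_b100g for r in rows],
                "phi": [r.phi for r in rows],
                "psi": [r.psi for r in rows],
            }
        )

    def peak(self, quantity: str = "srb", lam_hi: float = 20.0,
             xatol: float = 1e-4) -> forward.PeakResult:
        """(argmax λ, max value) of SRB or phi over mean family size."""
        return forward.peak_over_lambda(
            self.spec.n, self.params, quantity=quantity,
            variant=self.spec.variant, lam_hi=lam_hi, xatol=xatol,
        )

    def simulate(self, n_couples: int, lam: float, seed: int | None = None,
                 mechanism: str = "preconception") -> CohortResult:
        """Monte Carlo cohort under this rule; the independent oracle."""
        if mechanism == "preconception":
            return simulate_cohort(n_couples, lam, self.spec, self.params, seed=seed)
        if mechanism == "abortion":
            return simulate_abortion_variant(
                n_couples, lam, self.spec, self.params, seed=seed
            )
        raise ValueError(
            f"mechanism must be 'preconception' or 'abortion', got {mechanism!r}"
        )

    def __repr__(self) -> str:
        return (
            f"SexSelectionModel(n={self.spec.n}, variant={self.spec.variant.value!r}, "
            f"p={self.params.p})"
        )
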