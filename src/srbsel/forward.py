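"""Closed-form forward model: expected family composition and SRB.

For Poisson family sizes ``N ~ Poisson(lam)`` and girl-birth probability
``p``, a sex-selective intervention forces one designated birth male in a
"sonless-so-far" family.  The two behavioural variants differ only in the
probability that a family of size ``N`` intervenes:

* universal threshold ``n``:   the first ``n-1`` births are all girls,
  probability ``p**(n-1)``, for every ``N >= n`` (intervention at birth n);
* stopping rule (minimum ``n``): the first ``N-1`` births are all girls,
  probability ``p**(N-1)``, intervention at the last birth.

Each intervention adds on average ``p`` boys per intervening couple (the
forced birth would have been a girl with probability ``p``), so with
intervening-couple fraction ``phi`` the expected composition is

    E[boys]  = lam*(1-p) + p*phi,      E[girls] = lam*p - p*phi,

and total expected births ``lam`` are conserved.  The stopping-rule sum
``S = sum_{N>=n} Poisson(N; lam) p**N`` is evaluated through the Poisson
survival function, ``S = exp(lam*(p-1)) * P(Poisson(lam*p) >= n)``, which
is stable for large ``lam*p`` (no catastrophic cancellation of partial
exponential sums).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .params import DEFAULT_PARAMS, ModelSpec, NaturalBirthParams, PopulationRates, Variant

__all__ = [
    "ModelPrediction",
    "PeakResult",
    "PeakBoundaryWarning",
    "natural_srb",
    "apfb",
    "family_size_pmf",
    "predict",
    "predict_universal",
    "predict_stopping",
    "psi_from_phi",
    "peak_over_lambda",
    "expected_abortion_interventions",
]


@dataclass(frozen=True)
class ModelPrediction:
    """Expected per-couple composition and derived population ratios."""

    lam: float
    p: float
    e_boys: float
    e_girls: float
    phi: float
    degenerate: bool = False

    @property
    def r_prop(self) -> float:
        """Proportion of births that are male (canonical SRB representation)."""
        if self.lam == 0.0:
            return math.nan
        return self.e_boys / (self.e_boys + self.e_girls)

    @property
    def r_b100g(self) -> float:
        """SRB as boys per 100 girls; +inf in the degenerate regime."""
        if self.lam == 0.0:
            return math.nan
        if self.e_girls <= 0.0:
            return math.inf
        return 100.0 * self.e_boys / self.e_girls

    @property
    def psi(self) -> float:
        """Intervening fraction among parents (couples with >= 1 child)."""
        if self.lam == 0.0:
            return 0.0
        return self.phi / (-math.expm1(-self.lam))


class PeakBoundaryWarning(UserWarning):
    """The maximized quantity had no interior peak on the search interval."""


@dataclass(frozen=True)
class PeakResult:
    lam: float
    value: float
    at_boundary: bool = False

    def __iter__(self):  # allows ``lam_star, value = peak_over_lambda(...)``
        yield self.lam
        yield self.value


def natural_srb(params: NaturalBirthParams = DEFAULT_PARAMS) -> tuple[float, float]:
    """Benchmark sex ratios implied by ``p`` alone.

    Returns
    -------
    (boys_per_100_girls, girls_per_1000_boys)
        ``100*(1-p)/p`` and ``1000*p/(1-p)``; for the default p=0.486 these
        are 105.76 and 945.5 (the conventional "946 girls per 1000 boys").
    """
    return params.boys_per_100_girls, params.girls_per_1000_boys


def apfb(n: int) -> float:
    """Acceptable proportion of female births, percent: ``100 - 100/n``.

    Guilmoto's reparameterization of the intervention threshold: the share
    of female births a couple with threshold ``n`` tolerates before
    intervening (0% at n=1, 50% at n=2, 75% at n=4).
    """
    if int(n) != n or n < 1:
        raise ValueError(f"threshold n must be an integer >= 1, got {n}")
    return 100.0 - 100.0 / int(n)


def family_size_pmf(rates: PopulationRates, n_max: int | None = None) -> np.ndarray:
    """Poisson(lam) family-size probabilities for N = 0..n_max.

    When ``n_max`` is omitted it is chosen so the truncated tail mass is
    below 1e-12 (via the Poisson quantile function).
    """
    lam = _as_lam(rates)
    if n_max is None:
        n_max = int(stats.poisson.ppf(1.0 - 1e-13, lam)) + 1 if lam > 0 else 0
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    return stats.poisson.pmf(np.arange(n_max + 1), lam)


def _as_lam(rates: PopulationRates | float) -> float:
    if isinstance(rates, PopulationRates):
        return rates.lam
    return PopulationRates(float(rates)).lam


def _excess_boys_universal(lam, n: int, p: float):
    """p**n * P(N >= n): expected sex-converted births per couple, Model A."""
    return p**n * stats.poisson.sf(n - 1, lam)


def _excess_boys_stopping(lam, n: int, p: float):
    """sum_{N>=n} Poisson(N; lam) p**N, evaluated via the Poisson tail."""
    return np.exp(lam * (p - 1.0)) * stats.poisson.sf(n - 1, lam * p)


def _predict_arrays(lam, n: int, p: float, variant: Variant):
    """Vectorized (e_boys, e_girls, phi) over an array of lam values."""
    lam = np.asarray(lam, dtype=float)
    if variant is Variant.UNIVERSAL:
        extra = _excess_boys_universal(lam, n, p)
    else:
        extra = _excess_boys_stopping(lam, n, p)
    phi = extra / p
    e_boys = lam * (1.0 - p) + extra
    e_girls = lam * p - extra
    return e_boys, e_girls, phi


def predict(
    rates: PopulationRates | float,
    spec: ModelSpec,
    params: NaturalBirthParams = DEFAULT_PARAMS,
) -> ModelPrediction:
    """Forward prediction for a single (lam, variant, n, p) configuration."""
    lam = _as_lam(rates)
    e_boys, e_girls, phi = (
        float(x) for x in _predict_arrays(lam, spec.n, params.p, spec.variant)
    )
    degenerate = lam > 0.0 and e_girls <= 0.0
    return ModelPrediction(
        lam=lam, p=params.p, e_boys=e_boys, e_girls=e_girls, phi=phi,
        degenerate=degenerate,
    )


def predict_universal(
    rates: PopulationRates | float,
    n: int,
    params: NaturalBirthParams = DEFAULT_PARAMS,
) -> ModelPrediction:
    """Universal-threshold variant: sonless families force birth ``n`` male."""
    return predict(rates, ModelSpec(Variant.UNIVERSAL, n), params)


def predict_stopping(
    rates: PopulationRates | float,
    n: int,
    params: NaturalBirthParams = DEFAULT_PARAMS,
) -> ModelPrediction:
    """Stopping-rule variant: sonless families of size >= n force their last birth male."""
    return predict(rates, ModelSpec(Variant.STOPPING_RULE, n), params)


def psi_from_phi(phi: float, rates: PopulationRates | float) -> float:
    """Convert the all-couples fraction phi to the parents-only fraction psi.

    psi = phi / (1 - exp(-lam)); requires lam > 0 and phi not exceeding the
    fraction of couples that have any children.
    """
    lam = _as_lam(rates)
    if lam <= 0.0:
        raise ValueError("psi is undefined for lam = 0 (no parents)")
    parent_frac = -math.expm1(-lam)
    if not (0.0 <= phi <= parent_frac + 1e-12):
        raise ValueError(
            f"phi={phi} outside [0, 1 - exp(-lam)] = [0, {parent_frac:.6g}]"
        )
    return phi / parent_frac


def expected_abortion_interventions(
    phi: float, params: NaturalBirthParams = DEFAULT_PARAMS
) -> float:
    """Expected sex-selective abortions per couple under the abortion mechanism.

    Each intervening couple re-conceives until a male fetus, aborting each
    diagnosed female fetus: a geometric process with mean ``p/(1-p)``
    abortions per intervening couple, hence ``phi * p/(1-p)`` per couple
    overall.  For p near one half this is close to phi itself, i.e. close
    to one preconception intervention per intervening couple.
    """
    if not (0.0 <= phi <= 1.0):
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    return phi * params.p / (1.0 - params.p)


_QUANTITY_KEYS = ("srb", "phi")


def peak_over_lambda(
    n: int,
    params: NaturalBirthParams = DEFAULT_PARAMS,
    quantity: str = "srb",
    variant: Variant | str = Variant.STOPPING_RULE,
    lam_hi: float = 20.0,
    xatol: float = 1e-4,
) -> PeakResult:
    """Locate the maximum of SRB or phi over mean family size lam.

    A coarse grid (step 0.05 on (0, lam_hi]) brackets the maximum, which is
    then refined by bounded scalar maximization to absolute lam tolerance
    ``xatol``.  If the grid argmax sits on either end of the interval the
    quantity is monotone there; the boundary solution is returned with a
    :class:`PeakBoundaryWarning`.
    """
    if quantity not in _QUANTITY_KEYS:
        raise ValueError(f"quantity must be one of {_QUANTITY_KEYS}, got {quantity!r}")
    spec = ModelSpec(Variant.coerce(variant), n)

    def objective(lam):
        e_boys, e_girls, phi = _predict_arrays(lam, spec.n, params.p, spec.variant)
        if quantity == "phi":
            return phi
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(e_girls > 0.0, 100.0 * e_boys / e_girls, np.inf)

    grid = np.arange(0.05, lam_hi + 1e-9, 0.05)
    values = objective(grid)
    i = int(np.argmax(values))
    if i == 0 or i == len(grid) - 1:
        warnings.warn(
            f"{quantity} has no interior peak on (0, {lam_hi}]: "
            "returning the boundary solution",
            PeakBoundaryWarning,
            stacklevel=2,
        )
        return PeakResult(float(grid[i]), float(values[i]), at_boundary=True)

    res = optimize.minimize_scalar(
        lambda lam: -float(objective(np.asarray(lam))),
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": xatol},
    )
    return PeakResult(float(res.x), float(-res.fun), at_boundary=False)
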