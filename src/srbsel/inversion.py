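"""Estimating sex-selection propensity from observed SRB and fertility.

The forward model's birth accounting is, for any intervening-couple
fraction phi (each intervention converts a would-be girl with probability
p),

    E[boys]  = lam*(1-p) + p*phi,
    E[girls] = lam*p     - p*phi.

Given an observed sex ratio r = boys/girls and fertility lam (total
fertility rate used as the mean completed family size) this solves for the
unique consistent phi,

    phi = lam * (p*r - (1-p)) / (p * (1 + r)),

without committing to a particular threshold n: under the stopping rule the
same accounting holds for every n, so phi is an *effective* population
propensity.  Batch estimation over a table of (region, period, TFR, SRB)
records additionally fits an ordinary-least-squares line of phi on SRB, so
regions above or below the mean phi-given-SRB relationship can be
identified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import DEFAULT_PARAMS, NaturalBirthParams, PopulationRates

__all__ = [
    "Observation",
    "PropensityEstimate",
    "DegenerateRatioWarning",
    "phi_from_observation",
    "srb_at_fixed_phi",
    "batch_estimate",
    "PropensityModel",
    "PropensityResults",
]


class DegenerateRatioWarning(UserWarning):
    """The requested (phi, lam) pair implies a non-positive expected girl count."""


@dataclass(frozen=True)
class Observation:
    """One (region/period, fertility, SRB) record.

    ``srb`` is always stored as boys per 100 girls; unit conversion from
    proportion-male inputs happens at the I/O boundary.
    """

    label: str
    period: str
    tfr: float
    srb: float

    def __post_init__(self) -> None:
        if not (self.tfr > 0.0 and math.isfinite(self.tfr)):
            raise ValueError(f"{self.label!r}: tfr must be finite and > 0, got {self.tfr}")
        if not (self.srb > 0.0 and math.isfinite(self.srb)):
            raise ValueError(f"{self.label!r}: srb must be finite and > 0, got {self.srb}")


@dataclass(frozen=True)
class PropensityEstimate:
    """Estimated intervening fractions for one observation.

    ``phi_raw`` keeps the signed solution of the balance equation; ``phi``
    is clipped at zero when the observed SRB sits below the natural
    benchmark (the model has no female-favouring intervention).
    ``implausible`` flags phi_raw > 1, which no couple-fraction can reach.
    """

    label: str
    period: str
    tfr: float
    srb: float
    phi: float
    psi: float
    excess_boys_per_couple: float
    phi_raw: float
    below_benchmark: bool
    implausible: bool


def phi_from_observation(
    obs: Observation, params: NaturalBirthParams = DEFAULT_PARAMS
) -> PropensityEstimate:
    """Invert one (SRB, fertility) pair into an intervening-couple fraction."""
    p = params.p
    r = obs.srb / 100.0
    phi_raw = obs.tfr * (p * r - (1.0 - p)) / (p * (1.0 + r))
    below = phi_raw < 0.0
    implausible = phi_raw > 1.0
    phi = 0.0 if below else phi_raw
    # psi computed directly (not via psi_from_phi) so implausible records
    # surface as psi > 1 instead of raising mid-batch
    psi = phi / -math.expm1(-obs.tfr)
    return PropensityEstimate(
        label=obs.label,
        period=obs.period,
        tfr=obs.tfr,
        srb=obs.srb,
        phi=phi,
        psi=psi,
        excess_boys_per_couple=p * phi,
        phi_raw=phi_raw,
        below_benchmark=below,
        implausible=implausible,
    )


def srb_at_fixed_phi(
    phi: float,
    rates: PopulationRates | float,
    params: NaturalBirthParams = DEFAULT_PARAMS,
) -> float:
    """SRB (boys per 100 girls) implied by holding phi fixed while lam varies.

    Exact inverse of :func:`phi_from_observation`.  At fixed phi > 0 the
    SRB grows as lam shrinks — the disproportionality effect: the same
    number of converted births weighs more in a smaller birth cohort.
    Returns +inf with a :class:`DegenerateRatioWarning` when the implied
    expected girl count is non-positive.
    """
    lam = rates.lam if isinstance(rates, PopulationRates) else float(rates)
    if phi < 0.0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    if lam <= 0.0:
        raise ValueError(f"lam must be > 0, got {lam}")
    p = params.p
    e_boys = lam * (1.0 - p) + p * phi
    e_girls = lam * p - p * phi
    if e_girls <= 0.0:
        warnings.warn(
            f"phi={phi} at lam={lam} implies no surviving girl births",
            DegenerateRatioWarning,
            stacklevel=2,
        )
        return math.inf
    return 100.0 * e_boys / e_girls


class PropensityModel:
    """Batch propensity estimator over a series of observations.

    Statsmodels-style: construct from data, then :meth:`fit` returns a
    :class:`PropensityResults` carrying per-record estimates, the OLS line
    of phi on SRB across plausible records, and its residuals.
    """

    def __init__(
        self,
        observations: Sequence[Observation],
        params: NaturalBirthParams = DEFAULT_PARAMS,
    ):
        observations = list(observations)
        if not observations:
            raise ValueError("at least one observation is required")
        self.observations = observations
        self.params = params

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        params: NaturalBirthParams = DEFAULT_PARAMS,
        srb_unit: str = "b100g",
    ) -> "PropensityModel":
        """Build from a DataFrame with columns label, period, tfr, srb.

        ``srb_unit`` must be declared explicitly: ``"b100g"`` (boys per 100
        girls) or ``"prop"`` (proportion of births male).
        """
        from .io import convert_srb_to_b100g  # local import: io depends on this module

        missing = {"label", "period", "tfr", "srb"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        obs = [
            Observation(
                label=str(row.label),
                period=str(row.period),
                tfr=float(row.tfr),
                srb=convert_srb_to_b100g(float(row.srb), srb_unit),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(obs, params=params)

    def fit(self) -> "PropensityResults":
        estimates = [phi_from_observation(o, self.params) for o in self.observations]
        table = pd.DataFrame(
            {
                "label": [e.label for e in estimates],
                "period": [e.period for e in estimates],
                "tfr": [e.tfr for e in estimates],
                "srb": [e.srb for e in estimates],
                "phi": [e.phi for e in estimates],
                "psi": [e.psi for e in estimates],
                "excess_boys_per_couple": [e.excess_boys_per_couple for e in estimates],
                "phi_raw": [e.phi_raw for e in estimates],
                "below_benchmark": [e.below_benchmark for e in estimates],
                "implausible": [e.implausible for e in estimates],
            }
        )
        usable = ~table["implausible"]
        ols_res = None
        fitted = np.full(len(table), np.nan)
        if usable.sum() >= 2 and table.loc[usable, "srb"].nunique() > 1:
            X = sm.add_constant(table.loc[usable, "srb"].to_numpy())
            ols_res = sm.OLS(table.loc[usable, "phi"].to_numpy(), X).fit()
            fitted[usable.to_numpy()] = ols_res.fittedvalues
        elif usable.sum() >= 1:
            # single point or constant SRB: the "line" is the mean level
            fitted[usable.to_numpy()] = table.loc[usable, "phi"].mean()
        table["phi_fit"] = fitted
        table["residual"] = table["phi"] - table["phi_fit"]
        return PropensityResults(self, table, ols_res)


class PropensityResults:
    """Per-record propensity estimates plus the cross-record phi-on-SRB line."""

    def __init__(self, model: PropensityModel, estimates: pd.DataFrame, ols_result):
        self.model = model
        self.estimates = estimates
        self._ols = ols_result

    @property
    def params(self) -> NaturalBirthParams:
        return self.model.params

    @property
    def intercept(self) -> float:
        return float(self._ols.params[0]) if self._ols is not None else math.nan

    @property
    def slope(self) -> float:
        return float(self._ols.params[1]) if self._ols is not None else math.nan

    @property
    def resid(self) -> pd.Series:
        return self.estimates["residual"]

    def summary(self) -> str:
        t = self.estimates
        lines = [
            "Sex-selection propensity estimates "
            f"(benchmark p = {self.params.p:g}, "
            f"natural SRB = {self.params.boys_per_100_girls:.2f} boys/100 girls)",
            "",
            t.drop(columns=["phi_raw"]).to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
            "",
        ]
        if self._ols is not None:
            lines.append(
                f"OLS fit phi = {self.intercept:+.5f} {self.slope:+.6f} * SRB  "
                f"(n = {int(self._ols.nobs)}, R^2 = {self._ols.rsquared:.3f})"
            )
        n_flagged = int(t["implausible"].sum())
        if n_flagged:
            lines.append(f"{n_flagged} record(s) flagged implausible (phi > 1), excluded from fit")
        return "\n".join(lines)


def batch_estimate(
    series: Iterable[Observation],
    params: NaturalBirthParams = DEFAULT_PARAMS,
) -> PropensityResults:
    """Estimate phi/psi per record and the phi-on-SRB OLS line across records."""
    return PropensityModel(list(series), params=params).fit()
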