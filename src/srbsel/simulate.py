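"""Seeded Monte Carlo cohort simulator.

Implements the micro-level behavioural rules directly — per couple a
Poisson family size, sequential Bernoulli birth sexes, and the intervention
rule applied to the realized birth history — so it serves as an independent
oracle for every closed form in :mod:`srbsel.forward`.

Draw order is fixed and documented: the vector of family sizes first, then
the full matrix of natural birth outcomes (row = couple, column = birth
order), then, for the abortion mechanism, the geometric re-conception
counts of converted couples.  Identical inputs and seed therefore give a
bit-identical :class:`CohortResult`.

Standard errors use binomial / delta-method approximations:

* ``phi_hat``: sqrt(phi_hat * (1 - phi_hat) / n_couples);
* ``srb_b100g = 100 * B/G``: couples are i.i.d., so with per-couple boy and
  girl counts (b_i, g_i), sample moments give
  Var(B/G) ~= (var(b) - 2*(B/G)*cov(b,g) + (B/G)^2 * var(g)) / (n * mean(g)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .forward import predict_stopping
from .inversion import srb_at_fixed_phi
from .params import DEFAULT_PARAMS, ModelSpec, NaturalBirthParams, PopulationRates, Variant

__all__ = [
    "CohortResult",
    "Scenario",
    "simulate_cohort",
    "simulate_abortion_variant",
    "generate_observation_table",
]


@dataclass(frozen=True)
class CohortResult:
    """Aggregates of one simulated cohort of couples."""

    n_couples: int
    lam: float
    n: int
    variant: str
    p: float
    seed: int | None
    total_boys: int
    total_girls: int
    n_interventions: int
    n_converted: int
    n_parents: int
    se_srb: float
    # sex ratio at last vs earlier births among families with >= 2 children
    last_birth_boys: int
    last_birth_total: int
    earlier_birth_boys: int
    earlier_birth_total: int
    n_abortions: int | None = None

    @property
    def total_births(self) -> int:
        return self.total_boys + self.total_girls

    @property
    def srb_b100g(self) -> float:
        """Realized SRB, boys per 100 girls; NaN for an all-childless cohort."""
        if self.total_girls == 0:
            return math.nan if self.total_boys == 0 else math.inf
        return 100.0 * self.total_boys / self.total_girls

    @property
    def r_prop(self) -> float:
        if self.total_births == 0:
            return math.nan
        return self.total_boys / self.total_births

    @property
    def phi_hat(self) -> float:
        return self.n_interventions / self.n_couples

    @property
    def psi_hat(self) -> float:
        return self.n_interventions / self.n_parents if self.n_parents else math.nan

    @property
    def se_phi(self) -> float:
        ph = self.phi_hat
        return math.sqrt(ph * (1.0 - ph) / self.n_couples)

    @property
    def mean_abortions_per_intervening(self) -> float:
        if self.n_abortions is None or self.n_interventions == 0:
            return math.nan
        return self.n_abortions / self.n_interventions


def _simulate(
    n_couples: int,
    rates: PopulationRates | float,
    spec: ModelSpec,
    params: NaturalBirthParams,
    seed: int | None,
    count_abortions: bool,
) -> CohortResult:
    lam = rates.lam if isinstance(rates, PopulationRates) else PopulationRates(float(rates)).lam
    if n_couples < 1:
        raise ValueError(f"n_couples must be >= 1, got {n_couples}")
    p = params.p
    rng = np.random.default_rng(seed)

    N = rng.poisson(lam, n_couples)
    width = int(N.max()) if N.size else 0
    base = dict(
        n_couples=n_couples, lam=lam, n=spec.n, variant=spec.variant.value,
        p=p, seed=seed, n_parents=int((N > 0).sum()),
    )
    if width == 0:
        return CohortResult(
            **base, total_boys=0, total_girls=0, n_interventions=0, n_converted=0,
            se_srb=math.nan, last_birth_boys=0, last_birth_total=0,
            earlier_birth_boys=0, earlier_birth_total=0,
            n_abortions=0 if count_abortions else None,
        )

    girl = rng.random((n_couples, width)) < p  # natural outcome of each birth
    valid = np.arange(width)[None, :] < N[:, None]

    # all_girls_before[i, k]: births 0..k-1 of couple i are all girls
    prefix = np.cumprod(girl, axis=1).astype(bool)
    all_girls_before = np.empty_like(prefix)
    all_girls_before[:, 0] = True
    all_girls_before[:, 1:] = prefix[:, :-1]

    rows = np.arange(n_couples)
    if spec.variant is Variant.STOPPING_RULE:
        eligible = N >= spec.n
        forced_idx = np.where(eligible, N - 1, 0)
    else:
        eligible = N >= spec.n
        forced_idx = np.full(n_couples, spec.n - 1)
    intervene = eligible & all_girls_before[rows, forced_idx]
    converted = intervene & girl[rows, forced_idx]  # forced birth displaced a girl

    boy_final = ~girl
    boy_final[rows[intervene], forced_idx[intervene]] = True
    boy_final &= valid

    boys_i = boy_final.sum(axis=1)
    girls_i = N - boys_i

    total_boys = int(boys_i.sum())
    total_girls = int(girls_i.sum())

    # delta-method SE of 100*B/G from per-couple counts
    if total_girls > 0 and n_couples > 1:
        ratio = total_boys / total_girls
        cov = np.cov(boys_i, girls_i)
        g_bar = total_girls / n_couples
        var_ratio = (
            cov[0, 0] - 2.0 * ratio * cov[0, 1] + ratio**2 * cov[1, 1]
        ) / (n_couples * g_bar**2)
        se_srb = 100.0 * math.sqrt(max(var_ratio, 0.0))
    else:
        se_srb = math.nan

    # last-birth vs earlier-birth sex ratio among families with >= 2 children
    multi = N >= 2
    last_idx = np.where(multi, N - 1, 0)
    last_boys = int(boy_final[rows[multi], last_idx[multi]].sum())
    last_total = int(multi.sum())
    earlier_total = int((N[multi] - 1).sum())
    earlier_boys = int(boys_i[multi].sum()) - last_boys

    n_abortions: int | None = None
    if count_abortions:
        # converted couples abort the diagnosed female fetus and re-conceive
        # until a male one: total abortions per such couple ~ Geometric(1-p)
        # (number of conceptions up to and including the first male, minus
        # the male one, equals the number of trials of a fresh geometric).
        k = int(converted.sum())
        n_abortions = int(rng.geometric(1.0 - p, k).sum()) if k else 0

    return CohortResult(
        **base, total_boys=total_boys, total_girls=total_girls,
        n_interventions=int(intervene.sum()), n_converted=int(converted.sum()),
        se_srb=se_srb, last_birth_boys=last_boys, last_birth_total=last_total,
        earlier_birth_boys=earlier_boys, earlier_birth_total=earlier_total,
        n_abortions=n_abortions,
    )


def simulate_cohort(
    n_couples: int,
    rates: PopulationRates | float,
    spec: ModelSpec,
    params: NaturalBirthParams = DEFAULT_PARAMS,
    seed: int | None = None,
) -> CohortResult:
    """Simulate one cohort under the IVF-like (preconception) mechanism.

    Per couple: N ~ Poisson(lam); births are sequentially girls with
    probability p; the variant's rule decides whether one designated birth
    is forced male.  Each couple intervenes at most once.
    """
    return _simulate(n_couples, rates, spec, params, seed, count_abortions=False)


def simulate_abortion_variant(
    n_couples: int,
    rates: PopulationRates | float,
    spec: ModelSpec,
    params: NaturalBirthParams = DEFAULT_PARAMS,
    seed: int | None = None,
) -> CohortResult:
    """Simulate with female-selective abortion as the intervention mechanism.

    Birth outcomes are identical in distribution to :func:`simulate_cohort`
    (and identical in realization for the same seed); additionally counts
    the abortions incurred by couples whose designated birth carried a
    female fetus, who re-conceive geometrically until a male one.
    """
    return _simulate(n_couples, rates, spec, params, seed, count_abortions=True)


@dataclass(frozen=True)
class Scenario:
    """One synthetic region/period for :func:`generate_observation_table`.

    Exactly one of ``phi`` (a fixed effective propensity) or ``n`` (a
    stopping-rule threshold, from which phi follows) must be given.
    """

    label: str
    lam: float
    phi: float | None = None
    n: int | None = None
    period: str = "synthetic"

    def __post_init__(self) -> None:
        if (self.phi is None) == (self.n is None):
            raise ValueError(
                f"{self.label!r}: give exactly one of phi or n, "
                f"got phi={self.phi}, n={self.n}"
            )
        PopulationRates(self.lam)


def _simulate_fixed_phi(
    n_couples: int, lam: float, phi: float, p: float, rng: np.random.Generator
) -> tuple[int, int, float]:
    """Cohort where couples with children intervene independently w.p. psi.

    Forces the last birth of each intervening family male, so the expected
    composition matches the balance equations at the given phi exactly.
    Returns (boys, girls, se_srb).
    """
    parent_frac = -math.expm1(-lam)
    if not 0.0 <= phi <= parent_frac:
        raise ValueError(f"phi={phi} not attainable at lam={lam} (max {parent_frac:.4f})")
    psi = phi / parent_frac
    N = rng.poisson(lam, n_couples)
    width = int(N.max())
    girl = rng.random((n_couples, width)) < p
    valid = np.arange(width)[None, :] < N[:, None]
    intervene = (N > 0) & (rng.random(n_couples) < psi)
    rows = np.arange(n_couples)
    last_idx = np.where(N > 0, N - 1, 0)
    boy_final = ~girl
    boy_final[rows[intervene], last_idx[intervene]] = True
    boy_final &= valid
    boys_i = boy_final.sum(axis=1)
    girls_i = N - boys_i
    B, G = int(boys_i.sum()), int(girls_i.sum())
    ratio = B / G
    cov = np.cov(boys_i, girls_i)
    g_bar = G / n_couples
    var_ratio = (cov[0, 0] - 2 * ratio * cov[0, 1] + ratio**2 * cov[1, 1]) / (
        n_couples * g_bar**2
    )
    return B, G, 100.0 * math.sqrt(max(var_ratio, 0.0))


def generate_observation_table(
    scenarios: Sequence[Scenario] | Iterable[Scenario],
    params: NaturalBirthParams = DEFAULT_PARAMS,
    seed: int | None = None,
    mode: str = "deterministic",
    cohort: int = 100_000,
) -> pd.DataFrame:
    """Emit a synthetic observation table emulating national/state series.

    Deterministic mode writes the closed-form SRB for each scenario; noisy
    mode simulates a finite cohort per row.  Ground-truth phi is recorded
    alongside (``phi_true``) for recovery tests, and noisy rows carry the
    Monte Carlo ``se_srb`` so recovered phi can be judged against its
    sampling error.
    """
    if mode not in ("deterministic", "noisy"):
        raise ValueError(f"mode must be 'deterministic' or 'noisy', got {mode!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for sc in scenarios:
        if sc.phi is not None:
            phi_true = sc.phi
        else:
            phi_true = predict_stopping(sc.lam, sc.n, params).phi
        if mode == "deterministic":
            srb = srb_at_fixed_phi(phi_true, sc.lam, params)
            se = 0.0
        elif sc.n is not None:
            res = simulate_cohort(
                cohort, sc.lam, ModelSpec(Variant.STOPPING_RULE, sc.n), params,
                seed=int(rng.integers(2**31 - 1)),
            )
            srb, se = res.srb_b100g, res.se_srb
        else:
            B, G, se = _simulate_fixed_phi(cohort, sc.lam, phi_true, params.p, rng)
            srb = 100.0 * B / G
        rows.append(
            {"label": sc.label, "period": sc.period, "tfr": sc.lam, "srb": srb,
             "phi_true": phi_true, "se_srb": se}
        )
    return pd.DataFrame(rows)
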