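"""Two-population exponential growth model of tumor subclonal evolution.

A tumor starts from a single founder cell (MRCA0) at generation ``t0 = 0``
and grows exponentially at a net per-generation rate ``lambda_beta``.  At
generation ``tf`` one cell (MRCAf) acquires a fitness advantage quantified
by the selection coefficient ``s`` and seeds a derived subclone Kf growing
at rate ``lambda_beta * (1 + s)``; the remaining cells form the ancestral
clone Ka.  At the sampling generation ``te`` the subclone comprises a
fraction ``P`` of all tumor cells.

Somatic mutations are classified by where on the cell genealogy they arose:

``root``
    Preexist at t0; present in every tumor cell (cell fraction 1).
``trunk``
    Acquired on the foundation lineage (MRCA0 -> MRCAf) at generation
    ``t < tf``; present in all Kf cells and some Ka cells, with cell
    fraction ``fk(t) = P + (1 - P) * exp(-lambda_beta * t)``.
``branch``
    Acquired by the MRCAf cell at ``tf``; present in all Kf cells and no
    Ka cell, so their cell fraction is exactly ``P``.
``successive``
    Acquired inside Kf after ``tf``; cell fraction
    ``fs(t) = P * exp(-lambda_beta * (1 + s) * (t - tf))``.
``incidental``
    Acquired in Ka off the foundation lineage; a polyphyletic low-frequency
    tail, modelled here as neutral-lineage cohorts with expected fraction
    ``(1 - P) * exp(-lambda_beta * t)``.

All functions in this module are pure and deterministic; the stochastic
counterpart lives in :mod:`cloneclock.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DEATH_RATE",
    "EvolutionParams",
    "MutationClass",
    "net_growth_rate",
    "population_size",
    "subclone_fraction_forward",
    "solve_sampling_time",
    "expected_trunk_fraction",
    "trunk_mutation_count",
    "expected_successive_fraction",
    "expected_class_spectrum",
]

#: Per-daughter death probability used throughout the benchmark configuration.
DEFAULT_DEATH_RATE = 0.2


def net_growth_rate(death_rate: float) -> float:
    """Net per-generation growth rate ``lambda_beta = ln(2 * (1 - beta))``.

    Each division yields two daughters, each surviving with probability
    ``1 - beta``, so the expected per-generation multiplication factor of a
    clone is ``2 * (1 - beta)``.  ``beta`` must lie in ``[0, 0.5)`` for the
    population to be supercritical.
    """
    if not 0.0 <= death_rate < 0.5:
        raise ValueError(
            f"death_rate must be in [0, 0.5) for positive net growth, got {death_rate}"
        )
    return math.log(2.0 * (1.0 - death_rate))


class MutationClass(str, Enum):
    """Exhaustive, mutually exclusive genealogical classes of a mutation."""

    ROOT = "root"
    TRUNK = "trunk"
    BRANCH = "branch"
    INCIDENTAL = "incidental"
    SUCCESSIVE = "successive"


@dataclass
class EvolutionParams:
    """Full parameter vector of one tumor.

    Parameters
    ----------
    mu
        Mutations per diploid genome per cell division (>= 0).
    s
        Selection coefficient: relative increase of the subclone's net
        growth rate over the ancestral clone (> 0 for a true subclone).
    tf
        Subclone emergence time, in generations after t0 (> 0).
    te
        Sampling time, in generations after t0 (> tf).
    lambda_beta
        Net per-generation growth rate of the ancestral clone; derived from
        ``death_rate`` when not given explicitly.
    death_rate
        Per-daughter death probability beta in [0, 0.5).
    P
        Fraction of tumor cells belonging to the subclone at ``te``.

    Times are in generations (one cell-division interval) since the founder
    cell; t0 is pinned at 0.
    """

    mu: float | None = None
    s: float | None = None
    tf: float | None = None
    te: float | None = None
    lambda_beta: float | None = None
    death_rate: float | None = None
    P: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_beta is None and self.death_rate is not None:
            self.lambda_beta = net_growth_rate(self.death_rate)
        if self.mu is not None and self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.tf is not None and self.tf <= 0:
            raise ValueError(f"tf must be > 0, got {self.tf}")
        if self.te is not None and self.tf is not None and self.te <= self.tf:
            raise ValueError(f"te must exceed tf, got te={self.te} tf={self.tf}")
        if self.lambda_beta is not None and self.lambda_beta <= 0:
            raise ValueError(f"lambda_beta must be > 0, got {self.lambda_beta}")
        if self.P is not None and not 0.0 <= self.P <= 1.0:
            raise ValueError(f"P must lie in [0, 1], got {self.P}")

    @property
    def is_complete(self) -> bool:
        """True when every one of (mu, s, tf, te, P) is set and finite."""
        vals = (self.mu, self.s, self.tf, self.te, self.P)
        return all(v is not None and np.isfinite(v) for v in vals)

    def logit_residual(self) -> float:
        """Residual of the logit identity linking (P, s, tf, te, lambda_beta).

        For a deterministic trajectory ``ln(P / (1 - P)) = lambda_beta *
        (s * te - (1 + s) * tf)``.  Parameter sets closed through
        :func:`solve_sampling_time` satisfy this to machine precision;
        stochastic simulator truths satisfy it only in expectation.
        """
        if not self.is_complete or self.lambda_beta is None:
            raise ValueError("logit residual requires all of P, s, tf, te, lambda_beta")
        if not 0.0 < self.P < 1.0:
            raise ValueError("logit residual undefined for P in {0, 1}")
        lhs = math.log(self.P / (1.0 - self.P))
        rhs = self.lambda_beta * (self.s * self.te - (1.0 + self.s) * self.tf)
        return lhs - rhs

    def evolve(self, **changes) -> "EvolutionParams":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Deterministic expectations
# ---------------------------------------------------------------------------

def population_size(t: float, params: EvolutionParams) -> float:
    """Expected number of cells descended from the founder at generation ``t``.

    ``N(t) = exp(lambda_beta * t)`` with t0 = 0; equals 1 at t = 0 and is
    strictly increasing in ``t``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0 (t0 = 0), got {t}")
    if params.lambda_beta is None:
        raise ValueError("params.lambda_beta is required")
    return math.exp(params.lambda_beta * t)


def subclone_fraction_forward(params: EvolutionParams, N: float) -> float:
    """Subclone fraction ``P = exp(lambda_beta * (1 + s) * (te - tf)) / N``.

    ``N`` is the total tumor cell count at the sampling time ``te``; it must
    be at least the subclone's own size, otherwise the parameters are
    inconsistent.
    """
    for name in ("s", "tf", "te"):
        if getattr(params, name) is None:
            raise ValueError(f"params.{name} is required")
    if params.lambda_beta is None:
        raise ValueError("params.lambda_beta is required")
    kf = math.exp(params.lambda_beta * (1.0 + params.s) * (params.te - params.tf))
    p = kf / N
    if p > 1.0 + 1e-9:
        raise ValueError(
            f"inconsistent parameters: subclone size {kf:.6g} exceeds total N={N:.6g}"
        )
    return min(p, 1.0)


def solve_sampling_time(P: float, s: float, tf: float, lambda_beta: float) -> float:
    """Sampling time ``te`` implied by the clone-ratio identity.

    Inverts ``ln(P / (1 - P)) = lambda_beta * (s * te - (1 + s) * tf)``:

    ``te = [ln(P / (1 - P)) / lambda_beta + (1 + s) * tf] / s``

    A neutral subclone (s = 0) never changes the clone ratio, so ``te`` is
    undetermined; P at the boundaries {0, 1} makes the logit diverge.
    """
    if s == 0:
        raise ZeroDivisionError(
            "s = 0: a neutral subclone has no determined sampling time te"
        )
    if not 0.0 < P < 1.0:
        raise ValueError(f"logit diverges for P in {{0, 1}}; got P={P}")
    if tf <= 0:
        raise ValueError(f"tf must be > 0, got {tf}")
    if lambda_beta <= 0:
        raise ValueError(f"lambda_beta must be > 0, got {lambda_beta}")
    return (math.log(P / (1.0 - P)) / lambda_beta + (1.0 + s) * tf) / s


def expected_trunk_fraction(t, P: float, lambda_beta: float):
    """Cell fraction at ``te`` of a trunk mutation acquired at generation ``t``.

    ``fk(t) = P + (1 - P) * exp(-lambda_beta * t)``: strictly decreasing in
    ``t`` from 1 toward the asymptote ``P``.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("acquisition generation t must be >= 0")
    if not 0.0 <= P < 1.0:
        raise ValueError(f"P must lie in [0, 1), got {P}")
    out = P + (1.0 - P) * np.exp(-lambda_beta * t)
    return float(out) if out.ndim == 0 else out


def trunk_mutation_count(t: float, mu: float) -> float:
    """Expected number of trunk mutations accumulated by generation ``t``.

    Mutations accrue linearly along the foundation lineage: ``Mk(t) = mu * t``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    return mu * t


def expected_successive_fraction(t, params: EvolutionParams):
    """Cell fraction at ``te`` of a successive mutation acquired at ``t >= tf``.

    ``fs(t) = P * exp(-lambda_beta * (1 + s) * (t - tf))``: equals ``P`` at
    ``t = tf`` and decays toward 0.  Accepts scalars or arrays.
    """
    for name in ("s", "tf", "P"):
        if getattr(params, name) is None:
            raise ValueError(f"params.{name} is required")
    if params.lambda_beta is None:
        raise ValueError("params.lambda_beta is required")
    t = np.asarray(t, dtype=float)
    if np.any(t < params.tf):
        raise ValueError("successive mutations post-date emergence: t must be >= tf")
    out = params.P * np.exp(-params.lambda_beta * (1.0 + params.s) * (t - params.tf))
    return float(out) if out.ndim == 0 else out


def expected_class_spectrum(
    params: EvolutionParams,
    min_fraction: float = 1e-4,
    max_generations: int = 10_000,
) -> pd.DataFrame:
    """Expected per-class cohorts of the mutation spectrum at sampling.

    Returns a DataFrame with columns ``mutation_class``, ``generation``,
    ``cell_fraction`` and ``expected_count``:

    * one root cohort at fraction 1 (count unmodelled: they preexist at t0);
    * one trunk cohort per generation ``1 .. ceil(tf) - 1``, each with
      expected count ``mu`` and fraction ``fk(t)``;
    * the branch cohort at exactly fraction ``P`` with expected count ``mu``;
    * successive cohorts for generations ``floor(tf) + 1 ..`` with count
      ``mu`` each, truncated once ``fs`` falls below ``min_fraction``;
    * incidental cohorts at ``(1 - P) * exp(-lambda_beta * t)`` (the
      residual low-frequency tail; per-cohort multiplicity unmodelled),
      likewise truncated at ``min_fraction``.

    Within each class, fractions are strictly ordered by generation.
    """
    if not params.is_complete:
        raise ValueError("expected_class_spectrum requires fully specified params")
    lam = params.lambda_beta
    P, s, tf, te, mu = params.P, params.s, params.tf, params.te, params.mu
    rows: list[tuple[str, float, float, float]] = []
    rows.append((MutationClass.ROOT.value, 0.0, 1.0, math.nan))

    n_trunk_gen = max(int(math.ceil(tf)) - 1, 0)
    for t in range(1, n_trunk_gen + 1):
        rows.append(
            (MutationClass.TRUNK.value, float(t), expected_trunk_fraction(t, P, lam), mu)
        )

    if s > 0 and P > 0:
        rows.append((MutationClass.BRANCH.value, float(tf), float(P), mu))
        t = math.floor(tf) + 1
        while t <= min(te, tf + max_generations):
            fs = expected_successive_fraction(float(t), params)
            if fs < min_fraction:
                break
            rows.append((MutationClass.SUCCESSIVE.value, float(t), float(fs), mu))
            t += 1

    if P < 1.0:
        t = 1
        while t <= max_generations:
            f = (1.0 - P) * math.exp(-lam * t)
            if f < min_fraction:
                break
            rows.append((MutationClass.INCIDENTAL.value, float(t), f, math.nan))
            t += 1

    return pd.DataFrame(
        rows, columns=["mutation_class", "generation", "cell_fraction", "expected_count"]
    )
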