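"""Derived intratumor-heterogeneity metrics.

The fitness diversity index theta is the normalized two-class Shannon
entropy of the (P, 1 - P) clone mixture: 0 for a tumor composed entirely of
the ancestral or the derived clone, 1 for a perfectly balanced mixture.
Base-2 logarithms make the maximum exactly 1.  The subclone expansion score
tau = te / tf measures the duration of subclone growth relative to its
emergence time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .infer import Estimates

__all__ = [
    "DiversityMetrics",
    "fitness_diversity",
    "expansion_score",
    "impute_nonanalyzable",
    "diversity_metrics",
]


@dataclass
class DiversityMetrics:
    theta: float
    tau: float
    source: str  # "computed" or "imputed"


def fitness_diversity(P: float) -> float:
    """Fitness diversity index ``theta = -[P log2 P + (1-P) log2 (1-P)]``.

    Symmetric in P and 1 - P, zero at the endpoints (with 0 log 0 = 0) and
    maximal (exactly 1) at P = 0.5.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P must lie in [0, 1], got {P}")
    if P in (0.0, 1.0):
        return 0.0
    return -(P * math.log2(P) + (1.0 - P) * math.log2(1.0 - P))


def expansion_score(te: float, tf: float) -> float:
    """Subclone expansion score ``tau = te / tf``."""
    if tf <= 0:
        raise ValueError(f"tf must be > 0, got {tf}")
    return te / tf


def impute_nonanalyzable(estimates: Estimates) -> tuple[float, str]:
    """Theta for a sample given its analyzability verdict.

    Non-analyzable tumors are assumed dominated by a single clone and are
    assigned theta = 0, flagged "imputed"; analyzable ones pass through the
    computed index.
    """
    if estimates.analyzable is None:
        raise ValueError("analyzability verdict missing: run assess_analyzability first")
    if not estimates.analyzable:
        return 0.0, "imputed"
    return fitness_diversity(estimates.params.P), "computed"


def diversity_metrics(estimates: Estimates) -> DiversityMetrics:
    """Bundle theta and tau for one sample (tau is NaN when non-analyzable)."""
    theta, source = impute_nonanalyzable(estimates)
    if estimates.analyzable:
        tau = expansion_score(estimates.params.te, estimates.params.tf)
    else:
        tau = math.nan
    return DiversityMetrics(theta=theta, tau=tau, source=source)
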