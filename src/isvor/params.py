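"""Transition probabilities of the ISVOR rumor model.

The model splits a population into five roles — Ignorant (I), Spreader (S),
Variation (V, carrier of a mutated rumor version), Oyster (O, temporarily
silent), Recovery (R, immune) — and is parameterized by twelve per-step
transition probabilities plus the mean contact degree ``k`` used by the
mean-field equations.  The default values are the simulation-study settings
(mean degree 10 networks of 2000 individuals).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["IsvorParams", "DEFAULT_PARAMS"]

_PROBABILITY_FIELDS = (
    "alpha",
    "epsilon",
    "lam",
    "mu1",
    "mu2",
    "gamma",
    "eta",
    "xi1",
    "xi2",
    "theta",
    "beta1",
    "beta2",
)


@dataclass(frozen=True)
class IsvorParams:
    """Rates of the ISVOR model; all per-step/per-contact probabilities.

    Parameters
    ----------
    alpha:
        Probability that an ignorant becomes a spreader on contact with a
        spreader (rumor infection).
    epsilon:
        Probability that an ignorant becomes immune on contact with a
        spreader.  Absent from the mean-field equations by default; the
        agent-based model applies it only when explicitly enabled.
    lam:
        Probability that an ignorant becomes a variation carrier on contact
        with a variation.
    mu1, mu2:
        Immunization probabilities of the spreader / variation per contact
        with a non-ignorant individual.
    gamma:
        Spontaneous spreader -> variation mutation probability.
    eta:
        Spreader -> variation conversion probability per contact with a
        variation.
    xi1, xi2:
        Silencing probabilities: spreader / variation -> oyster.
    theta:
        Oyster forgetting probability (oyster -> recovery).
    beta1, beta2:
        Oyster resuscitation probabilities (back to spreader / variation).
    k:
        Mean contact degree of the mean-field approximation.  Ignored by the
        agent-based model, where contacts come from the graph.
    """

    alpha: float = 0.5
    epsilon: float = 0.0
    lam: float = 0.2
    mu1: float = 0.5
    mu2: float = 0.5
    gamma: float = 0.3
    eta: float = 0.5
    xi1: float = 0.5
    xi2: float = 0.5
    theta: float = 0.25
    beta1: float = 0.1
    beta2: float = 0.1
    k: float = 10.0

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ParameterError(
                    f"{name}={value!r} is not a probability in [0, 1]"
                )
        if not self.k > 0:
            raise ParameterError(f"k={self.k!r} must be positive")

    def replace(self, **changes: float) -> "IsvorParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @property
    def probability_fields(self) -> tuple[str, ...]:
        return _PROBABILITY_FIELDS


#: Default parameter set used throughout the simulation experiments.
DEFAULT_PARAMS = IsvorParams()
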