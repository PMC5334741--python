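"""Shared solver configuration for the consensus models."""

from __future__ import annotations

from dataclasses import dataclass

from .prefrel import Interval

__all__ = ["SolverConfig", "PRINCIPLES"]

PRINCIPLES = ("freedom", "fraternity", "equality", "mixed")


@dataclass(frozen=True)
class SolverConfig:
    """Options shared by the regime-I and regime-II consensus models.

    Parameters
    ----------
    principle
        Social-choice rule: ``freedom`` minimizes the weighted total
        deviation (the p=1 distance), ``fraternity`` the worst per-expert
        weighted deviation (p=∞), ``equality`` equalizes weighted deviations
        across experts, and ``mixed`` blends all three.
    lambda1, lambda2
        Mixing weights of the ``mixed`` principle: ``lambda1`` scales the
        max-deviation (fraternity) term and ``lambda2`` the weighted-total
        (freedom) term, with ``1 - lambda1 - lambda2`` on the equality term,
        following the printed objectives of the combined models.
    alpha_bounds
        Bounds on the per-entry selection coefficients α that pick a crisp
        value ``l + α(u - l)`` inside each expert interval (regime I).
        Default ``[0.1, 1]``, which reproduces the reference case study; set
        to ``[0, 1]`` for the loosest reading.
    pair_scope
        ``upper`` (default) sums deviations over pairs ``i < j`` only, the
        lower triangle being determined by reciprocity; ``full`` sums over
        all ordered pairs ``i ≠ j``.
    tolerance
        Feasibility tolerance handed to the LP backend.
    seed
        Seed recorded for synthetic runs; the solves themselves are
        deterministic.
    """

    principle: str = "freedom"
    lambda1: float = 0.2
    lambda2: float = 0.3
    alpha_bounds: Interval = Interval(0.1, 1.0)
    pair_scope: str = "upper"
    tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.principle not in PRINCIPLES:
            raise ValueError(f"principle must be one of {PRINCIPLES}, got {self.principle!r}")
        if self.pair_scope not in ("upper", "full"):
            raise ValueError(f"pair_scope must be 'upper' or 'full', got {self.pair_scope!r}")
        if not (0.0 <= self.lambda1 <= 1.0 and 0.0 <= self.lambda2 <= 1.0):
            raise ValueError("lambda1 and lambda2 must lie in [0, 1]")
        if self.lambda1 + self.lambda2 > 1.0 + 1e-12:
            raise ValueError("lambda1 + lambda2 must not exceed 1")
        bounds = self.alpha_bounds
        if not isinstance(bounds, Interval):
            object.__setattr__(self, "alpha_bounds", Interval(*bounds))

    @property
    def lambda_equality(self) -> float:
        return 1.0 - self.lambda1 - self.lambda2
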