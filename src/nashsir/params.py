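"""Model parameters for the SIR epidemic with rational social distancing.

Time is measured in units of the mean infectious period, so the recovery
rate is identically 1 and the transmission rate of an unmodified population
equals the basic reproduction number ``R0``.  Utility is measured in units
in which the quadratic distancing-cost coefficient xi equals 1; the
infection cost ``alpha`` is expressed in those units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ModelParams", "default_initial_conditions"]

#: Seed prevalence used throughout: the epidemic starts on the exponential
#: growth branch, where i/r = R0 - 1 holds for the unmodified dynamics.
DEFAULT_R0_SEED = 1e-6


def default_initial_conditions(R0: float, r0: float = DEFAULT_R0_SEED) -> tuple[float, float, float]:
    """Early-epidemic initial state (s0, i0, r0) with i0 = r0*(R0-1).

    On the early exponential branch of an SIR epidemic with constant
    transmission rate R0, infections grow like e^((R0-1)t) while recoveries
    integrate them, which fixes the ratio i/r = R0 - 1.
    """
    i0 = r0 * (R0 - 1.0)
    return 1.0 - i0 - r0, i0, r0


@dataclass
class ModelParams:
    """Parameter set of the epidemic game.

    Parameters
    ----------
    R0 : float
        Basic reproduction number; must exceed 1 for an epidemic to occur.
    alpha : float
        Average cost of one infection, in utility units (xi = 1).
    s0, i0, r0 : float, optional
        Initial compartment fractions.  If omitted they default to the
        early-epidemic seed r0 = 1e-6, i0 = r0*(R0-1), s0 = 1 - i0 - r0.
    tf : float or None
        Decision horizon (time at which a perfect vaccine arrives), in
        infectious periods.  ``None`` means "choose self-consistently
        large": solvers pick a horizon at which the unmodified epidemic
        has burnt out (infected fraction below 1e-9).
    xi : float
        Social-distancing cost coefficient.  The closed-form results
        assume the utility is expressed in units with xi = 1.
    """

    R0: float
    alpha: float = 0.0
    s0: float | None = None
    i0: float | None = None
    r0: float | None = None
    tf: float | None = None
    xi: float = 1.0
    _tf_cache: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.R0 > 1.0:
            raise ValueError(f"R0 must exceed 1, got {self.R0}")
        if self.alpha < 0.0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.xi <= 0.0:
            raise ValueError(f"xi must be positive, got {self.xi}")
        if self.s0 is None and self.i0 is None and self.r0 is None:
            self.s0, self.i0, self.r0 = default_initial_conditions(self.R0)
        elif None in (self.s0, self.i0, self.r0):
            raise ValueError("give all of s0, i0, r0 or none of them")
        if min(self.s0, self.i0, self.r0) < 0.0:
            raise ValueError("initial fractions must be non-negative")
        if abs(self.s0 + self.i0 + self.r0 - 1.0) > 1e-12:
            raise ValueError(
                f"initial fractions must sum to 1, got {self.s0 + self.i0 + self.r0!r}"
            )
        if self.tf is not None and not self.tf > 0.0:
            raise ValueError(f"tf must be positive, got {self.tf}")

    def with_(self, **changes) -> "ModelParams":
        """Copy with fields replaced (horizon cache dropped)."""
        changes.setdefault("_tf_cache", None)
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "alpha": self.alpha,
            "xi": self.xi,
            "s0": self.s0,
            "i0": self.i0,
            "r0": self.r0,
            "tf": self.tf,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            R0=float(d["R0"]),
            alpha=float(d.get("alpha", 0.0)),
            s0=None if d.get("s0") is None else float(d["s0"]),
            i0=None if d.get("i0") is None else float(d["i0"]),
            r0=None if d.get("r0") is None else float(d["r0"]),
            tf=None if d.get("tf") is None else float(d["tf"]),
            xi=float(d.get("xi", 1.0)),
        )
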