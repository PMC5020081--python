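"""Parameter containers for the seven-parameter diffusion model.

The model describes two-choice decisions as a Wiener process with drift
``v`` between absorbing boundaries at 0 and ``a`` (diffusion coefficient
fixed at 1, the fast-dm scaling).  The process starts at ``zr * a`` and the
observed response time is the first-passage time plus a non-decision time
``t0``.  Across trials the drift is normally distributed (SD ``sv``) while
the relative starting point and the non-decision time vary uniformly with
ranges ``szr`` and ``st0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields


class ParameterDomainError(ValueError):
    """Raised when diffusion-model parameters violate their domain."""


@dataclass(frozen=True)
class BasicParams:
    """The four parameters of the basic (no-variability) diffusion model.

    Attributes
    ----------
    a : float
        Threshold separation (evidence units), ``a > 0``.
    v : float
        Mean drift rate (evidence units per second); its sign selects the
        favoured boundary.
    t0 : float
        Non-decision time in seconds, ``t0 >= 0``.
    zr : float
        Relative starting point (fraction of ``a``), ``0 < zr < 1``.
    """

    a: float
    v: float
    t0: float
    zr: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterDomainError(f"threshold separation a={self.a} must be > 0")
        if not (0.0 < self.zr < 1.0):
            raise ParameterDomainError(f"relative starting point zr={self.zr} must be in (0, 1)")
        if not (self.t0 >= 0):
            raise ParameterDomainError(f"non-decision time t0={self.t0} must be >= 0")
        for name in ("a", "v", "t0", "zr"):
            val = getattr(self, name)
            if val != val or val in (float("inf"), float("-inf")):
                raise ParameterDomainError(f"{name}={val} is not finite")


@dataclass(frozen=True)
class DiffusionParams:
    """Full diffusion-model parameter set with intertrial variabilities.

    Trial-level distributions: drift ~ Normal(v, sv); relative start
    ~ Uniform(zr - szr/2, zr + szr/2); non-decision time
    ~ Uniform(t0 - st0/2, t0 + st0/2).

    For two-drift stimulus designs ``v`` is the drift of the
    lower-boundary-associated stimulus (nu_0, typically negative) and
    ``v1`` the drift of the upper-boundary-associated stimulus (nu_1);
    ``v1 is None`` marks a one-drift design.
    """

    a: float
    v: float
    t0: float
    zr: float
    sv: float = 0.0
    st0: float = 0.0
    szr: float = 0.0
    v1: float | None = None

    def __post_init__(self) -> None:
        BasicParams(self.a, self.v, self.t0, self.zr)  # reuse basic validation
        if self.sv < 0 or self.st0 < 0 or self.szr < 0:
            raise ParameterDomainError(
                f"intertrial variabilities must be >= 0 (sv={self.sv}, st0={self.st0}, szr={self.szr})"
            )
        if self.t0 - self.st0 / 2 < -1e-12:
            raise ParameterDomainError(
                f"t0 - st0/2 = {self.t0 - self.st0 / 2} < 0: non-decision time support reaches below zero"
            )
        if not (self.zr - self.szr / 2 > 0 and self.zr + self.szr / 2 < 1):
            raise ParameterDomainError(
                f"starting-point range zr +- szr/2 = {self.zr} +- {self.szr / 2} must stay inside (0, 1)"
            )
        if self.v1 is not None and (self.v1 != self.v1):
            raise ParameterDomainError("v1 is not finite")

    # -- convenience -----------------------------------------------------
    @property
    def basic(self) -> BasicParams:
        return BasicParams(self.a, self.v, self.t0, self.zr)

    @property
    def is_two_drift(self) -> bool:
        return self.v1 is not None

    @property
    def t_min(self) -> float:
        """Lower edge of the response-time support, t0 - st0/2 (seconds)."""
        return self.t0 - self.st0 / 2

    @property
    def v_total(self) -> float:
        """Overall accumulation-speed measure.

        For two-drift designs this is the difference between the
        upper-stimulus and lower-stimulus drifts (nu_1 - nu_0); for
        one-drift designs it is simply the drift rate.
        """
        if self.v1 is None:
            return self.v
        return self.v1 - self.v

    def drift_for_stimulus(self, stimulus: int) -> float:
        if stimulus == 0 or self.v1 is None:
            return self.v
        return self.v1

    def main_values(self) -> dict[str, float]:
        """The four psychologically central parameters (drift as v_total)."""
        return {"a": self.a, "v": self.v_total, "t0": self.t0, "zr": self.zr}

    def replace(self, **kwargs) -> "DiffusionParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

MAIN_PARAM_NAMES = ("a", "v", "t0", "zr")
ALL_PARAM_NAMES = ("a", "v", "t0", "zr", "sv", "st0", "szr")
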