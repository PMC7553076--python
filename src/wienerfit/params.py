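"""Parameter container for the four-parameter Wiener diffusion model.

The model describes two-choice decisions as a Wiener process with drift
``v`` and diffusion scale ``s`` that starts at ``z = z_rel * a`` between an
absorbing lower boundary at 0 and an upper boundary at ``a``.  Observed
response time is the first-passage time plus a non-decision offset ``ter``.
Between-trial variability parameters are deliberately not part of this
container: they are fixed at zero throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class ParameterError(ValueError):
    """Raised when diffusion parameters violate their domain."""


@dataclass(frozen=True)
class DMParams:
    """Diffusion-model parameters.

    Parameters
    ----------
    a : float
        Boundary separation (evidence units), ``a > 0``.
    z_rel : float
        Relative starting point in ``(0, 1)``; the absolute start is
        ``z = z_rel * a``.  ``0.5`` means no a-priori bias.
    ter : float
        Non-decision time in seconds, ``ter >= 0``.
    v : float
        Drift rate (evidence units per second); positive drift favours
        the upper boundary.
    s : float
        Intra-trial diffusion scale; a fixed convention (1 by default,
        0.1 in the classic EZ formulation), never estimated.
    """

    a: float
    z_rel: float
    ter: float
    v: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        if not (0.0 < self.z_rel < 1.0):
            raise ParameterError(f"relative start z_rel must lie in (0,1), got {self.z_rel}")
        if not (self.ter >= 0):
            raise ParameterError(f"non-decision time ter must be >= 0, got {self.ter}")
        if not (self.s > 0):
            raise ParameterError(f"diffusion scale s must be > 0, got {self.s}")

    @classmethod
    def unchecked(cls, a: float, z_rel: float, ter: float, v: float,
                  s: float = 1.0) -> "DMParams":
        """Construct without domain validation.

        Exists for estimators whose output may leave the model domain —
        notably the closed-form EZ inversion, whose non-decision time can
        come out negative; that invalid-estimate pathway is preserved
        rather than masked.
        """
        obj = object.__new__(cls)
        for name, val in (("a", a), ("z_rel", z_rel), ("ter", ter),
                          ("v", v), ("s", s)):
            object.__setattr__(obj, name, float(val))
        return obj

    @property
    def z(self) -> float:
        """Absolute starting point ``z_rel * a`` (strictly inside (0, a))."""
        return self.z_rel * self.a

    def reflected(self) -> "DMParams":
        """Parameters of the mirrored process (upper boundary mapped to lower)."""
        return replace(self, z_rel=1.0 - self.z_rel, v=-self.v)

    def with_scale(self, s: float) -> "DMParams":
        """Rescale the parameter vector to another diffusion-scale convention.

        ``a`` and ``v`` scale linearly with ``s``; ``z_rel`` and ``ter`` are
        scale free.
        """
        factor = s / self.s
        return DMParams(a=self.a * factor, z_rel=self.z_rel, ter=self.ter,
                        v=self.v * factor, s=s)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.z_rel, self.ter, self.v)
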