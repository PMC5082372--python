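"""Intuitionistic fuzzy machinery: restricted equivalence functions,
IFS construction, and exponential IFS divergence.

A restricted equivalence function (REF) is a symmetric similarity
``[0,1]^2 -> [0,1]`` with ``REF(x,y)=1`` iff ``x=y`` and ``REF(x,y)=0`` iff
``{x,y}={0,1}``.  REFs are built from two automorphisms of the unit interval
via

    REF(x, y) = phi_out^{-1}(1 - |phi_in(x) - phi_in(y)|)

With the outer automorphism ``phi_out(x) = log((e-1)x + 1)`` and inner
``phi_in(x) = x^2`` this yields

    REF(x, y) = (e^{1 - |x^2 - y^2|} - 1) / (e - 1)

whose sensitivity to *where* on the gray scale a difference occurs (through
``x^2``) is what lets it discriminate regions that agree in |x - y| but not
in mean level.  Chaira's classical REF, ``(e^{1-|x-y|} - 1)/(e - 1)``, is the
identity-inner-automorphism special case and serves as the comparison
baseline.

An intuitionistic fuzzy set (IFS) augments a membership plane ``mu`` with a
non-membership plane ``nu`` and hesitation ``pi = 1 - mu - nu``.  Here ``nu``
is derived from ``mu`` through a fuzzy-complement generator (Sugeno by
default, Yager selectable).  The divergence between two IFS planes is the
exponential divergence evaluated on hesitation-weighted effective
memberships ``mu + w*pi``; the weight ``w`` defaults to 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "REFParams",
    "ref_eval",
    "chaira_ref",
    "IFSPlane",
    "build_ifs",
    "ifs_divergence",
]

_E = float(np.e)


def _check_unit(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError(f"{name} outside [0, 1]: range [{arr.min()}, {arr.max()}]")
    return arr


def _phi_out(x: np.ndarray) -> np.ndarray:
    return np.log((_E - 1.0) * x + 1.0)


def _phi_out_inv(x: np.ndarray) -> np.ndarray:
    return (np.exp(x) - 1.0) / (_E - 1.0)


@dataclass(frozen=True)
class REFParams:
    """Automorphism pair (and strong negation) defining a REF.

    ``inner`` and ``outer``/``outer_inv`` must be strictly increasing
    bijections of [0, 1] fixing 0 and 1.  ``negation`` is an involutive
    strong negation with c(0)=1, c(1)=0; the default composition only uses
    it implicitly through the ``1 - |...|`` form, but it is kept explicit so
    alternative constructions remain expressible.
    """

    inner: Callable[[np.ndarray], np.ndarray] = field(default=np.square)
    outer: Callable[[np.ndarray], np.ndarray] = field(default=_phi_out)
    outer_inv: Callable[[np.ndarray], np.ndarray] = field(default=_phi_out_inv)
    negation: Callable[[np.ndarray], np.ndarray] = field(default=lambda x: 1.0 - x)

    @classmethod
    def identity_inner(cls) -> "REFParams":
        """The REF with phi_in = identity (Chaira's classical form)."""
        return cls(inner=lambda x: x)

    @classmethod
    def power_inner(cls, p: float) -> "REFParams":
        """REF with phi_in(x) = x**p (p > 0); p = 2 is the default REF."""
        if p <= 0:
            raise ValueError(f"automorphism exponent must be > 0, got {p}")
        return cls(inner=lambda x, _p=float(p): np.power(x, _p))


def ref_eval(x, y, params: REFParams | None = None) -> np.ndarray | float:
    """Evaluate the REF at (x, y), elementwise over broadcastable arrays.

    With default parameters this is ``(e^{1 - |x^2 - y^2|} - 1)/(e - 1)``.
    Raises ``ValueError`` if any input lies outside [0, 1].
    """
    if params is None:
        params = REFParams()
    xa = _check_unit("x", x)
    ya = _check_unit("y", y)
    out = params.outer_inv(params.negation(np.abs(params.inner(xa) - params.inner(ya))))
    # clip away one-ULP excursions from the transcendental round trip
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(x) and np.isscalar(y) else out


def chaira_ref(x, y, scale: float | None = None) -> np.ndarray | float:
    """Chaira's comparison REF, ``scale * (e^{1 - |x - y|} - 1)``.

    The exact scale making this a REF (value 1 at x == y) is ``1/(e - 1) =
    0.58198...``; that is the default.  The commonly printed 3-decimal
    rounding 0.582 can be passed explicitly via ``scale``.
    """
    if scale is None:
        scale = 1.0 / (_E - 1.0)
    xa = _check_unit("x", x)
    ya = _check_unit("y", y)
    out = scale * (np.exp(1.0 - np.abs(xa - ya)) - 1.0)
    return float(out) if np.isscalar(x) and np.isscalar(y) else out


@dataclass(frozen=True)
class IFSPlane:
    """Per-pixel membership / non-membership / hesitation triple."""

    mu: np.ndarray
    nu: np.ndarray
    pi: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu", "nu", "pi"):
            arr = _check_unit(name, getattr(self, name))
            object.__setattr__(self, name, arr)
        if self.mu.shape != self.nu.shape or self.mu.shape != self.pi.shape:
            raise ValueError("mu, nu, pi must share a shape")
        resid = np.abs(self.mu + self.nu + self.pi - 1.0)
        if resid.size and resid.max() > 1e-9:
            raise ValueError(
                f"mu + nu + pi must equal 1 (max residual {resid.max():.3g})"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mu.shape


def build_ifs(mu, epsilon: float, generator: str = "sugeno") -> IFSPlane:
    """Construct an IFS plane from a membership plane.

    The non-membership is derived through a fuzzy-complement generator:

    - ``sugeno`` (default): ``nu = (1 - mu) / (1 + epsilon * mu)``
    - ``yager``:            ``nu = (1 - mu^(1+epsilon))^(1/(1+epsilon))``

    Both reduce to the classical complement ``1 - mu`` at ``epsilon = 0``
    (hesitation zero everywhere).  ``epsilon`` must lie in [0, 1].
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    mu_a = _check_unit("mu", mu)
    if generator == "sugeno":
        nu = (1.0 - mu_a) / (1.0 + epsilon * mu_a)
    elif generator == "yager":
        p = 1.0 + epsilon
        nu = np.power(np.clip(1.0 - np.power(mu_a, p), 0.0, 1.0), 1.0 / p)
    else:
        raise ValueError(f"unknown generator {generator!r}")
    pi = np.clip(1.0 - mu_a - nu, 0.0, 1.0)
    # re-derive nu so the triple sums to exactly 1 after the clip
    nu = 1.0 - mu_a - pi
    return IFSPlane(mu=mu_a, nu=nu, pi=pi, epsilon=epsilon)


def exponential_divergence_kernel(m_a: np.ndarray, m_b: np.ndarray) -> np.ndarray:
    """Pointwise exponential divergence between effective memberships.

    ``2 - (1 - a + b) e^{a-b} - (1 - b + a) e^{b-a}`` — non-negative,
    symmetric, and zero exactly where ``a == b``.
    """
    d = m_a - m_b
    return 2.0 - (1.0 - d) * np.exp(d) - (1.0 + d) * np.exp(-d)


def ifs_divergence(
    a: IFSPlane,
    b: IFSPlane,
    param: float = 0.6,
    normalizer: float | None = None,
    kernel: Callable[[np.ndarray, np.ndarray], np.ndarray] = exponential_divergence_kernel,
) -> float:
    """Normalized exponential divergence between two IFS planes.

    ``param`` is the hesitation weight: the kernel is evaluated on effective
    memberships ``mu + param * pi``.  The summed pointwise divergence is
    divided by ``normalizer`` (default: the number of elements compared).
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not 0.0 <= param <= 1.0:
        raise ValueError(f"param must be in [0, 1], got {param}")
    eff_a = a.mu + param * a.pi
    eff_b = b.mu + param * b.pi
    total = float(np.sum(np.maximum(kernel(eff_a, eff_b), 0.0)))
    if normalizer is None:
        normalizer = float(a.mu.size)
    return total / normalizer
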