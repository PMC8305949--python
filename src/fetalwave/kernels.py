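"""Mother wavelets and two-order multiwavelet banks.

Four explicit kernels in dimensionless time:

* ``haar`` -- the Haar step wavelet, +1 on [0, 1/2), -1 on [1/2, 1).
* ``fsch`` -- the Faber-Schauder piecewise-linear wavelet,
  psi(t) = (L(2t) - 2 L(2t - 1) + L(2t - 2)) / 2 with the hat
  L(t) = max(0, 1 - |t|).
* ``psi1``, ``psi2`` -- Clifford wavelets obtained from Clifford-Hermite-
  Jacobi polynomials against the weight (1 + |x|^2)^alpha exp(-beta |x|^2)
  with alpha = 3/2, beta = 1/2, restricted to a line through the origin.
  The vector part of an odd monogenic polynomial reverses with direction,
  so the 1-D restriction is the odd function sign(t) * p(|t|) * w(|t|),
  which also guarantees zero mean:

      psi1(t) = C1 sign(t) (-2 r + r^3)                 (1+r^2)^{3/2} e^{-r^2/2}
      psi2(t) = C2 sign(t) (r + 16 r^3 + 24 r^5 + 13 r^7 + r^9)
                                                        (1+r^2)^{3/2} e^{-r^2/2}

  with r = |t|.  C1, C2 are L2-normalization constants computed by
  quadrature at construction (they have no closed form) and cached.

Kernels live in dimensionless time; the transform module owns all
physical-time scaling.  Gaussian-decay kernels are truncated at |t| >= 10
where their magnitude is below 1e-12.

Two-order banks pair kernels: ``hfsch`` = (haar, fsch) and ``clifford`` =
(psi1, psi2); each single kernel is also available as a one-component bank
for single-wavelet runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Tuple

import numpy as np
from scipy.integrate import quad

from .errors import DegenerateKernelError, InvalidArgumentError, UnknownBankError

__all__ = [
    "WaveletKernel",
    "MultiwaveletBank",
    "eval_haar",
    "eval_faber_schauder",
    "eval_clifford_psi1",
    "eval_clifford_psi2",
    "compute_normalization",
    "make_bank",
    "get_kernel",
    "BANK_NAMES",
]

#: truncation radius for Gaussian-decay kernels (tail below 1e-12 there)
_GAUSS_RADIUS = 10.0


def _hat(t: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, 1.0 - np.abs(t))


def _haar_raw(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where((t >= 0.0) & (t < 0.5), 1.0, 0.0) - np.where(
        (t >= 0.5) & (t < 1.0), 1.0, 0.0
    )


def _fsch_raw(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return 0.5 * (_hat(2.0 * t) - 2.0 * _hat(2.0 * t - 1.0) + _hat(2.0 * t - 2.0))


def _clifford_weight(r: np.ndarray) -> np.ndarray:
    return (1.0 + r * r) ** 1.5 * np.exp(-0.5 * r * r)


def _psi1_raw(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    r = np.abs(t)
    out = np.sign(t) * (-2.0 * r + r**3) * _clifford_weight(r)
    return np.where(r < _GAUSS_RADIUS, out, 0.0)


def _psi2_raw(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    r = np.abs(t)
    poly = r + 16.0 * r**3 + 24.0 * r**5 + 13.0 * r**7 + r**9
    out = np.sign(t) * poly * _clifford_weight(r)
    return np.where(r < _GAUSS_RADIUS, out, 0.0)


def compute_normalization(
    raw_profile: Callable[[np.ndarray], np.ndarray],
    support: Tuple[float, float],
) -> float:
    """L2-normalization constant for a raw kernel profile.

    Returns c > 0 such that c * raw_profile has unit L2 norm, via adaptive
    quadrature over the (effective) support.  The support endpoints of the
    Gaussian-decay kernels are chosen so the neglected tail is < 1e-12.

    Raises
    ------
    DegenerateKernelError
        If the profile is (numerically) identically zero.
    """
    a, b = support
    breakpoints = [x for x in (-0.5, 0.0, 0.5, 1.0, 1.5) if a < x < b]
    norm2, _ = quad(
        lambda x: float(raw_profile(np.asarray(x)) ** 2),
        a,
        b,
        points=breakpoints or None,
        limit=400,
    )
    if norm2 <= 1e-30:
        raise DegenerateKernelError("raw profile has (numerically) zero L2 norm")
    return 1.0 / float(np.sqrt(norm2))


@dataclass(frozen=True)
class WaveletKernel:
    """An L2-normalized mother wavelet in dimensionless time."""

    name: str
    raw: Callable[[np.ndarray], np.ndarray]
    support: Tuple[float, float]
    norm_constant: float

    @property
    def effective_support_radius(self) -> float:
        """|t| beyond which the kernel magnitude is below 1e-12."""
        return max(abs(self.support[0]), abs(self.support[1]))

    def __call__(self, t) -> np.ndarray:
        return self.evaluate(t)

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the normalized kernel at dimensionless time(s) t."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise InvalidArgumentError("kernel argument must be finite")
        return self.norm_constant * self.raw(t)

    def __hash__(self) -> int:  # callables break dataclass hashing
        return hash(self.name)

    def __eq__(self, other) -> bool:
        return isinstance(other, WaveletKernel) and other.name == self.name


@dataclass(frozen=True)
class MultiwaveletBank:
    """An ordered tuple of independent mother-wavelet components.

    Two-order banks analyze a signal through two 'blind cameras', one per
    component; reconstructions are averaged downstream.
    """

    name: str
    components: Tuple[WaveletKernel, ...]

    def __len__(self) -> int:
        return len(self.components)


@lru_cache(maxsize=None)
def get_kernel(name: str) -> WaveletKernel:
    """Build (and cache) a normalized kernel by name."""
    table = {
        "haar": (_haar_raw, (0.0, 1.0)),
        "fsch": (_fsch_raw, (-0.5, 1.5)),
        "psi1": (_psi1_raw, (-_GAUSS_RADIUS, _GAUSS_RADIUS)),
        "psi2": (_psi2_raw, (-_GAUSS_RADIUS, _GAUSS_RADIUS)),
    }
    if name not in table:
        raise UnknownBankError(name)
    raw, support = table[name]
    return WaveletKernel(name, raw, support, compute_normalization(raw, support))


#: bank name -> component kernel names
BANK_NAMES = {
    "hfsch": ("haar", "fsch"),
    "clifford": ("psi1", "psi2"),
    "haar": ("haar",),
    "fsch": ("fsch",),
    "psi1": ("psi1",),
    "psi2": ("psi2",),
}


@lru_cache(maxsize=None)
def make_bank(name: str) -> MultiwaveletBank:
    """Return a named multiwavelet bank with normalized components.

    ``hfsch`` and ``clifford`` are the two-order banks; single-kernel names
    give one-component banks for single-wavelet runs.
    """
    if name not in BANK_NAMES:
        raise UnknownBankError(
            f"unknown bank {name!r}; choose from {sorted(BANK_NAMES)}"
        )
    return MultiwaveletBank(name, tuple(get_kernel(k) for k in BANK_NAMES[name]))


def eval_haar(t) -> np.ndarray:
    """Haar mother wavelet: +1 on [0, 1/2), -1 on [1/2, 1), 0 elsewhere."""
    return get_kernel("haar").evaluate(t)


def eval_faber_schauder(t) -> np.ndarray:
    """L2-normalized Faber-Schauder wavelet (hat-function combination)."""
    return get_kernel("fsch").evaluate(t)


def eval_clifford_psi1(t) -> np.ndarray:
    """First Clifford wavelet (odd 1-D restriction, L2-normalized)."""
    return get_kernel("psi1").evaluate(t)


def eval_clifford_psi2(t) -> np.ndarray:
    """Second Clifford wavelet (odd 1-D restriction, L2-normalized)."""
    return get_kernel("psi2").evaluate(t)
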