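"""Wavelet-energy Shannon entropy and optimal-level selection.

The energy at level j is the squared coefficient mass across positions and
bank components,

    E_j = sum_{components} sum_k d_{j,k}^2,

the level probabilities are p_j = E_j / E with E = sum_j E_j over the full
computed level range, and the entropy curve is the partial sum

    Ent(J) = -sum_{j=0}^{J} p_j log p_j      (natural log, 0 log 0 = 0).

Because the denominator is fixed, Ent(J) is non-decreasing in J and
bounded by log(number of levels).  The curve flattens once deeper levels
stop contributing energy; the optimal decomposition level is the first
level at which the curve is stationary within a relative tolerance.
A scale-resolving bank flattens earlier, so the selected level doubles as
a compactness measure of the representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidArgumentError, ZeroEnergyError
from .kernels import make_bank
from .signal import Signal
from .transform import MultiwaveletDecomposition, analyze_multi, max_level

__all__ = [
    "EnergyProfile",
    "EntropyCurve",
    "level_energies",
    "level_probabilities",
    "entropy_curve",
    "optimal_level",
    "WaveletEnergyTransformer",
]


@dataclass(frozen=True)
class EnergyProfile:
    """Per-level wavelet energies E_j and their total."""

    energies: np.ndarray

    @property
    def total(self) -> float:
        return float(self.energies.sum())


@dataclass(frozen=True)
class EntropyCurve:
    """Level probabilities p_j and the partial-sum entropy Ent(J) in nats."""

    probabilities: np.ndarray
    ent: np.ndarray
    optimal_J: Optional[int] = None

    def to_frame(self):
        """Two-column table (J, Ent) for plotting / CSV export."""
        import pandas as pd

        return pd.DataFrame({"J": np.arange(self.ent.size), "Ent": self.ent})


def level_energies(decomp: MultiwaveletDecomposition) -> EnergyProfile:
    """Squared coefficient mass per level, summed over bank components.

    The multiwavelet coefficient norm sums the component contributions, so
    a two-order bank's E_j is the sum of both components' level-j
    energies.
    """
    if not decomp.per_component:
        raise InvalidArgumentError("empty decomposition")
    levels = decomp.top_level + 1
    energies = np.zeros(levels)
    for comp in decomp.per_component:
        for j, d in enumerate(comp.levels):
            energies[j] += float(d @ d)
    return EnergyProfile(energies)


def level_probabilities(profile: EnergyProfile) -> np.ndarray:
    """p_j = E_j / E over the full level range (fixed denominator)."""
    total = profile.total
    if total <= 0.0:
        raise ZeroEnergyError("signal carries no wavelet energy at any level")
    return profile.energies / total


def entropy_curve(profile: EnergyProfile) -> EntropyCurve:
    """Partial sums Ent(J) = -sum_{j<=J} p_j ln p_j for J = 0..Jmax."""
    p = level_probabilities(profile)
    terms = np.where(p > 0.0, -p * np.log(np.where(p > 0.0, p, 1.0)), 0.0)
    return EntropyCurve(probabilities=p, ent=np.cumsum(terms))


def optimal_level(curve: EntropyCurve, tol: float = 0.01) -> int:
    """First level from which the entropy curve stays flat.

    Returns the smallest J >= 1 such that every step |Ent(j) - Ent(j-1)|
    for j >= J is within tol * Ent(Jmax) (the curve is stationary from J
    on), or Jmax when the curve never flattens.  Requiring the whole
    suffix to be flat, rather than a single small step, keeps spuriously
    early selections from curves that are flat at the start because the
    coarse levels carry no energy.  A degenerate all-zero curve returns 0
    with a warning.
    """
    if tol <= 0.0:
        raise InvalidArgumentError("tol must be positive")
    ent = curve.ent
    if ent.size < 2:
        raise InvalidArgumentError("entropy curve needs at least 2 levels")
    top = float(ent[-1])
    if top <= 0.0:
        warnings.warn(
            "entropy curve is identically zero (degenerate signal)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0
    steps = np.abs(np.diff(ent))
    flat = steps <= tol * max(top, np.finfo(float).tiny)
    J = ent.size - 1
    for j in range(steps.size - 1, -1, -1):
        if not flat[j]:
            break
        J = j + 1
    object.__setattr__(curve, "optimal_J", J)
    return J


class WaveletEnergyTransformer(BaseEstimator, TransformerMixin):
    """Per-level wavelet energy features for sklearn pipelines.

    Transforms each row of X (a uniformly sampled signal) into its
    per-level energy distribution p_0..p_J under the configured bank —
    a compact spectral-shape feature usable by any downstream estimator.

    Parameters
    ----------
    bank : str, default "clifford"
        Bank name (clifford, hfsch, haar, fsch, psi1, psi2).
    levels : int or None, default None
        Top decomposition level; None uses the deepest level the signal
        length allows.
    fs : float, default 250.0
        Sampling rate of the rows of X in Hz.
    normalize : bool, default True
        Return probabilities p_j (True) or raw energies E_j (False).
    """

    def __init__(
        self,
        bank: str = "clifford",
        levels: int | None = None,
        fs: float = 250.0,
        normalize: bool = True,
    ):
        self.bank = bank
        self.levels = levels
        self.fs = fs
        self.normalize = normalize

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_levels_ = (
            self.levels if self.levels is not None else max_level(X.shape[1])
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "n_levels_")
        X = self._validate(X)
        bank = make_bank(self.bank)
        out = np.empty((X.shape[0], self.n_levels_ + 1))
        for i, row in enumerate(X):
            decomp = analyze_multi(Signal(row, self.fs), bank, self.n_levels_)
            profile = level_energies(decomp)
            out[i] = (
                level_probabilities(profile) if self.normalize else profile.energies
            )
        return out

    @staticmethod
    def _validate(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] < 4:
            raise InvalidArgumentError(
                "X must be (n_signals, n_samples) with n_samples >= 4"
            )
        return X
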