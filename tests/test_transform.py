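"""Dyadic analysis/synthesis: exactness, Parseval, calibration, frames."""

import numpy as np
import pytest

from fetalwave.errors import (
    InvalidArgumentError,
    LevelOverflowError,
    LevelRangeError,
)
from fetalwave.kernels import make_bank
from fetalwave.signal import Signal
from fetalwave.transform import (
    analyze,
    analyze_multi,
    approximation,
    combine_components,
    decomposition_frame,
    detail_component,
    frame_calibration,
    max_level,
    reconstruct,
)


def test_zero_signal_gives_zero_coefficients():
    sig = Signal(np.zeros(64), fs=64.0)
    coeffs = analyze(sig, "haar", 3)
    for d in coeffs.levels:
        assert np.all(d == 0.0)


def test_constant_signal_gives_zero_details():
    sig = Signal(np.full(64, 3.7), fs=64.0)
    coeffs = analyze(sig, "haar", 5)
    for d in coeffs.levels:
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
    np.testing.assert_allclose(coeffs.coarse_residual.samples, 3.7)


def test_step_signal_brute_force_oracle():
    """[1, 1, -1, -1]: inner products against explicitly tabulated Haar
    translates (coarse atom [1,1,-1,-1]/2, fine atoms [1,-1,0,0]/sqrt2...)."""
    x = np.array([1.0, 1.0, -1.0, -1.0])
    coeffs = analyze(Signal(x, fs=4.0), "haar", 1)
    coarse_atom = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
    fine_atoms = [
        np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2.0),
        np.array([0.0, 0.0, 1.0, -1.0]) / np.sqrt(2.0),
    ]
    assert coeffs.levels[0] == pytest.approx([x @ coarse_atom])  # magnitude 2
    assert coeffs.levels[1] == pytest.approx([x @ a for a in fine_atoms])
    assert abs(coeffs.levels[0][0]) == pytest.approx(2.0)


def test_haar_full_reconstruction_machine_precision(dyadic_signal):
    J = max_level(len(dyadic_signal))
    coeffs = analyze(dyadic_signal, "haar", J)
    rec = reconstruct(coeffs, J)
    np.testing.assert_allclose(rec.samples, dyadic_signal.samples, atol=1e-10)


def test_haar_parseval(dyadic_signal):
    J = max_level(len(dyadic_signal))
    coeffs = analyze(dyadic_signal, "haar", J)
    total = sum(float(d @ d) for d in coeffs.levels)
    total += float(coeffs.coarse_residual.samples @ coeffs.coarse_residual.samples)
    assert total == pytest.approx(float(dyadic_signal.samples @ dyadic_signal.samples), rel=1e-9)


def test_haar_approximation_equals_block_means(dyadic_signal):
    """Pyramid-algorithm oracle: the Haar level-J approximation is the
    blockwise mean at scale n / 2^J."""
    n = len(dyadic_signal)
    x = dyadic_signal.samples
    coeffs = analyze(dyadic_signal, "haar", max_level(n))
    for J in (2, 4, 6):
        block = n // 2**J
        oracle = np.repeat(x.reshape(2**J, block).mean(axis=1), block)
        np.testing.assert_allclose(
            approximation(coeffs, J).samples, oracle, atol=1e-10
        )


def test_haar_approximation_matches_pywavelets(dyadic_signal):
    """Independent cross-check against PyWavelets' Haar pyramid."""
    pywt = pytest.importorskip("pywt")
    n = len(dyadic_signal)
    x = dyadic_signal.samples
    coeffs = analyze(dyadic_signal, "haar", max_level(n))
    J = 5
    depth = int(np.log2(n)) - J
    parts = pywt.wavedec(x, "haar", level=depth)
    parts = [parts[0]] + [np.zeros_like(p) for p in parts[1:]]
    oracle = pywt.waverec(parts, "haar")
    np.testing.assert_allclose(approximation(coeffs, J).samples, oracle, atol=1e-10)


def test_single_coefficient_synthesizes_one_bump():
    n, j, k = 64, 3, 5
    sig = Signal(np.zeros(n), fs=64.0)
    # full depth so the Haar family is complete and all gains are 1
    coeffs = analyze(sig, "haar", max_level(n))
    d = [np.zeros_like(lev) for lev in coeffs.levels]
    d[j][k - coeffs.k_starts[j]] = 1.0
    from fetalwave.transform import DyadicCoefficients

    crafted = DyadicCoefficients.from_levels(
        "haar", tuple(d), coeffs.k_starts, coeffs.coarse_residual, fs=64.0
    )
    bump = detail_component(crafted, j).samples
    block = n // 2**j
    expected = np.zeros(n)
    expected[k * block : k * block + block // 2] = 2.0 ** (j / 2) / np.sqrt(n)
    expected[k * block + block // 2 : (k + 1) * block] = -(2.0 ** (j / 2)) / np.sqrt(n)
    np.testing.assert_allclose(bump, expected, atol=1e-10)
    for other in range(len(d)):
        if other != j:
            np.testing.assert_allclose(
                detail_component(crafted, other).samples, 0.0, atol=1e-10
            )


def test_telescoping(dyadic_signal):
    coeffs = analyze(dyadic_signal, "psi1", 5)
    for J in range(1, 5):
        np.testing.assert_allclose(
            reconstruct(coeffs, J).samples,
            approximation(coeffs, J + 1).samples,
            atol=1e-12,
        )


def test_linearity(rng):
    n = 128
    x, y = rng.normal(size=n), rng.normal(size=n)
    a, b = 2.5, -1.3
    cx = analyze(Signal(x, 128.0), "fsch", 4)
    cy = analyze(Signal(y, 128.0), "fsch", 4)
    cz = analyze(Signal(a * x + b * y, 128.0), "fsch", 4)
    for dz, dx, dy in zip(cz.levels, cx.levels, cy.levels):
        np.testing.assert_allclose(dz, a * dx + b * dy, atol=1e-10)


def test_haar_translation_covariance(rng):
    """Shifting by one fine-level position shifts fine coefficients."""
    n, J = 128, 6
    x = rng.normal(size=n)
    shift = n // 2**J
    xs = np.roll(x, shift)
    cj = analyze(Signal(x, float(n)), "haar", J).levels[J]
    cjs = analyze(Signal(xs, float(n)), "haar", J).levels[J]
    np.testing.assert_allclose(np.roll(cj, 1), cjs, atol=1e-10)


def test_clifford_sine_reconstruction_within_tolerance():
    fs, T = 250.0, 10.0
    n = int(fs * T)
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * 5.0 * t)
    J = max_level(n)
    coeffs = analyze(Signal(x, fs), "psi1", J)
    rec = reconstruct(coeffs, J)
    err = np.linalg.norm(rec.samples - x) / np.linalg.norm(x)
    assert err <= 0.05


def test_hfsch_bank_roundtrip_dyadic_random(dyadic_signal):
    J = max_level(len(dyadic_signal))
    decomp = analyze_multi(dyadic_signal, make_bank("hfsch"), J)
    rec = combine_components(decomp, J)
    err = np.linalg.norm(rec.samples - dyadic_signal.samples) / np.linalg.norm(
        dyadic_signal.samples
    )
    assert err <= 0.05


def test_multi_component_structure(dyadic_signal):
    decomp = analyze_multi(dyadic_signal, make_bank("clifford"), 4)
    assert len(decomp.per_component) == 2
    assert {c.kernel_name for c in decomp.per_component} == {"psi1", "psi2"}
    single = analyze_multi(dyadic_signal, make_bank("haar"), 4)
    assert len(single.per_component) == 1
    zero = analyze_multi(Signal(np.zeros(64), 64.0), make_bank("clifford"), 3)
    for comp in zero.per_component:
        for d in comp.levels:
            np.testing.assert_allclose(d, 0.0, atol=1e-14)


def test_identical_components_average_to_either(dyadic_signal):
    """Averaging two identical components equals one alone."""
    from fetalwave.transform import MultiwaveletDecomposition

    c = analyze(dyadic_signal, "haar", 4)
    twin = MultiwaveletDecomposition("twin", (c, c))
    np.testing.assert_allclose(
        combine_components(twin, 4).samples, reconstruct(c, 4).samples, atol=1e-12
    )


def test_haar_calibration_gains_are_one():
    gains = frame_calibration("haar", 256.0, 256, 7)
    np.testing.assert_allclose(gains, 1.0, atol=1e-10)


def test_clifford_gains_positive():
    for name in ("psi1", "psi2"):
        gains = frame_calibration(name, 250.0, 1000, max_level(1000))
        assert np.all(gains > 0.0)


def test_calibrated_probe_roundtrip_unbiased():
    """A probe sinusoid at a level's passband center round-trips within 5%."""
    from fetalwave.transform import _level_center_cycle

    fs, n = 250.0, 1024
    J = max_level(n)
    m = _level_center_cycle("psi2", n, J - 1)
    t = np.arange(n) / n
    probe = np.sin(2 * np.pi * m * t + np.pi / 4)
    coeffs = analyze(Signal(probe, fs), "psi2", J)
    rec = reconstruct(coeffs, J).samples
    ratio = float(rec @ probe) / float(probe @ probe)
    assert 0.95 <= ratio <= 1.05


def test_level_overflow_and_range_errors(dyadic_signal):
    with pytest.raises(LevelOverflowError):
        analyze(dyadic_signal, "haar", 20)
    with pytest.raises(InvalidArgumentError):
        analyze(dyadic_signal, "haar", 0)
    coeffs = analyze(dyadic_signal, "haar", 3)
    with pytest.raises(LevelRangeError):
        detail_component(coeffs, 9)
    with pytest.raises(LevelRangeError):
        approximation(coeffs, 0)
    with pytest.raises(InvalidArgumentError):
        from fetalwave.transform import MultiwaveletDecomposition

        combine_components(MultiwaveletDecomposition("empty", ()), 1)


def test_decomposition_frame_columns(dyadic_signal):
    decomp = analyze_multi(dyadic_signal, make_bank("hfsch"), 3)
    frame = decomposition_frame(decomp)
    assert list(frame.columns) == ["level", "position", "component", "value"]
    assert set(frame["component"]) == {0, 1}
    assert frame["level"].max() == 3
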