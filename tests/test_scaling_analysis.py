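"""Binned depth curves, local scaling exponents, size-distribution fits."""

import math

import numpy as np
import pandas as pd
import pytest

from phylodepth import (
    closed_form_depth,
    collect_points,
    compare_curves,
    evolvability_subtree_points,
    fit_size_distribution,
    local_exponents,
    log_bin,
    make_balanced,
    reference_curve,
    sample_powerlaw_sizes,
)


def test_collect_points_examples(cherry):
    points = collect_points([("cherry", cherry)])
    assert sorted(zip(points.A, points.d)) == [
        (1, 0.0),
        (1, 0.0),
        (3, pytest.approx(2 / 3)),
    ]
    b2 = collect_points([make_balanced(2)])
    assert len(b2) == 7 and b2.A.max() == 7


def test_log_bin_hand_example():
    curve = log_bin((np.array([2, 3, 4]), np.array([1.0, 1.0, 3.0])), base=2, min_A=2)
    t = curve.table
    assert list(t.k) == [0, 1]
    assert list(t.mean_d) == [1.0, 3.0]
    assert list(t.n_points) == [2, 1]
    assert t.se_d.iloc[0] == 0.0  # two identical values: zero spread
    assert t.se_d.iloc[1] == 0.0  # single-point bin, flagged se 0
    assert t.A_center.iloc[0] == pytest.approx(math.sqrt(6))


def test_log_bin_single_size():
    curve = log_bin((np.full(5, 8.0), np.array([1, 2, 3, 4, 5.0])), base=2, min_A=2)
    t = curve.table
    assert len(t) == 1
    assert t.mean_d.iloc[0] == 3.0
    assert t.A_center.iloc[0] == pytest.approx(8.0)
    assert t.se_d.iloc[0] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1) / math.sqrt(5))


def test_log_bin_mass_preserving_and_min_A():
    rng = np.random.default_rng(0)
    A = rng.integers(1, 500, size=1000)
    d = rng.random(1000)
    curve = log_bin((A, d), base=2, min_A=2)
    assert curve.table.n_points.sum() == (A >= 2).sum()
    with pytest.raises(ValueError):
        log_bin((np.array([1.0]), np.array([0.0])), base=2, min_A=2)
    with pytest.raises(ValueError):
        log_bin((A, d), base=1.0)


def test_local_exponents_exact_power_law():
    A = np.array([4.0 * 2**i for i in range(10)])
    eta = local_exponents(log_bin((A, A**0.5), base=2, min_A=2)).eta
    assert np.allclose(eta, 0.5, rtol=1e-12)
    beta = local_exponents(log_bin((A, np.log(A) ** 2), base=2, min_A=2)).beta
    assert np.allclose(beta, 2.0, rtol=1e-12)


def test_local_exponents_domain_handling(caplog):
    # mean_d <= 0 bins skipped; A <= e gives NaN beta
    A = np.array([2.0, 4.0, 8.0, 16.0])
    d = np.array([0.0, 1.0, 2.0, 4.0])
    with caplog.at_level("WARNING", logger="phylodepth"):
        exps = local_exponents(log_bin((A, d), base=2, min_A=2))
    assert len(exps) == 2  # first bin (d=0) dropped
    assert np.isfinite(exps.eta).all()
    with pytest.raises(ValueError):
        local_exponents(log_bin((A[:1], d[:1] + 1), base=2, min_A=2))


def test_evolvability_exponents_favor_squared_log():
    """Local exponents of the p = 0.24 model curve over A in [10, 1000]:
    beta sits nearer 2 than 1 while eta is around 0.5 and drifts down."""
    A, d = evolvability_subtree_points(0.24, 24, 300, seed=5)
    exps = local_exponents(log_bin((A, d), base=2, min_A=2))
    sel = exps[(exps.A_center >= 10) & (exps.A_center <= 1000)]
    assert len(sel) >= 5
    assert np.mean(np.abs(sel.beta - 2)) < np.mean(np.abs(sel.beta - 1))
    assert 0.2 < sel.eta.mean() < 0.8
    assert sel.eta.iloc[-1] < sel.eta.iloc[0]


def test_size_distribution_recovery():
    sizes = sample_powerlaw_sizes(5000, gamma=1.6, seed=42)
    fit = fit_size_distribution(sizes)
    assert abs(fit.gamma_hat - 1.6) < 0.1
    assert 0 < fit.gamma_se < 0.1
    ls = fit_size_distribution(sizes, method="ls")
    assert abs(ls.gamma_hat - fit.gamma_hat) < 0.35


def test_size_distribution_refusals():
    with pytest.raises(ValueError, match="100"):
        fit_size_distribution([2, 3, 4] * 10)
    with pytest.raises(ValueError, match="degenerate"):
        fit_size_distribution([5] * 200)
    with pytest.raises(ValueError, match="t_min"):
        fit_size_distribution(np.r_[np.ones(50, dtype=int), np.full(60, 3)])


def test_ccdf_strictly_greater_convention():
    sizes = np.array([2, 2, 4] * 40)
    fit = fit_size_distribution(sizes)
    ccdf = fit.ccdf.set_index("T").F
    assert ccdf.loc[2] == pytest.approx(1 / 3)
    assert ccdf.loc[4] == 0.0
    assert fit.ccdf.F.is_monotonic_decreasing


def test_compare_curves_identity_and_mismatch():
    A, d = evolvability_subtree_points(0.5, 8, 50, seed=1)
    curve = log_bin((A, d), base=2, min_A=2)
    comp = compare_curves(curve, curve)
    assert comp.rms == 0.0
    assert (comp.table.d_diff == 0).all()
    other = log_bin((A, d), base=3, min_A=2)
    with pytest.raises(ValueError, match="re-bin"):
        compare_curves(curve, other)


def test_compare_reference_curves_diverge():
    """Caterpillar minus balanced differences are positive and grow with A."""
    bal = reference_curve("balanced", 1023)
    cat = reference_curve("caterpillar", 1023)
    cb = log_bin((bal.A, bal.d), base=2, min_A=3)
    cc = log_bin((cat.A, cat.d), base=2, min_A=3)
    comp = compare_curves(cc, cb)
    diffs = comp.table.sort_values("k").d_diff.to_numpy()
    assert (diffs > 0).all()
    assert (np.diff(diffs) > 0).all()
    assert comp.rms > 0
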