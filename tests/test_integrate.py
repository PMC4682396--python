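"""Merging formulas (Ave/wAve/pwAve) against independent brute-force
oracles, and the position-wise integration against a naive
reimplementation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylmerge.errors import DataIntegrityError, UsageError
from methylmerge.integrate import (
    depth_weights,
    integrate_ave,
    integrate_positions,
    integrate_pwave,
    integrate_wave,
    methylation_level,
    poisson_weights,
)
from methylmerge.io_calls import CytosineCall, MapperCallSet

from conftest import random_callset


# -- independent oracles ----------------------------------------------------

def pmf_oracle(k: int, lam: float) -> float:
    """Poisson pmf via log-factorial, independent of scipy."""
    return math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))


def naive_integrate(callsets, min_mappers, min_depth):
    """Set-comprehension reimplementation of position-wise merging."""
    keys = set()
    for cs in callsets:
        keys |= set(cs.calls)
    out = {}
    for key in keys:
        cov = [
            (cs.calls[key], cs.lam)
            for cs in callsets
            if key in cs.calls and cs.calls[key].depth >= min_depth
        ]
        if len(cov) < min_mappers:
            continue
        levels = [c.n_meth / c.depth for c, _ in cov]
        depths = [c.depth for c, _ in cov]
        pmfs = [pmf_oracle(c.depth, lam) for c, lam in cov]
        out[key] = (
            sum(levels) / len(levels),
            sum(l * d for l, d in zip(levels, depths)) / sum(depths),
            sum(l * p for l, p in zip(levels, pmfs)) / sum(pmfs),
        )
    return out


# -- per-position level -----------------------------------------------------

@pytest.mark.parametrize(
    "n_meth,n_unmeth,expected", [(3, 1, 0.75), (0, 7, 0.0), (5, 0, 1.0)]
)
def test_methylation_level(n_meth, n_unmeth, expected):
    assert methylation_level(n_meth, n_unmeth) == expected


def test_methylation_level_errors():
    with pytest.raises(DataIntegrityError):
        methylation_level(-1, 2)
    with pytest.raises(UsageError):
        methylation_level(0, 0)


# -- merging formulas -------------------------------------------------------

def test_integrate_ave_examples():
    assert integrate_ave([0.5, 0.7]) == pytest.approx(0.6)
    assert integrate_ave([0.2]) == 0.2
    assert integrate_ave([0.1, 0.2, 0.9]) == pytest.approx(0.4)


def test_depth_weights_examples():
    assert depth_weights([10, 30]) == pytest.approx([0.25, 0.75])
    assert depth_weights([7, 7, 7]) == pytest.approx([1 / 3] * 3)
    assert depth_weights([1, 2, 3]) == pytest.approx([1 / 6, 1 / 3, 1 / 2])
    with pytest.raises(UsageError):
        depth_weights([1, 0])


def test_integrate_wave_examples():
    assert integrate_wave([0.2, 0.6], [10, 30]) == pytest.approx(0.50)
    assert integrate_wave([0.1, 0.5, 0.9], [4, 4, 4]) == pytest.approx(
        integrate_ave([0.1, 0.5, 0.9])
    )
    assert integrate_wave([0.33], [12]) == pytest.approx(0.33)


def test_poisson_weights_symmetric():
    assert poisson_weights([10, 10], [10, 10]) == pytest.approx([0.5, 0.5])


def test_poisson_weights_against_pmf_oracle():
    w = poisson_weights([10, 30], [10, 10])
    p10, p30 = pmf_oracle(10, 10), pmf_oracle(30, 10)
    assert w[0] / w[1] == pytest.approx(p10 / p30, rel=1e-9)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_poisson_weights_typical_depth_preferred():
    # depth 2 is typical for lambda 2, anomalously low for lambda 20
    w = poisson_weights([2, 2], [2, 20])
    assert w[0] > w[1]


def test_poisson_weights_underflow_falls_back_to_depth():
    # lambda 0 with positive depth zeroes every pmf
    with np.errstate(all="ignore"):
        w = poisson_weights([10, 30], [0.0, 0.0])
    assert w == pytest.approx([0.25, 0.75])


def test_integrate_pwave_examples():
    assert integrate_pwave([0.3, 0.7], [8, 8], [8, 8]) == pytest.approx(0.5)
    assert integrate_pwave([0.42], [5], [9]) == pytest.approx(0.42)
    rng = np.random.default_rng(3)
    levels = rng.random(3)
    depths = rng.integers(1, 40, 3)
    lams = rng.uniform(1, 20, 3)
    pmfs = [pmf_oracle(int(d), lam) for d, lam in zip(depths, lams)]
    expected = sum(l * p for l, p in zip(levels, pmfs)) / sum(pmfs)
    assert integrate_pwave(levels, depths, lams) == pytest.approx(expected, abs=1e-12)


def test_formula_suite_many_random_instances():
    """Merged levels match independent oracles on 1000 random instances."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(1, 5))
        depths = rng.integers(1, 60, n)
        meths = np.array([rng.integers(0, d + 1) for d in depths])
        lams = rng.uniform(0.5, 30, n)
        levels = np.array(
            [methylation_level(int(m), int(d - m)) for m, d in zip(meths, depths)]
        )
        assert levels == pytest.approx(meths / depths, abs=1e-15)
        assert integrate_ave(levels) == pytest.approx(levels.mean(), abs=1e-12)
        wave = integrate_wave(levels, depths)
        assert wave == pytest.approx(
            float(np.dot(levels, depths)) / depths.sum(), abs=1e-12
        )
        pmfs = np.array([pmf_oracle(int(d), lam) for d, lam in zip(depths, lams)])
        assert integrate_pwave(levels, depths, lams) == pytest.approx(
            float(np.dot(levels, pmfs)) / pmfs.sum(), abs=1e-12
        )


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_merged_levels_are_convex_combinations(data):
    """All three merged levels lie within [min level, max level] and the
    weight vectors sum to one."""
    n = data.draw(st.integers(1, 5))
    levels = data.draw(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
    )
    depths = data.draw(st.lists(st.integers(1, 100), min_size=n, max_size=n))
    lams = data.draw(
        st.lists(st.floats(0.1, 40, allow_nan=False), min_size=n, max_size=n)
    )
    lo, hi = min(levels), max(levels)
    for merged in (
        integrate_ave(levels),
        integrate_wave(levels, depths),
        integrate_pwave(levels, depths, lams),
    ):
        assert lo - 1e-9 <= merged <= hi + 1e-9
    assert depth_weights(depths).sum() == pytest.approx(1.0, abs=1e-9)
    assert poisson_weights(depths, lams).sum() == pytest.approx(1.0, abs=1e-9)


# -- position-wise integration ---------------------------------------------

def _three_callsets(seed=9, n_positions=200, max_pos=300):
    rng = np.random.default_rng(seed)
    return [
        random_callset(rng, m, n_positions=n_positions, max_pos=max_pos)
        for m in ("bismark", "bsmap", "bsseeker2")
    ]


def test_integrate_positions_matches_naive_oracle():
    callsets = _three_callsets()
    for k, d in ((1, 1), (2, 1), (2, 3), (3, 1)):
        got = {
            (c.chrom, c.pos, c.strand): c
            for c in integrate_positions(callsets, "all", k, d)
        }
        want = naive_integrate(callsets, k, d)
        assert set(got) == set(want)
        for key, (ave, wave, pwave) in want.items():
            assert got[key].level_ave == pytest.approx(ave, abs=1e-12)
            assert got[key].level_wave == pytest.approx(wave, abs=1e-12)
            assert got[key].level_pwave == pytest.approx(pwave, abs=1e-12)


def test_single_mapper_identity():
    (cs,) = _three_callsets()[:1]
    out = integrate_positions([cs], "all", min_mappers=1, min_depth=1)
    assert len(out) == sum(1 for c in cs if c.depth >= 1)
    for c in out:
        call = cs.calls[(c.chrom, c.pos, c.strand)]
        level = call.n_meth / call.depth
        assert c.level_ave == c.level_wave == c.level_pwave == pytest.approx(level)
        assert c.n_covering == 1


def test_position_covered_by_one_mapper_dropped_at_k2():
    a = MapperCallSet("a", lam=5)
    b = MapperCallSet("b", lam=5)
    a.add(CytosineCall("chr1", 10, "+", "CG", 2, 2))
    a.add(CytosineCall("chr1", 20, "+", "CG", 1, 0))
    b.add(CytosineCall("chr1", 10, "+", "CG", 3, 1))
    out = integrate_positions([a, b], "all", min_mappers=2, min_depth=1)
    assert [(c.pos, c.n_covering) for c in out] == [(10, 2)]


def test_min_mappers_monotonicity():
    """Raising the covering-mapper threshold never emits more positions."""
    for seed in (1, 2, 3):
        callsets = _three_callsets(seed=seed)
        counts = [
            len(integrate_positions(callsets, "wave", k, 1)) for k in (1, 2, 3)
        ]
        assert counts[0] >= counts[1] >= counts[2]


def test_equal_depth_equal_lambda_makes_methods_coincide():
    a = MapperCallSet("a", lam=7)
    b = MapperCallSet("b", lam=7)
    a.add(CytosineCall("chr1", 5, "+", "CG", 3, 4))
    b.add(CytosineCall("chr1", 5, "+", "CG", 6, 1))
    (c,) = integrate_positions([a, b], "all", 2, 1)
    assert c.level_wave == pytest.approx(c.level_ave, abs=1e-12)
    assert c.level_pwave == pytest.approx(c.level_ave, abs=1e-12)


def test_literal_zero_level_reading():
    """count_zero_level=False drops a mapper reporting a fully
    unmethylated site from n_i."""
    a = MapperCallSet("a", lam=5)
    b = MapperCallSet("b", lam=5)
    a.add(CytosineCall("chr1", 10, "+", "CG", 0, 6))
    b.add(CytosineCall("chr1", 10, "+", "CG", 3, 3))
    assert integrate_positions([a, b], "ave", 2, 1)[0].n_covering == 2
    assert integrate_positions([a, b], "ave", 2, 1, count_zero_level=False) == []


def test_usage_errors():
    with pytest.raises(UsageError):
        integrate_positions([], "ave")
    with pytest.raises(UsageError):
        integrate_positions(_three_callsets(), "median")
    with pytest.raises(UsageError):
        integrate_positions(_three_callsets(), "ave", min_mappers=0)
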