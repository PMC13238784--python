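import numpy as np
import pandas as pd
import pytest

import forestdiv as fd
from forestdiv.functional import FunctionalSpace

from conftest import make_abundance
from oracles import cwm_brute, fdis_brute, fdvar_brute, hull_volume_mc


def trait_table(values: dict) -> fd.TraitTable:
    """TraitTable replicating one value vector across the 5 traits, or a
    full per-trait dict."""
    first = next(iter(values.values()))
    if np.isscalar(first):
        data = {t: list(values.values()) for t in fd.TRAIT_NAMES}
    else:
        data = {t: [values[sp][i] for sp in values]
                for i, t in enumerate(fd.TRAIT_NAMES)}
    return fd.TraitTable(pd.DataFrame(data, index=list(values)))


def space_from(coords: dict) -> FunctionalSpace:
    df = pd.DataFrame.from_dict(coords, orient="index")
    return FunctionalSpace(coords=df, mean=df.mean(), std=df.std(ddof=1))


class TestCWM:
    def test_single_species(self):
        ab = make_abundance({"P1": {"A": 1.0}})
        out = fd.cwm(ab, trait_table({"A": 10.0}))
        assert out.loc["P1", "CWM_SLA"] == pytest.approx(10.0)

    def test_weighted_arithmetic(self):
        ab = make_abundance({"P1": {"A": 0.25, "B": 0.75}})
        out = fd.cwm(ab, trait_table({"A": 8.0, "B": 4.0}))
        assert out.loc["P1", "CWM_SLA"] == pytest.approx(5.0)

    def test_missing_species_named(self):
        ab = make_abundance({"P1": {"A": 0.5, "B": 0.5}})
        with pytest.raises(fd.ValidationError, match="B"):
            fd.cwm(ab, trait_table({"A": 8.0}))

    def test_raw_scale_not_standardized(self):
        ab = make_abundance({"P1": {"A": 0.5, "B": 0.5}})
        out = fd.cwm(ab, trait_table({"A": 100.0, "B": 300.0}))
        assert out.loc["P1", "CWM_LC"] == pytest.approx(200.0)


class TestFDis:
    def test_monoculture_is_zero(self):
        ab = make_abundance({"P1": {"A": 1.0}})
        sp = space_from({"A": [0.3, -1.2]})
        assert fd.fdis(ab, sp).loc["P1"] == pytest.approx(0.0)

    def test_two_species_one_dimension(self):
        ab = make_abundance({"P1": {"A": 0.5, "B": 0.5}})
        sp = space_from({"A": [0.0], "B": [2.0]})
        assert fd.fdis(ab, sp).loc["P1"] == pytest.approx(1.0)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = rng.integers(3, 8)
            coords = rng.standard_normal((k, 3))
            w = rng.dirichlet(np.ones(k))
            names = [f"s{i}" for i in range(k)]
            ab = make_abundance({"P1": dict(zip(names, w))})
            base = fd.fdis(ab, space_from(dict(zip(names, coords)))).loc["P1"]
            # random rotation + translation
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            moved = coords @ q + rng.standard_normal(3)
            rotated = fd.fdis(ab, space_from(dict(zip(names, moved)))).loc["P1"]
            assert rotated == pytest.approx(base, rel=1e-10)


class TestFRic:
    def unit_square_space(self):
        return space_from(
            {"A": [0.0, 0.0], "B": [1.0, 0.0], "C": [0.0, 1.0], "D": [1.0, 1.0]}
        )

    def test_community_equals_pool(self):
        ab = make_abundance({"P1": {s: 0.25 for s in "ABCD"}})
        fr, flag = fd.fric(ab, self.unit_square_space())
        assert fr.loc["P1"] == pytest.approx(1.0)
        assert flag.loc["P1"] == "ok"

    def test_triangle_is_half_the_square(self):
        ab = make_abundance({"P1": {"A": 0.1, "B": 0.6, "C": 0.3}})
        fr, _ = fd.fric(ab, self.unit_square_space())
        assert fr.loc["P1"] == pytest.approx(0.5)

    def test_abundance_ignored_beyond_presence(self):
        even = make_abundance({"P1": {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}})
        skew = make_abundance({"P1": {"A": 0.98, "B": 0.01, "C": 0.01}})
        sp = self.unit_square_space()
        assert fd.fric(even, sp)[0].loc["P1"] == fd.fric(skew, sp)[0].loc["P1"]

    def test_too_few_points_flagged_zero(self):
        ab = make_abundance({"P1": {"A": 0.5, "B": 0.5}})
        fr, flag = fd.fric(ab, self.unit_square_space())
        assert fr.loc["P1"] == 0.0 and flag.loc["P1"] == "degenerate"

    def test_collinear_points_flagged_zero(self):
        sp = space_from(
            {"A": [0.0, 0.0], "B": [1.0, 1.0], "C": [2.0, 2.0], "D": [0.0, 3.0]}
        )
        ab = make_abundance({"P1": {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}})
        fr, flag = fd.fric(ab, sp)
        assert fr.loc["P1"] == 0.0 and flag.loc["P1"] == "degenerate"

    def test_monotone_when_species_added(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((10, 2))
        names = [f"s{i}" for i in range(10)]
        sp = space_from(dict(zip(names, pts)))
        small = make_abundance({"P1": {n: 0.25 for n in names[:4]}})
        bigger = make_abundance({"P1": {n: 1 / 6 for n in names[:6]}})
        assert (fd.fric(bigger, sp)[0].loc["P1"]
                >= fd.fric(small, sp)[0].loc["P1"] - 1e-12)

    def test_matches_rejection_sampling_in_3d(self):
        rng = np.random.default_rng(21)
        pts = rng.standard_normal((12, 3))
        names = [f"s{i}" for i in range(12)]
        sp = space_from(dict(zip(names, pts)))
        ab = make_abundance({"P1": {n: 1 / 7 for n in names[:7]}})
        fr, _ = fd.fric(ab, sp)
        num = hull_volume_mc(pts[:7], np.random.default_rng(1))
        den = hull_volume_mc(pts, np.random.default_rng(2))
        assert fr.loc["P1"] == pytest.approx(num / den, rel=0.01)


class TestFDiv:
    def test_identical_traits_give_zero(self):
        ab = make_abundance({"P1": {"A": 0.4, "B": 0.6}})
        assert fd.fdiv(ab, trait_table({"A": 7.0, "B": 7.0})).loc["P1"] == 0.0

    def test_two_species_hand_computation(self):
        # one trait with values e and e^3, equal weights:
        # ln xbar = 2, V = 1, score = (2/pi) arctan 5
        ab = make_abundance({"P1": {"A": 0.5, "B": 0.5}})
        tt = trait_table({"A": np.e, "B": np.e**3})
        expected = 2.0 / np.pi * np.arctan(5.0)
        assert fd.fdiv(ab, tt).loc["P1"] == pytest.approx(expected, rel=1e-12)

    def test_score_saturates_below_one(self):
        ab = make_abundance({"P1": {"A": 0.5, "B": 0.5}})
        tt = trait_table({"A": 1e-8, "B": 1e8})
        v = fd.fdiv(ab, tt).loc["P1"]
        assert 0.99 < v < 1.0


def test_metrics_match_brute_force_oracles():
    """CWM, FDis and FDiv equal independent loop implementations on random
    communities (the standardized-space metrics get coordinates directly)."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        k = int(rng.integers(2, 10))
        names = [f"s{i}" for i in range(k)]
        w = rng.dirichlet(np.ones(k) * 0.7)
        weights = dict(zip(names, w))
        ab = make_abundance({"P1": weights})

        traits = np.exp(rng.normal(1.0, 0.6, (k, 5)))
        tt = trait_table({n: traits[i] for i, n in enumerate(names)})
        out = fd.cwm(ab, tt)
        for j, t in enumerate(fd.TRAIT_NAMES):
            expect = cwm_brute(weights, {n: traits[i, j] for i, n in enumerate(names)})
            assert out.loc["P1", f"CWM_{t}"] == pytest.approx(expect, abs=1e-10)

        coords = rng.standard_normal((k, 3))
        sp = space_from(dict(zip(names, coords)))
        expect = fdis_brute(weights, {n: coords[i] for i, n in enumerate(names)})
        assert fd.fdis(ab, sp).loc["P1"] == pytest.approx(expect, abs=1e-10)

        expect = fdvar_brute(weights, {n: traits[i] for i, n in enumerate(names)})
        assert fd.fdiv(ab, tt).loc["P1"] == pytest.approx(expect, abs=1e-10)


def test_functional_profile_shapes_and_standardization():
    rng = np.random.default_rng(2)
    names = [f"s{i}" for i in range(8)]
    rows = {}
    for p in range(4):
        w = rng.dirichlet(np.ones(8))
        rows[f"P{p}"] = dict(zip(names, w))
    ab = make_abundance(rows, stratum="overstory")
    tt = trait_table({n: np.exp(rng.normal(2, 0.5, 5)) for n in names})
    prof = fd.functional_profile(ab, tt)
    assert list(prof.columns) == [
        "stratum", "CWM_SLA", "CWM_LN", "CWM_LP", "CWM_LK", "CWM_LC",
        "FDis", "FRic", "FRic_flag", "FDiv",
    ]
    space = fd.functional_space(ab, tt)
    np.testing.assert_allclose(space.coords.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(space.coords.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_unit_invariance_of_fdis_and_fric():
    """Rescaling raw trait units changes nothing once traits are z-scored."""
    rng = np.random.default_rng(14)
    names = [f"s{i}" for i in range(9)]
    raw = np.exp(rng.normal(1, 0.5, (9, 5)))
    rows = {f"P{p}": dict(zip(names, rng.dirichlet(np.ones(9))))
            for p in range(3)}
    ab = make_abundance(rows)
    t1 = trait_table({n: raw[i] for i, n in enumerate(names)})
    scale = np.array([1000.0, 0.01, 3.7, 42.0, 0.5])
    t2 = trait_table({n: raw[i] * scale for i, n in enumerate(names)})
    s1, s2 = fd.functional_space(ab, t1), fd.functional_space(ab, t2)
    pd.testing.assert_series_equal(fd.fdis(ab, s1), fd.fdis(ab, s2))
    pd.testing.assert_series_equal(fd.fric(ab, s1)[0], fd.fric(ab, s2)[0])
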