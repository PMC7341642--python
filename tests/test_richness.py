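"""Incidence matrices, richness estimators, accumulation curves, ratio extrapolation."""

import itertools
import subprocess

import numpy as np
import pytest

from mycocheck import (IncidenceMatrix, accumulation_curve, bootstrap_richness,
                       build_incidence, chao2, hawksworth_estimate)
from mycocheck.errors import EmptySelectionError, InsufficientSamplesError
from tests.conftest import random_incidence


def matrix_from_freq(freqs, m):
    """Incidence matrix whose species i occurs in the first freqs[i] units."""
    presence = np.zeros((len(freqs), m), dtype=bool)
    for i, f in enumerate(freqs):
        presence[i, :f] = True
    return IncidenceMatrix([f"s{i}" for i in range(len(freqs))],
                           [f"u{j}" for j in range(m)], presence)


class TestBuildIncidence:
    def test_publication_unit(self, toy_checklist):
        im = build_incidence(toy_checklist, sample_unit="publication")
        assert im.presence.shape == (3, 2)
        assert im.S_obs == 3 and im.m == 2
        assert im.Q1 == 2 and im.Q2 == 1  # two one-pub species, one in both

    def test_record_unit_columns_are_singletons(self, toy_checklist):
        im = build_incidence(toy_checklist, sample_unit="record")
        assert im.presence.shape == (3, 4)
        assert (im.presence.sum(axis=0) == 1).all()

    def test_empty_scope_raises(self, toy_checklist):
        with pytest.raises(EmptySelectionError):
            build_incidence(toy_checklist, scope={"ML"})


class TestChao2:
    def test_no_uniques_returns_observed(self):
        im = matrix_from_freq([2, 3, 4], m=4)
        est = chao2(im)
        assert est.value == im.S_obs and est.se == 0.0

    def test_hand_computed_classic_value(self):
        # S_obs=5, m=4, Q1=2, Q2=1: 5 + (3/4) * 4/2 = 6.5
        im = matrix_from_freq([1, 1, 2, 3, 4], m=4)
        est = chao2(im)
        assert est.value == pytest.approx(6.5)
        assert est.variant == "classic"
        a, r = 3 / 4, 2.0
        expected_se = np.sqrt(1 * (a**2 * r**4 / 4 + a**2 * r**3 + a * r**2 / 2))
        assert est.se == pytest.approx(expected_se)

    def test_bias_corrected_fallback_when_no_duplicates(self):
        im = matrix_from_freq([1, 1, 1, 3], m=5)
        est = chao2(im)
        assert est.variant == "bias-corrected"
        assert est.value == pytest.approx(4 + (4 / 5) * 3 * 2 / 2)
        assert est.se >= 0

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientSamplesError):
            chao2(matrix_from_freq([1, 1], m=1))

    def test_never_below_observed_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            im = random_incidence(rng)
            assert chao2(im).value >= im.S_obs

    def test_se_matches_monte_carlo_sd(self):
        """Analytic Chao2 se tracks the replicate SD (lognormal detectability)."""
        rng = np.random.default_rng(7)
        s_true, m = 200, 50
        q = np.clip(0.10 * rng.lognormal(0.0, 1.0, size=s_true), 0.005, 0.95)
        values, ses = [], []
        for _ in range(500):
            presence = rng.random((s_true, m)) < q[:, None]
            keep = presence.sum(axis=1) > 0
            im = IncidenceMatrix([f"s{i}" for i in range(keep.sum())],
                                 [f"u{j}" for j in range(m)], presence[keep])
            est = chao2(im)
            values.append(est.value)
            ses.append(est.se)
        assert np.std(values, ddof=1) == pytest.approx(np.mean(ses), rel=0.25)


class TestBootstrap:
    def test_saturated_matrix_returns_observed(self):
        im = matrix_from_freq([3, 3, 3], m=3)
        est = bootstrap_richness(im, n_boot=50, seed=0)
        assert est.value == pytest.approx(im.S_obs)

    def test_hand_computed_value(self):
        # 2 species, m=2, incidences {1, 2}: 2 + (1 - 1/2)^2 = 2.25
        im = matrix_from_freq([1, 2], m=2)
        assert bootstrap_richness(im, n_boot=50, seed=0).value == pytest.approx(2.25)

    def test_se_reproducible_under_seed(self, sim_small):
        cl, _ = sim_small
        im = build_incidence(cl)
        a = bootstrap_richness(im, n_boot=100, seed=5)
        b = bootstrap_richness(im, n_boot=100, seed=5)
        assert a.se == b.se and a.value == b.value

    def test_never_below_observed_on_random_matrices(self):
        rng = np.random.default_rng(43)
        for _ in range(200):
            im = random_incidence(rng)
            assert bootstrap_richness(im, n_boot=30, seed=0).value >= im.S_obs - 1e-9


class TestAccumulationCurve:
    def test_full_effort_equals_observed(self, sim_small):
        cl, _ = sim_small
        im = build_incidence(cl)
        for method in ("exact", "random"):
            ac = accumulation_curve(im, method=method, n_perm=20, seed=1)
            assert ac.expected_S[-1] == pytest.approx(im.S_obs)

    def test_first_point_is_mean_per_sample_richness(self):
        rng = np.random.default_rng(9)
        im = random_incidence(rng, n_species=12, m=6)
        ac = accumulation_curve(im, method="exact")
        assert ac.expected_S[0] == pytest.approx(im.incidence_freq.sum() / im.m)

    def test_exact_equals_mean_over_all_orderings(self):
        rng = np.random.default_rng(11)
        im = random_incidence(rng, n_species=5, m=3)
        exact = accumulation_curve(im, method="exact").expected_S
        totals = np.zeros(im.m)
        for order in itertools.permutations(range(im.m)):
            seen = np.cumsum(im.presence[:, list(order)], axis=1) > 0
            totals += seen.sum(axis=0)
        assert exact == pytest.approx(totals / 6)

    def test_monotone_and_concave_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            im = random_incidence(rng)
            s = accumulation_curve(im, method="exact").expected_S
            diffs = np.diff(np.concatenate([[0.0], s]))
            assert (diffs >= -1e-9).all()
            assert (np.diff(diffs) <= 1e-9).all()

    def test_random_mean_converges_to_exact(self):
        rng = np.random.default_rng(13)
        im = random_incidence(rng, n_species=10, m=20)
        exact = accumulation_curve(im, method="exact").expected_S
        rand = accumulation_curve(im, method="random", n_perm=10_000, seed=2).expected_S
        assert np.max(np.abs(rand - exact)) < 0.15


class TestHawksworth:
    @pytest.mark.parametrize("S,P,E,pct", [
        (4843, 7072, 42_432, 11.4),
        (432, 2807, 16_842, 2.6),
    ])
    def test_printed_table_values(self, S, P, E, pct):
        hw = hawksworth_estimate(S, P)
        assert hw.E == E and hw.pct_known_display == pct

    def test_saturation_and_excess_flag(self):
        assert hawksworth_estimate(600, 100).pct_known_display == 100.0
        over = hawksworth_estimate(700, 100)
        assert over.exceeds_expectation and over.pct_known > 100

    def test_nonpositive_plants_rejected(self):
        with pytest.raises(ValueError):
            hawksworth_estimate(10, 0)


def test_estimators_match_vegan_specpool(tmp_path):
    """Independent cross-check of Chao2 (value and se) and bootstrap against vegan."""
    rng = np.random.default_rng(5)  # yields Q1=12, Q2=6: classic branch exercised
    im = random_incidence(rng, n_species=20, m=10)
    csv = tmp_path / "m.csv"
    # vegan::specpool wants sites x species
    np.savetxt(csv, im.presence.T.astype(int), delimiter=",", fmt="%d")
    script = tmp_path / "specpool.R"
    script.write_text(
        f'x <- as.matrix(read.csv("{csv}", header=FALSE))\n'
        "suppressMessages(library(vegan))\n"
        "p <- specpool(x)\n"
        'cat(p$chao, p$chao.se, p$boot, sep="\\n")\n')
    res = subprocess.run(["Rscript", "--vanilla", str(script)],
                         capture_output=True, text=True, check=True)
    chao_r, chao_se_r, boot_r = map(float, res.stdout.strip().split("\n"))
    est = chao2(im)
    assert est.value == pytest.approx(chao_r, rel=1e-6)
    assert est.se == pytest.approx(chao_se_r, rel=1e-4)
    assert bootstrap_richness(im, n_boot=50, seed=0).value == pytest.approx(
        boot_r, rel=1e-6)
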