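import numpy as np
import pytest
import statsmodels.api as sm

from phytoclim.exceptions import DegenerateSampleError, ValidationError
from phytoclim.fitting import (
    FitSample,
    choose_threshold,
    classify_env_zones,
    confusion,
    fit_cloglog_batch,
    fit_species,
    project_species,
    sample_presences,
    sample_pseudo_absences,
    suitability_score,
    thin_occurrences,
    tss,
)
from phytoclim.grids import Grid
from phytoclim.synthetic import generate_species

import pandas as pd


class TestEnvZones:
    def test_two_blobs_recovered_exactly(self, world):
        clim = world["clim"]
        # force two sharply different climate regimes in the same world
        import copy
        c2 = copy.deepcopy(clim)
        half = clim.grid.n_rows // 2
        c2.tmean[:, half:, :] += 60.0
        c2.tmin[:, half:, :] += 60.0
        c2.tmax[:, half:, :] += 60.0
        zones = classify_env_zones(c2, world["moisture"], k=2, seed=1)
        rows, _ = np.nonzero(clim.grid.land_mask)
        top = zones.zone_of_cell[rows < half]
        bottom = zones.zone_of_cell[rows >= half]
        assert np.unique(top).size == 1 and np.unique(bottom).size == 1
        assert top[0] != bottom[0]

    def test_seeded_determinism(self, world):
        a = classify_env_zones(world["clim"], world["moisture"], k=6, seed=9)
        b = classify_env_zones(world["clim"], world["moisture"], k=6, seed=9)
        assert np.array_equal(a.zone_of_cell, b.zone_of_cell)

    def test_every_zone_nonempty_and_replicates_agree(self, world):
        from sklearn.metrics import adjusted_rand_score
        ref = classify_env_zones(world["clim"], world["moisture"], k=6, seed=0)
        assert np.unique(ref.zone_of_cell).size == 6
        for seed in range(1, 4):
            rep = classify_env_zones(world["clim"], world["moisture"], k=6, seed=seed)
            assert adjusted_rand_score(ref.zone_of_cell, rep.zone_of_cell) > 0.5


class TestThinning:
    def _grid(self):
        return Grid(n_rows=10, n_cols=10, cell_size=10.0, origin=(0.0, 100.0))

    def test_five_records_in_one_cell_collapse(self):
        g = self._grid()
        df = pd.DataFrame({"species_id": ["a"] * 5,
                           "x": [5.0, 6.0, 7.0, 5.5, 6.5], "y": [95.0] * 5})
        out = thin_occurrences(df, g)
        assert len(out) == 1

    def test_unique_records_unchanged(self):
        g = self._grid()
        df = pd.DataFrame({"species_id": ["a", "a", "b"],
                           "x": [5.0, 15.0, 5.0], "y": [95.0, 95.0, 95.0]})
        assert len(thin_occurrences(df, g)) == 3

    def test_out_of_grid_dropped_and_counted(self):
        g = self._grid()
        df = pd.DataFrame({"species_id": ["a", "a"], "x": [5.0, -50.0],
                           "y": [95.0, 95.0]})
        out = thin_occurrences(df, g)
        assert len(out) == 1 and out.attrs["n_dropped"] == 1

    def test_output_size_equals_distinct_pairs(self):
        g = self._grid()
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "species_id": rng.choice(["a", "b", "c"], 1000),
            "x": rng.uniform(0, 100, 1000), "y": rng.uniform(0, 100, 1000),
        })
        out = thin_occurrences(df, g)
        row, col = g.cell_of_xy(df.x.to_numpy(), df.y.to_numpy())
        expected = len({(s, r, c) for s, r, c in zip(df.species_id, row, col)})
        assert len(out) == expected


class _FakeZones:
    """Minimal zone model with prescribed labels."""

    def __init__(self, labels, k):
        from phytoclim.fitting import EnvZoneModel
        self.model = EnvZoneModel(k=k, medoids=np.zeros((k, 2)),
                                  zone_of_cell=np.asarray(labels))

    def __getattr__(self, item):
        return getattr(self.model, item)


class TestPresenceSampling:
    def test_below_cap_returns_all(self):
        zones = _FakeZones(np.zeros(200, int), 1)
        cells = np.arange(120)
        assert np.array_equal(sample_presences(cells, zones, cap=400, seed=0), cells)

    def test_minimum_presences_enforced(self):
        zones = _FakeZones(np.zeros(10, int), 1)
        with pytest.raises(DegenerateSampleError):
            sample_presences(np.arange(6), zones)

    def test_proportions_conserved_80_20(self):
        labels = np.array([0] * 800 + [1] * 200)
        zones = _FakeZones(labels, 2)
        out = sample_presences(np.arange(1000), zones, cap=400, seed=3)
        picked = labels[out]
        assert (picked == 0).sum() == 320 and (picked == 1).sum() == 80

    def test_counts_follow_largest_remainder(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 10, 1500)
        zones = _FakeZones(labels, 10)
        out = sample_presences(np.arange(1500), zones, cap=400, seed=5)
        counts = np.bincount(labels[out], minlength=10)
        # independent largest-remainder apportionment
        full = np.bincount(labels, minlength=10)
        quota = full / full.sum() * 400
        ref = np.floor(quota).astype(int)
        order = np.argsort(-(quota - ref))
        ref[order[:400 - ref.sum()]] += 1
        assert np.array_equal(counts, ref)


class TestPseudoAbsences:
    def test_inverse_weighting_80_20(self):
        """Presence zones 80/20 -> absence zone expectation 20/80."""
        labels = np.array([0] * 2000 + [1] * 2000)
        zones = _FakeZones(labels, 2)
        presences = np.concatenate([np.arange(160), 2000 + np.arange(40)])
        counts = np.zeros(2)
        n_draws = 50
        for seed in range(n_draws):
            absc = sample_pseudo_absences(presences, zones, seed=seed)
            assert absc.size == presences.size
            assert np.intersect1d(absc, presences).size == 0
            counts += np.bincount(labels[absc], minlength=2)
        frac = counts / counts.sum()
        n_total = 200 * n_draws
        se = np.sqrt(0.2 * 0.8 / n_total)
        assert abs(frac[0] - 0.2) < 4 * se

    def test_small_species_get_exactly_20(self):
        labels = np.tile(np.arange(20), 100)
        zones = _FakeZones(labels, 20)
        absc = sample_pseudo_absences(np.arange(10), zones, seed=0)
        assert absc.size == 20

    def test_multinomial_expectation_four_zones(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 4, 4000)
        zones = _FakeZones(labels, 4)
        presences = np.flatnonzero(labels == 0)[:100]
        presences = np.concatenate([presences, np.flatnonzero(labels == 1)[:50],
                                    np.flatnonzero(labels == 2)[:30],
                                    np.flatnonzero(labels == 3)[:20]])
        prop = np.array([100, 50, 30, 20]) / 200
        w = (1 / prop) / (1 / prop).sum()
        counts = np.zeros(4)
        for seed in range(50):
            absc = sample_pseudo_absences(presences, zones, seed=seed)
            counts += np.bincount(labels[absc], minlength=4)
        frac = counts / counts.sum()
        se = np.sqrt(w * (1 - w) / (200 * 50))
        assert np.all(np.abs(frac - w) < 5 * se)


class TestSuitability:
    def test_zero_biomass_floor_case(self):
        p = suitability_score(0.0, (0.0, 1.0))
        assert p == pytest.approx(1 - np.exp(-1e-6), rel=1e-6)

    def test_identity_calibration(self):
        B = np.array([0.5, 1.0, 2.0])
        p = suitability_score(B, (0.0, 1.0))
        np.testing.assert_allclose(p, 1 - np.exp(-(B + 1e-6)), rtol=1e-12)

    def test_strictly_increasing_in_biomass(self):
        rng = np.random.default_rng(7)
        B = np.sort(rng.uniform(0, 50, 10_000))
        p = suitability_score(B, (-2.0, 0.7))
        assert np.all(np.diff(p) > 0)


class TestThreshold:
    def test_worked_example_lowest_maximizer(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert choose_threshold(scores, labels) == pytest.approx(0.5)

    def test_matches_bruteforce_on_interleaved_scores(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.all() or not labels.any():
                continue
            thr = choose_threshold(scores, labels)
            got = sum(confusion(scores, labels, thr)[i] for i in (0, 3))
            best = max(
                sum(confusion(scores, labels, c)[i] for i in (0, 3))
                for c in np.concatenate([scores, [scores.min() - 1, scores.max() + 1]])
            )
            assert got == best

    def test_separable_scores_give_perfect_split(self):
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2])
        labels = np.array([1, 1, 1, 0, 0])
        thr = choose_threshold(scores, labels)
        tp, fp, fn, tn = confusion(scores, labels, thr)
        assert tp + tn == 5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateSampleError):
            choose_threshold(np.array([0.1, 0.2]), np.array([1, 1]))


class TestTSS:
    def test_perfect_classifier(self):
        assert tss(10, 0, 0, 10) == 1.0

    def test_sensitivity_plus_specificity_minus_one(self):
        assert tss(9, 2, 1, 8) == pytest.approx(0.9 + 0.8 - 1.0)

    def test_all_positive_prediction_scores_zero(self):
        assert tss(10, 10, 0, 0) == pytest.approx(0.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            tss(0, 0, 0, 5)


class TestCloglogCalibration:
    def test_matches_statsmodels_glm(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1.5, 400)
        eta = -0.5 + 0.8 * z
        p = 1 - np.exp(-np.exp(eta))
        y = (rng.random(400) < p).astype(float)
        b0, b1, nll = fit_cloglog_batch(z[None, :], y, n_iter=60)
        X = sm.add_constant(z)
        ref = sm.GLM(y, X, family=sm.families.Binomial(
            link=sm.families.links.CLogLog())).fit()
        assert b0[0] == pytest.approx(ref.params[0], abs=2e-3)
        assert b1[0] == pytest.approx(ref.params[1], abs=2e-3)
        assert nll[0] == pytest.approx(-ref.llf, rel=1e-4)

    def test_batch_consistency(self):
        rng = np.random.default_rng(10)
        z = rng.normal(0, 1, (5, 100))
        y = rng.integers(0, 2, 100).astype(float)
        b0, b1, nll = fit_cloglog_batch(z, y)
        for s in range(5):
            s0, s1, snll = fit_cloglog_batch(z[s][None], y)
            assert s0[0] == pytest.approx(b0[s]) and snll[0] == pytest.approx(nll[s])


class TestFitSpecies:
    def test_fewer_than_seven_presences_rejected(self):
        with pytest.raises(DegenerateSampleError):
            FitSample(np.arange(6), np.arange(10, 30))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError):
            FitSample(np.arange(10), np.arange(5, 25))

    def test_seeded_determinism(self, world):
        sp = generate_species(14, world["clim"], seed=51, moisture=world["moisture"],
                              occurrences_per_species=60)[0]
        pres = sp.occurrence_cells[:40]
        absc = np.setdiff1d(np.flatnonzero(~sp.true_suitable), pres)[:40]
        sample = FitSample(pres, absc)
        idx = sample.cells
        kw = dict(seed=4, generations=8, popsize=2)
        m1 = fit_species(sample, world["t"][idx], world["w"][idx],
                         world["a_max"]["C3"][idx], **kw)
        m2 = fit_species(sample, world["t"][idx], world["w"][idx],
                         world["a_max"]["C3"][idx], **kw)
        np.testing.assert_array_equal(m1.params.to_vector(), m2.params.to_vector())
        assert m1.nll == m2.nll and m1.tss == m2.tss

    def test_more_generations_never_worse(self, world):
        sp = generate_species(14, world["clim"], seed=53, moisture=world["moisture"],
                              occurrences_per_species=60)[1]
        pres = sp.occurrence_cells[:40]
        absc = np.setdiff1d(np.flatnonzero(~sp.true_suitable), pres)[:40]
        sample = FitSample(pres, absc)
        idx = sample.cells
        args = (sample, world["t"][idx], world["w"][idx], world["a_max"]["C3"][idx])
        short = fit_species(*args, seed=4, generations=5, popsize=2)
        long = fit_species(*args, seed=4, generations=40, popsize=2)
        assert long.nll <= short.nll + 1e-9

    def test_separable_sample_reaches_perfect_sample_tss(self, world):
        """Presences exactly where the true model grows, absences where it
        cannot: the refit separates the sample perfectly."""
        sp = generate_species(14, world["clim"], seed=55, moisture=world["moisture"],
                              occurrences_per_species=100)[2]
        pres = sp.occurrence_cells
        absc = np.setdiff1d(np.flatnonzero(~sp.true_suitable), pres)
        rng = np.random.default_rng(0)
        absc = rng.choice(absc, size=min(absc.size, pres.size), replace=False)
        sample = FitSample(pres, absc)
        idx = sample.cells
        m = fit_species(sample, world["t"][idx], world["w"][idx],
                        world["a_max"]["C3"][idx], seed=11, generations=300,
                        popsize=2)
        assert m.tss == pytest.approx(1.0)

    def test_threshold_reproduces_confusion_matrix(self, world):
        sp = generate_species(14, world["clim"], seed=57, moisture=world["moisture"],
                              occurrences_per_species=60)[0]
        pres = sp.occurrence_cells[:30]
        absc = np.setdiff1d(np.flatnonzero(~sp.true_suitable), pres)[:30]
        sample = FitSample(pres, absc)
        idx = sample.cells
        m = fit_species(sample, world["t"][idx], world["w"][idx],
                        world["a_max"]["C3"][idx], seed=2, generations=10, popsize=2)
        scores, _ = project_species(m, world["t"][idx], world["w"][idx],
                                    world["a_max"]["C3"][idx])
        tp, fp, fn, tn = confusion(scores, sample.labels, m.threshold)
        assert tss(tp, fp, fn, tn) == pytest.approx(m.tss)
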