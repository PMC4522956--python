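"""Sampler correctness, energy closed forms, and entropy estimators."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lipas.errors import ValidationError
from lipas.lipid_models import CLASS_SP3, build_coordinates, make_topology
from lipas.mc_ensemble import (
    K_B,
    EnergyModel,
    bound_state_frequency,
    classify_torsion,
    count_gauche,
    discretize_boltzmann,
    ensemble_entropy,
    lj_pair,
    metropolis_sample,
    torsion_energy,
    total_energy,
)

TOY_STATES = (-60.0, 60.0, 180.0)


def boltzmann_enumeration(topology, model, states=TOY_STATES):
    """Exact Boltzmann weights over the discrete torsion grid."""
    combos = list(itertools.product(states, repeat=topology.n_torsions))
    e = np.array(
        [total_energy(build_coordinates(topology, list(c)), model) for c in combos]
    )
    w = np.exp(-(e - e.min()) / model.kT)
    return combos, w / w.sum()


def snapshot_state_counts(result, combos, states):
    snaps = result.torsion_snapshots[::10]  # thin against autocorrelation
    idx = np.zeros(len(snaps), dtype=int)
    for k, combo in enumerate(combos):
        match = np.ones(len(snaps), dtype=bool)
        for q, val in enumerate(combo):
            match &= np.abs(snaps[:, q] - val) < 1.0
        idx[match] = k
    return np.bincount(idx, minlength=len(combos))


class TestEnergyModel:
    def test_kT_at_300K(self):
        model = EnergyModel()
        assert model.kT == pytest.approx(K_B * 300.0, abs=1e-12)
        assert model.kT == pytest.approx(0.59616, abs=1e-5)

    def test_gauche_anti_gap_matches_declared_coefficients(self):
        """Butane fragment: E(one gauche) − E(all anti) = series gap at 60°."""
        butane = make_topology({"n_carbons": 4})
        model = EnergyModel(min_bond_separation=99)
        e_anti = total_energy(build_coordinates(butane, [180.0]), model)
        e_gauche = total_energy(build_coordinates(butane, [60.0]), model)
        a1, a3 = dict(model.torsion_coefficients)[CLASS_SP3]
        expected = (a1 * (1 + math.cos(math.radians(60))) +
                    a3 * (1 + math.cos(math.radians(180)))) - 0.0
        assert e_gauche - e_anti == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9, abs=1e-12)

    def test_lj_zero_crossing_and_minimum(self):
        assert lj_pair(0.118, 3.905, 3.905) == pytest.approx(0.0, abs=1e-15)
        r_min = 2.0 ** (1.0 / 6.0) * 3.905
        assert lj_pair(0.118, 3.905, r_min) == pytest.approx(-0.118, abs=1e-12)

    def test_all_anti_total_is_pure_lj_tail(self, default_model):
        """Torsion term vanishes at anti; the rest is the 1-5+ LJ sum,
        recomputed here with an independent double loop."""
        topo = make_topology("stearic")
        conf = build_coordinates(topo, [180.0] * 15)
        lj = dict(default_model.lj_params)
        sites = topo.site_types()
        expected = 0.0
        for i in range(18):
            for j in range(i + 4, 18):
                r = float(np.linalg.norm(conf.coordinates[i] - conf.coordinates[j]))
                if r < default_model.lj_cutoff:
                    eps = math.sqrt(lj[sites[i]][0] * lj[sites[j]][0])
                    sig = (lj[sites[i]][1] + lj[sites[j]][1]) / 2.0
                    expected += lj_pair(eps, sig, r)
        assert total_energy(conf, default_model) == pytest.approx(expected, abs=1e-9)

    def test_missing_torsion_class_is_configuration_error(self):
        from lipas.errors import ConfigurationError

        model = EnergyModel(torsion_coefficients=((CLASS_SP3, (0.6, 2.0)),))
        with pytest.raises(ConfigurationError, match="allylic"):
            model.arrays_for(make_topology("oleic"))

    def test_kernel_agrees_with_reference_energy(self, default_model, rng):
        from lipas import _kernels

        for name in ["stearic", "oleic", "linoleic", "cis-vaccenic"]:
            topo = make_topology(name)
            arr = default_model.arrays_for(topo)
            buf = np.zeros((arr["n"], 3))
            for _ in range(5):
                t = rng.uniform(-179.9, 180.0, topo.n_torsions)
                for i, v in topo.frozen_torsions().items():
                    t[i] = v
                e_kernel = _kernels.total_energy(
                    arr["n"], arr["r"], arr["theta"], np.radians(t),
                    arr["a1"], arr["a3"], arr["pair_i"], arr["pair_j"],
                    arr["eps4"], arr["sigma2"], arr["cutoff2"], buf,
                )
                e_ref = total_energy(build_coordinates(topo, t), default_model)
                assert e_kernel == pytest.approx(e_ref, rel=1e-9, abs=1e-9)


class TestSampler:
    def test_toy_chain_matches_boltzmann_enumeration(
        self, toy_hexane, torsion_only_model
    ):
        """27-state detailed-balance check against exhaustive enumeration."""
        combos, p = boltzmann_enumeration(toy_hexane, torsion_only_model)
        rejections = 0
        for seed in range(3):
            res = metropolis_sample(
                toy_hexane, torsion_only_model, n_steps=200_000, burn_in=20_000,
                seed=seed, discrete_states=TOY_STATES, record_snapshots=True,
            )
            counts = snapshot_state_counts(res, combos, TOY_STATES)
            _, pval = stats.chisquare(counts, p * counts.sum())
            if pval < 0.01:
                rejections += 1
        assert rejections == 0

    def test_infinite_temperature_accepts_everything(self, toy_hexane):
        # bounded (torsion-only) energies: kT ≫ max ΔE accepts every move
        model = EnergyModel(temperature=1e6, min_bond_separation=99)
        res = metropolis_sample(toy_hexane, model, n_steps=20_000, seed=0)
        assert res.accepted_fraction == pytest.approx(1.0, abs=1e-3)

    def test_same_seed_gives_bitwise_identical_traces(self, toy_hexane):
        a = metropolis_sample(toy_hexane, n_steps=5_000, seed=42)
        b = metropolis_sample(toy_hexane, n_steps=5_000, seed=42)
        assert np.array_equal(a.energies, b.energies)
        c = metropolis_sample(toy_hexane, n_steps=5_000, seed=43)
        assert not np.array_equal(a.energies, c.energies)

    def test_frozen_torsions_never_move(self):
        res = metropolis_sample("oleic", n_steps=3_000, burn_in=0, seed=0,
                                record_snapshots=True)
        assert np.all(res.torsion_snapshots[:, 7] == 0.0)

    def test_entropy_nonincreasing_as_temperature_drops(
        self, toy_hexane, torsion_only_model
    ):
        hot = metropolis_sample(toy_hexane, torsion_only_model,
                                n_steps=100_000, seed=0,
                                discrete_states=TOY_STATES)
        cold = metropolis_sample(
            toy_hexane, torsion_only_model.with_temperature(30.0),
            n_steps=100_000, seed=0, discrete_states=TOY_STATES,
        )
        assert cold.entropy <= hot.entropy

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(n_steps=0), "n_steps"),
            (dict(n_steps=100, burn_in=100), "burn_in"),
        ],
    )
    def test_invalid_run_parameters(self, toy_hexane, kwargs, match):
        with pytest.raises(ValidationError, match=match):
            metropolis_sample(toy_hexane, **kwargs)


class TestHistogramAndEntropy:
    def test_constant_trace_single_bin(self):
        edges, p = discretize_boltzmann(np.full(100, 3.7), 0.5)
        assert len(p) == 1 and p[0] == 1.0

    def test_uniform_trace_even_bins(self, rng):
        x = rng.uniform(0.0, 10.0, 200_000)
        x[0], x[1] = 0.0, 10.0  # pin the range
        edges, p = discretize_boltzmann(x, 1.0)
        assert len(p) == 10
        assert np.abs(p - 0.1).max() < 0.01

    @pytest.mark.parametrize("n", [2, 17, 1000])
    def test_normalization(self, rng, n):
        _, p = discretize_boltzmann(rng.normal(size=n), 0.3)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (p >= 0).all()

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            discretize_boltzmann([], 0.5)
        with pytest.raises(ValidationError):
            discretize_boltzmann([1.0, 2.0], 0.0)

    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0], 0.0),
            ([0.5, 0.5], math.log(2.0)),
            ([0.5, 0.5, 0.0], math.log(2.0)),  # 0·ln 0 ≡ 0
            ([1.0 / 7.0] * 7, math.log(7.0)),
        ],
    )
    def test_entropy_closed_forms(self, p, expected):
        assert ensemble_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_entropy_bounded_by_log_bins(self, rng):
        for _ in range(20):
            raw = rng.random(rng.integers(1, 30))
            p = raw / raw.sum()
            assert 0.0 <= ensemble_entropy(p) <= math.log(len(p)) + 1e-12

    def test_entropy_input_validation(self):
        with pytest.raises(ValidationError, match="negative"):
            ensemble_entropy([1.1, -0.1])
        with pytest.raises(ValidationError, match="sum"):
            ensemble_entropy([0.4, 0.4])


@pytest.fixture(scope="module")
def short_runs():
    model = EnergyModel()
    return {
        name: metropolis_sample(name, model, n_steps=50_000, seed=0)
        for name in ("stearic", "oleic", "linoleic")
    }


class TestBoundStateFrequency:
    def test_modal_bin_center(self, short_runs):
        res = short_runs["stearic"]
        k = int(np.argmax(res.probabilities))
        center = 0.5 * (res.bin_edges[k] + res.bin_edges[k + 1])
        mass, _ = bound_state_frequency(res, center)
        assert mass == res.probabilities.max()

    def test_energy_below_ensemble_range(self, short_runs):
        mass, pct = bound_state_frequency(short_runs["oleic"], -1e6)
        assert mass == 0.0 and pct == 0.0

    def test_energy_above_ensemble_range(self, short_runs):
        mass, pct = bound_state_frequency(short_runs["oleic"], 1e6)
        assert mass == 0.0 and pct == 100.0

    @pytest.mark.parametrize(
        "lipid, e_bound", [("stearic", -3.0), ("oleic", 4.0), ("linoleic", 37.0)]
    )
    def test_reported_bound_enthalpies_evaluate(self, short_runs, lipid, e_bound):
        """The putative bound-state enthalpies are valid query points."""
        mass, pct = bound_state_frequency(short_runs[lipid], e_bound)
        assert 0.0 <= mass <= 1.0
        assert 0.0 <= pct <= 100.0


class TestTorsionClassification:
    @pytest.mark.parametrize(
        "angle, expected",
        [
            (180.0, "anti"), (-150.0, "anti"), (121.0, "anti"),
            (60.0, "gauche"), (-60.0, "gauche"), (120.0, "gauche"),
            (31.0, "gauche"), (270.0, "gauche"),  # normalized to −90°
            (0.0, "cis"), (30.0, "cis"), (-15.0, "cis"), (360.0, "cis"),
        ],
    )
    def test_classify(self, angle, expected):
        assert classify_torsion(angle) == expected

    def test_count_gauche_all_anti(self):
        assert count_gauche(build_coordinates("stearic", [180.0] * 15)) == 0

    def test_count_gauche_every_torsion(self):
        conf = build_coordinates("stearic", [60.0] * 15)
        assert count_gauche(conf) == 15

    def test_count_gauche_excludes_frozen_cis(self):
        # oleic all-anti except the frozen cis: the 0° torsion is not gauche
        # anyway, but a cis-frozen bond must never leak into the count
        conf = build_coordinates("oleic", [60.0] * 14)
        assert count_gauche(conf, exclude_frozen=True) == 14
        assert count_gauche(conf, exclude_frozen=False) == 14
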