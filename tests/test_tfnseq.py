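import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from kodep.synth import SimConfig, TrueGene, simulate_tfnseq
from kodep.tfnseq import (
    AbundanceTrajectory,
    ModelFits,
    class_fractions,
    fit_library,
    fit_models,
    halving_time,
    overabundance,
    relative_abundance,
    replicate_error,
    select_model,
)

T4 = np.array([0.0, 2.0, 4.0, 6.0])


def _traj(counts, totals, times=T4, gene="g"):
    return AbundanceTrajectory(gene, np.asarray(times, dtype=float),
                               np.asarray(counts), np.asarray(totals))


class TestTrajectory:
    def test_hand_arithmetic(self):
        tr = _traj([100, 50], [1000, 2000], times=[0.0, 2.0])
        assert np.allclose(tr.rel_abundance, [1.0, 0.25])
        assert tr.f0 == pytest.approx(0.1)

    def test_proportional_counts_are_flat(self):
        tr = _traj([10, 20, 40, 80], [100, 200, 400, 800])
        assert np.allclose(tr.rel_abundance, 1.0)

    def test_invariants(self):
        with pytest.raises(ValueError):
            _traj([10, 200], [100, 100], times=[0.0, 2.0])  # count > total
        with pytest.raises(ValueError):
            _traj([0, 10], [100, 100], times=[0.0, 2.0])  # zero at t = 0
        with pytest.raises(ValueError):
            _traj([10, 10], [100, 100], times=[2.0, 4.0])  # missing t = 0
        with pytest.raises(ValueError):
            _traj([10, 10], [100, 0], times=[0.0, 2.0])  # zero total


class TestRelativeAbundance:
    def test_drop_low_count_with_reason(self):
        counts = pd.DataFrame(
            [[100, 90, 80], [5, 4, 3]],
            index=["keep", "shallow"],
            columns=[0.0, 2.0, 4.0],
        )
        trajs, dropped = relative_abundance(counts, min_count0=20)
        assert [tr.gene_id for tr in trajs] == ["keep"]
        assert dropped["gene_id"].tolist() == ["shallow"]
        assert "count(0)" in dropped["reason"].iloc[0]

    def test_header_contracts(self):
        counts = pd.DataFrame([[100, 90]], index=["g"], columns=["t=2", "t=4"])
        with pytest.raises(ValueError):
            relative_abundance(counts)  # no t = 0 column
        counts2 = pd.DataFrame([[100, 90, 80]], index=["g"], columns=[0.0, 4.0, 2.0])
        with pytest.raises(ValueError):
            relative_abundance(counts2)  # not increasing


class TestFitModels:
    def test_flat_trajectory_all_models_tie(self):
        tr = _traj([1000, 1000, 1000, 1000], [10000, 10000, 10000, 10000])
        fits = fit_models(tr)
        assert fits.ll_no_effect == pytest.approx(fits.ll_sufficiency, abs=1e-6)
        assert fits.ll_no_effect == pytest.approx(fits.ll_overabundance, abs=1e-6)
        assert fits.delta_sufficiency == pytest.approx(0.0, abs=1e-3)

    def test_exact_piecewise_recovery(self):
        # r = (1, 1, 0.25, 0.0625): wild-type growth to T = 2, then halving
        # of the relative abundance every hour (delta = ln 2)
        counts = np.array([10000, 10000, 2500, 625])
        tr = _traj(counts, np.full(4, 1_000_000))
        fits = fit_models(tr)
        assert fits.T_overabundance == pytest.approx(2.0, abs=0.02)
        assert fits.delta_overabundance == pytest.approx(math.log(2.0), rel=0.01)

    def test_nesting_on_simulated_genes(self):
        truth = [TrueGene("ess", True, "overabundance", 1.5, 10.0)] + [
            TrueGene(f"flat{i}", False, "no_effect") for i in range(20)
        ]
        counts = simulate_tfnseq(truth, SimConfig(depth=100_000, seed=4))
        trajs, _ = relative_abundance(counts)
        for tr in trajs:
            fits = fit_models(tr)
            assert fits.ll_no_effect <= fits.ll_sufficiency + 1e-9
            assert fits.ll_sufficiency <= fits.ll_overabundance + 1e-9

    def test_matches_brute_force_oracle_on_small_instances(self):
        cases = [
            ([8, 6, 3, 1], [50, 50, 50, 50]),
            ([20, 20, 10, 2], [40, 40, 40, 40]),
            ([12, 12, 12, 12], [48, 48, 48, 48]),
        ]
        for counts, totals in cases:
            tr = _traj(counts, totals)
            fits = fit_models(tr)
            oracle = oracles.brute_force_trajectory_fit(T4, counts, totals)
            assert fits.ll_no_effect == pytest.approx(oracle["ll_no_effect"], abs=1e-9)
            # the profiled optimizer must do at least as well as the
            # exhaustive grid, and the grid is near-exhaustive
            assert fits.ll_overabundance >= oracle["ll_overabundance"] - 1e-6
            assert fits.ll_overabundance <= oracle["ll_overabundance"] + 0.02
            assert fits.ll_sufficiency >= oracle["ll_sufficiency"] - 1e-6
            assert fits.ll_sufficiency <= oracle["ll_sufficiency"] + 0.02

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError):
            fit_models(_traj([10, 10], [100, 100], times=[0.0, 2.0]))


class TestSelectModel:
    def test_flat_is_no_effect(self):
        tr = _traj([1000, 1000, 1000, 1000], [10000, 10000, 10000, 10000])
        call = select_model(fit_models(tr))
        assert call.model == "no_effect"
        assert call.p_no_effect == pytest.approx(1.0)

    def test_noise_free_sufficiency(self):
        # r decays from t = 0: exp(-0.5 t) at t = (0, 2, 4, 6)
        r = np.exp(-0.5 * T4)
        counts = np.round(20000 * r).astype(int)
        call = select_model(fit_models(_traj(counts, np.full(4, 1_000_000))))
        assert call.model == "sufficiency"
        assert call.log10_o == 0.0

    def test_overabundance_maps_through_k0(self):
        counts = np.array([10000, 10000, 2500, 625])
        call = select_model(fit_models(_traj(counts, np.full(4, 1_000_000))), k0=1.0)
        assert call.model == "overabundance"
        assert call.log10_o == pytest.approx(call.T_hat / math.log(10.0))

    def test_boundary_arrest_time_flagged_censored(self):
        fits = ModelFits("g", ll_no_effect=-100.0, ll_sufficiency=-60.0,
                         ll_overabundance=-40.0, delta_sufficiency=0.5,
                         delta_overabundance=1.0, T_overabundance=6.0, t_last=6.0)
        call = select_model(fits)
        assert call.model == "overabundance" and call.censored

    def test_nonconvergence_is_unclassifiable(self):
        fits = ModelFits("g", -10.0, -9.0, -8.0, 0.1, 0.1, 1.0, 6.0, converged=False)
        assert select_model(fits).model == "unclassifiable"


class TestOverabundance:
    def test_closed_forms(self):
        call = select_model(
            fit_models(_traj([10000, 10000, 2500, 625], np.full(4, 1_000_000)))
        )
        assert overabundance(call, 1.0) == pytest.approx(math.exp(1.0 * call.T_hat))
        suff = select_model(
            fit_models(_traj(np.round(20000 * np.exp(-0.5 * T4)).astype(int),
                             np.full(4, 1_000_000)))
        )
        assert overabundance(suff, 1.0) == 1.0

    def test_requires_k0_and_classification(self):
        flat = select_model(fit_models(_traj([1000] * 4, [10000] * 4)))
        with pytest.raises(ValueError):
            overabundance(flat, 1.0)
        over = select_model(fit_models(_traj([10000, 10000, 2500, 625], np.full(4, 1_000_000))))
        with pytest.raises(ValueError):
            overabundance(over, None)


class TestHalvingTime:
    def test_log_interpolated_crossing(self):
        # r = (1, 0.8, 0.4): crossing of 0.5 between t = 2 and t = 4
        tr = _traj([10000, 8000, 4000], [100000] * 3, times=[0.0, 2.0, 4.0])
        expected = 2.0 + 2.0 * (math.log(0.8) - math.log(0.5)) / (math.log(0.8) - math.log(0.4))
        assert halving_time(tr) == pytest.approx(expected, abs=1e-9)

    def test_none_when_never_below_half(self):
        tr = _traj([10000, 9000, 8000], [100000] * 3, times=[0.0, 2.0, 4.0])
        assert halving_time(tr) is None


class TestLibrary:
    def test_no_flat_genes_warns_and_skips_normalization(self):
        # the one retained gene decays; its compositional counterpart starts
        # below the count floor and is dropped, so no flat reference exists
        counts = pd.DataFrame(
            [[1000, 500, 250, 125], [15, 600, 1200, 2400]],
            index=["falls", "shallow"],
            columns=[0.0, 2.0, 4.0, 6.0],
        )
        with pytest.warns(UserWarning, match="no-effect"):
            res = fit_library(counts, k0=1.0)
        assert np.allclose(res.norm, 1.0)
        assert res.dropped["gene_id"].tolist() == ["shallow"]

    def test_k0_required(self):
        counts = pd.DataFrame([[100, 90, 80]], index=["g"], columns=[0.0, 2.0, 4.0])
        for bad in (None, 0.0, float("nan")):
            with pytest.raises(ValueError):
                fit_library(counts, k0=bad)

    def test_bh_option_runs_and_is_conservative(self):
        truth = [TrueGene("ess", True, "overabundance", 1.5, 10.0)] + [
            TrueGene(f"flat{i}", False, "no_effect") for i in range(30)
        ]
        counts = simulate_tfnseq(truth, SimConfig(depth=200_000, seed=8))
        plain = fit_library(counts, k0=1.0)
        bh = fit_library(counts, k0=1.0, multiple_testing="bh")
        n_flat_plain = (plain.calls["model"] == "no_effect").sum()
        n_flat_bh = (bh.calls["model"] == "no_effect").sum()
        assert n_flat_bh >= n_flat_plain
        assert bh.calls.loc["ess", "model"] == "overabundance"

    def test_class_fractions_structure(self):
        calls = pd.DataFrame(
            {"model": ["no_effect", "sufficiency", "overabundance", "overabundance"]},
            index=["a", "b", "c", "d"],
        )
        ess = pd.Series([False, True, True, True], index=["a", "b", "c", "d"])
        out = class_fractions(calls, essential=ess)
        assert out["n"] == 4
        assert out["essential_split"]["overabundance"] == pytest.approx(2 / 3)
        assert out["essential_split"]["sufficiency"] == pytest.approx(1 / 3)


class TestReplicateError:
    def _calls(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_identical_replicates_zero_spread(self):
        rep = self._calls([{"gene_id": "g", "model": "overabundance", "log10_o": 1.5}])
        out = replicate_error([rep, rep.copy()])
        assert out.loc["g", "log10_o_sd"] == 0.0
        assert not out.loc["g", "class_discordant"]

    def test_hand_arithmetic(self):
        a = self._calls([{"gene_id": "g", "model": "overabundance", "log10_o": 1.4}])
        b = self._calls([{"gene_id": "g", "model": "overabundance", "log10_o": 1.6}])
        out = replicate_error([a, b])
        assert out.loc["g", "log10_o_mean"] == pytest.approx(1.5)
        assert out.loc["g", "log10_o_sd"] == pytest.approx(math.sqrt(0.02), rel=1e-6)

    def test_missing_and_discordant_flags(self):
        a = self._calls([
            {"gene_id": "g", "model": "overabundance", "log10_o": 1.0},
            {"gene_id": "h", "model": "sufficiency", "log10_o": 0.0},
        ])
        b = self._calls([{"gene_id": "g", "model": "sufficiency", "log10_o": 0.0}])
        out = replicate_error([a, b])
        assert out.loc["g", "class_discordant"]
        assert out.loc["h", "missing_in_replicate"]

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            replicate_error([self._calls([{"gene_id": "g", "model": "no_effect", "log10_o": None}])])

    def test_replicate_spread_magnitude_at_depth(self):
        # two independent deep replicates of a strongly depleted gene give a
        # log10 o spread on the tenths scale, not the decades scale
        truth = [TrueGene("ess", True, "overabundance", 1.5, 10.0)] + [
            TrueGene(f"flat{i}", False, "no_effect") for i in range(50)
        ]
        reps = []
        for seed in (21, 22):
            counts = simulate_tfnseq(truth, SimConfig(depth=1_000_000, seed=seed))
            reps.append(fit_library(counts, k0=1.0).calls)
        out = replicate_error(reps)
        assert out.loc["ess", "model"] == "overabundance"
        assert out.loc["ess", "log10_o_mean"] == pytest.approx(1.5, abs=0.3)
        assert out.loc["ess", "log10_o_sd"] < 0.3


@settings(max_examples=15)
@given(st.integers(0, 2**31 - 1))
def test_likelihood_nesting_property(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(20, 200, size=4)
    totals = counts + rng.integers(100, 1000, size=4)
    fits = fit_models(_traj(counts, totals))
    assert fits.ll_no_effect <= fits.ll_sufficiency + 1e-9
    assert fits.ll_sufficiency <= fits.ll_overabundance + 1e-9
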