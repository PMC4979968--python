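"""Lesion protocol: deafferentation bookkeeping, the GABA ramp, ISI
statistics, determinism and post-lesion physiology."""

import numpy as np
import pytest

from thalcort.experiment import (
    OMISSION_BOUNDS,
    CohortResult,
    RunSummary,
    SimulationConfig,
    apply_lesion,
    gaba_current,
    isi_statistics,
    lesion_sweep,
    model_wavelet_bank,
    run_simulation,
    summarize_run,
)
from thalcort.network import build_network


def _edge_set(topology):
    out = {}
    for proj in topology.projections:
        out[proj.spec.name] = set(zip(proj.src.tolist(), proj.tgt.tolist()))
    return out


class TestApplyLesion:
    def test_thirty_percent_counts(self, topology):
        les = apply_lesion(topology, 0.30)
        mask = les.lesion_mask
        assert mask[:800].sum() == 240
        assert mask[800:].sum() == 60
        # lesioned neurons have no remaining edges in any projection
        for proj in les.projections:
            if proj.spec.source == "E":
                assert not mask[proj.src].any()
            if proj.spec.target == "E":
                assert not mask[proj.tgt].any()
            if proj.spec.target == "CRX":
                assert not mask[proj.tgt].any()

    def test_zero_fraction_identity(self, topology):
        les = apply_lesion(topology, 0.0)
        assert not les.lesion_mask.any()
        assert _edge_set(les) == _edge_set(topology)

    def test_intact_edges_preserved_exactly(self, topology):
        """Set-difference oracle: lesioning removes exactly the edges that
        touch a lesioned neuron and nothing else."""
        les = apply_lesion(topology, 0.30)
        mask = les.lesion_mask
        before, after = _edge_set(topology), _edge_set(les)
        for proj in topology.projections:
            spec = proj.spec

            def hit(pop, idx):
                if pop == "E":
                    return mask[idx]
                if pop == "I":
                    return mask[800 + idx]
                if pop == "CRX":
                    return mask[idx]
                return False

            expected = {
                (s, t)
                for s, t in before[spec.name]
                if not hit(spec.source, s) and not hit(spec.target, t)
            }
            assert after[spec.name] == expected

    def test_block_overflow_rejected(self, topology):
        with pytest.raises(ValueError):
            apply_lesion(topology, 0.30, anchor=700)


class TestGabaCurrent:
    CFG = SimulationConfig(gaba_enabled=True, gaba_amplitude=2.0)

    def test_zero_before_lesion(self):
        assert gaba_current(0.0, self.CFG) == 0.0
        assert gaba_current(9999.0, self.CFG) == 0.0

    def test_linear_ramp_midpoint(self):
        t = self.CFG.lesion_time + self.CFG.gaba_ramp / 2
        assert gaba_current(t, self.CFG) == pytest.approx(-1.0)

    def test_plateau(self):
        t = self.CFG.lesion_time + 10 * self.CFG.gaba_ramp
        assert gaba_current(t, self.CFG) == pytest.approx(-2.0)

    def test_disabled_is_zero(self):
        cfg = SimulationConfig(gaba_enabled=False)
        assert gaba_current(15_000.0, cfg) == 0.0

    def test_amplitude_scales_with_lesion_size(self):
        small = SimulationConfig(lesion_fraction=0.10)
        large = SimulationConfig(lesion_fraction=0.50)
        assert large.gaba_plateau == pytest.approx(5 * small.gaba_plateau)
        from dataclasses import replace

        assert replace(small, lesion_fraction=0.50).gaba_plateau == large.gaba_plateau


class TestIsiStatistics:
    def test_hand_computed(self):
        times = np.array([100.0, 105.0, 400.0])
        ids = np.zeros(3, dtype=int)
        s = isi_statistics((times, ids), (0, 1000))
        assert np.allclose(s.isis[0], [5.0, 295.0])
        assert s.burst_fraction == pytest.approx(0.5)

    def test_empty_train(self):
        s = isi_statistics((np.empty(0), np.empty(0, dtype=int)), (0, 1000))
        assert s.burst_fraction is None
        assert s.isis == {}

    def test_regular_slow_train_not_bursting(self):
        times = np.arange(0, 1000, 100.0)
        ids = np.zeros(times.size, dtype=int)
        s = isi_statistics((times, ids), (0, 1000))
        assert s.burst_fraction == 0.0
        assert s.neuron_class[0] == "tonic"

    def test_window_restriction(self):
        times = np.array([10.0, 20.0, 500.0, 510.0])
        ids = np.zeros(4, dtype=int)
        s = isi_statistics((times, ids), (0, 100))
        assert np.allclose(s.isis[0], [10.0])


class TestRunSimulation:
    def test_determinism(self):
        cfg = SimulationConfig(duration=2500.0, lesion_time=1500.0, seed=5)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        for pop in a.rasters:
            assert np.array_equal(a.rasters[pop][0], b.rasters[pop][0])
            assert np.array_equal(a.rasters[pop][1], b.rasters[pop][1])
            assert np.array_equal(a.lfp[pop], b.lfp[pop])

    def test_lesioned_neurons_silent_after_lesion(self, short_run):
        mask = short_run.lesion_mask
        times, ids = short_run.rasters["CRX"]
        post = times >= short_run.config.lesion_time
        assert not mask[ids[post]].any()

    def test_lfp_lengths(self, short_run):
        for pop in ("SP", "NSP", "TRN", "CRX"):
            assert short_run.lfp[pop].size == short_run.config.n_steps

    def test_deafferented_zone_disfacilitation(self):
        """Deafferentation hyperpolarizes the thalamic cells mapped to the
        lesioned cortical block: the deafferented reticular zone drops below
        its own pre-lesion baseline, and the deafferented relay (NSP) zone
        ends up hyperpolarized relative to the intact relay zone (the two
        zones are statistically identical before the lesion)."""
        cfg = SimulationConfig(duration=8000.0, lesion_time=4000.0, seed=2,
                               gaba_enabled=False, record_thalamic_v=True,
                               record_rasters=False)
        res = run_simulation(cfg)
        V = res.provenance["thalamic_v"]
        # thalamic rows: SP 0-99, NSP 100-199, TRN 200-299; the lesioned 30%
        # of cortex maps topographically onto cells 0-29 of each nucleus
        trn0 = V[:, 200:230].mean(axis=1)
        assert trn0[5000:].mean() < trn0[1000:4000].mean() - 2.0
        nsp0 = V[:, 100:130].mean(axis=1)
        nsp1 = V[:, 130:200].mean(axis=1)
        assert abs(nsp0[1000:4000].mean() - nsp1[1000:4000].mean()) < 2.0
        assert nsp0[5000:].mean() < nsp1[5000:].mean() - 2.0

    def test_no_lesion_run_keeps_spectrum(self):
        cfg = SimulationConfig(duration=10_000.0, lesion_time=5000.0, seed=3,
                               lesion_fraction=0.0, record_rasters=False)
        res = run_simulation(cfg)
        assert not res.lesion_mask.any()
        bank = model_wavelet_bank()
        s = summarize_run(res, bank)
        assert s.pre_peak == pytest.approx(s.post_peak, abs=0.75)


class TestCohortRules:
    def _summary(self, seed, pre_peak):
        return RunSummary(seed=seed, pre_peak=pre_peak, post_peak=9.0,
                          retained=OMISSION_BOUNDS[0] <= pre_peak <= OMISSION_BOUNDS[1],
                          spectra={}, burst_fractions={}, nsp_post_peak=7.0,
                          mean_nsp_v={})

    def test_omission_rule_bounds(self):
        runs = [self._summary(0, 9.9), self._summary(1, 12.5), self._summary(2, 8.0)]
        cohort = CohortResult(runs=runs, config=SimulationConfig(), bank=None)
        assert [r.seed for r in cohort.retained] == [0]
        assert cohort.omitted_seeds() == [1, 2]

    def test_mean_peaks_over_retained_only(self):
        runs = [self._summary(0, 9.0), self._summary(1, 10.0), self._summary(2, 13.0)]
        cohort = CohortResult(runs=runs, config=SimulationConfig(), bank=None)
        pre, post = cohort.mean_peaks()
        assert pre == pytest.approx(9.5)
        assert post == pytest.approx(9.0)


def test_lesion_sweep_structure():
    table = lesion_sweep(
        sizes=[0.0, 0.3],
        reps=1,
        config=SimulationConfig(duration=10_000.0, lesion_time=5000.0),
    )
    assert list(table.lesion_fraction) == [0.0, 0.3]
    assert {"mean_post_peak", "sem_post_peak", "n"} <= set(table.columns)
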