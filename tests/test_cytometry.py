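"""Competitive-binding simulation: occupancy closed forms, gating,
quadrants, KD fitting, and the population-level blocking behaviours."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epibinseq as eb
from epibinseq.clones import CloneSpec, RAbSpec, PER_EPITOPE, TRA_EPITOPE
from epibinseq.cytometry import background_threshold

BLOCKER = CloneSpec("blk", "pertuzumab", PER_EPITOPE, 1.0, "ATG", "M", 1.0)
NONBLOCKER = CloneSpec("non", "none", None, None, "ATG", "M", 1.0)


def rab(conc, kd=1.0, epitope=PER_EPITOPE, channel="AF647", rid="r1"):
    return RAbSpec(rid, epitope, conc, kd, channel)


class TestOccupancyFraction:
    def test_zero_ligand_gives_zero_occupancy(self):
        occ = eb.rab_occupancy_fraction(NONBLOCKER, [rab(0.0)], 1e5, 1e-4)
        assert occ["r1"] == 0.0

    def test_half_saturation_at_kd_for_non_blocking_clone(self):
        occ = eb.rab_occupancy_fraction(NONBLOCKER, [rab(1.0, kd=1.0)], 1e5, 1e-4)
        assert occ["r1"] == pytest.approx(0.5)

    def test_symmetric_competition_gives_one_third(self):
        # x_r = 1 and C_q/K_q = 1 -> p = 1/(1+1+1)
        occ = eb.rab_occupancy_fraction(BLOCKER, [rab(1.0, kd=1.0)], 1e4, 1e-4)
        assert occ["r1"] == pytest.approx(1.0 / 3.0)

    def test_full_blockade_limit(self):
        occ = eb.rab_occupancy_fraction(BLOCKER, [rab(1.0, kd=1.0)], 1e9, 1.0)
        assert occ["r1"] <= 1e-8

    def test_non_binder_never_blocks(self):
        with_q = eb.rab_occupancy_fraction(NONBLOCKER, [rab(1.0)], 1e9, 1.0)
        without_q = eb.rab_occupancy_fraction(NONBLOCKER, [rab(1.0)], 0.0, 1.0)
        assert with_q == without_q

    def test_shared_epitope_rabs_compete(self):
        rabs = [rab(1.0, rid="a"), rab(1.0, rid="b")]
        occ = eb.rab_occupancy_fraction(NONBLOCKER, rabs, 0.0, 1e-4)
        assert occ["a"] == pytest.approx(1.0 / 3.0)
        assert occ["b"] == pytest.approx(1.0 / 3.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            eb.rab_occupancy_fraction(BLOCKER, [rab(1.0)], -1.0, 1e-4)
        with pytest.raises(ValueError):
            RAbSpec("r", PER_EPITOPE, -1.0, 1.0, "AF647")

    @given(
        c1=st.floats(0.01, 100.0),
        c2=st.floats(0.01, 100.0),
        q=st.floats(0.0, 1e6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_occupancy_monotone_in_concentration_and_blockade(self, c1, c2, q):
        lo, hi = sorted((c1, c2))
        p_lo = eb.rab_occupancy_fraction(BLOCKER, [rab(lo)], q, 1e-4)["r1"]
        p_hi = eb.rab_occupancy_fraction(BLOCKER, [rab(hi)], q, 1e-4)["r1"]
        assert p_hi >= p_lo  # increasing in rAb concentration
        p_more_q = eb.rab_occupancy_fraction(BLOCKER, [rab(lo)], q + 1e5, 1e-4)["r1"]
        assert p_more_q <= p_lo  # decreasing in qAb copies when blocking
        p_non = eb.rab_occupancy_fraction(NONBLOCKER, [rab(lo)], q, 1e-4)["r1"]
        p_non2 = eb.rab_occupancy_fraction(NONBLOCKER, [rab(lo)], q + 1e5, 1e-4)["r1"]
        assert p_non == p_non2  # invariant in qAb copies when not blocking


class TestSimulateCellEvents:
    def test_zero_cells_gives_empty_table(self):
        cfg = eb.SimConfig(n_cells=0)
        events = eb.simulate_cell_events(cfg, [NONBLOCKER], [rab(1.0)])
        assert len(events) == 0
        assert "AF647" in events.columns

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            eb.simulate_cell_events(eb.SimConfig(n_cells=10), [], [])

    def test_reproducible_under_fixed_seed(self, library, rabs):
        cfg = eb.SimConfig(n_cells=2000, seed=7)
        a = eb.simulate_cell_events(cfg, library, [rabs["Pert-AF647"]])
        b = eb.simulate_cell_events(cfg, library, [rabs["Pert-AF647"]])
        assert a.equals(b)

    def test_fluorescence_non_negative(self, library, rabs):
        cfg = eb.SimConfig(n_cells=5000, seed=1)
        events = eb.simulate_cell_events(cfg, library, list(rabs.values()))
        for ch in ("AF647", "AF488"):
            assert (events[ch] >= 0).all()

    def test_noise_free_fluorescence_matches_occupancy_exactly(self):
        # non-binder at c = kd -> p = 1/2 for every cell, so F = gain*A/2
        cfg = eb.SimConfig(
            n_cells=500, noise_sd=0.0, antigen_low_fraction=0.0, seed=3, gain=0.5
        )
        events = eb.simulate_cell_events(cfg, [NONBLOCKER], [rab(1.0, kd=1.0)])
        np.testing.assert_allclose(events["AF647"], 0.5 * 0.5 * events["A"])

    def test_mean_fluorescence_matches_lognormal_closed_form(self):
        # E[A] for log10(A) ~ N(mu, s^2) is 10^mu * exp((s ln10)^2 / 2)
        cfg = eb.SimConfig(
            n_cells=10_000, noise_sd=0.0, antigen_low_fraction=0.0, seed=11, gain=1.0
        )
        events = eb.simulate_cell_events(cfg, [NONBLOCKER], [rab(1.0, kd=1.0)])
        s = cfg.log10_antigen_sd * math.log(10.0)
        expected = 10 ** cfg.log10_antigen_median * math.exp(s * s / 2.0) * 0.5
        sem = events["AF647"].std() / math.sqrt(len(events))
        assert abs(events["AF647"].mean() - expected) < 3 * sem


class TestGateAndSort:
    def _events(self, values):
        import pandas as pd

        return pd.DataFrame(
            {"clone_id": [f"c{i}" for i in range(len(values))],
             "A": 1.0, "Q": 1.0, "AF647": values}
        )

    def test_infinite_threshold_sorts_everything(self):
        gate = eb.gate_and_sort(self._events([1.0, 2.0, 3.0]), "AF647", math.inf)
        assert gate.percent_negative == 100.0
        assert gate.n_sorted == 3

    def test_zero_threshold_sorts_nothing(self):
        gate = eb.gate_and_sort(self._events([1.0, 2.0, 3.0]), "AF647", 0.0)
        assert gate.percent_negative == 0.0
        assert gate.n_sorted == 0

    def test_hand_counted_gate(self):
        gate = eb.gate_and_sort(self._events([1.0, 2.0, 10.0, 20.0]), "AF647", 5.0)
        assert gate.percent_negative == 50.0
        assert gate.sorted_counts == {"c0": 1, "c1": 1}

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            eb.gate_and_sort(self._events([1.0]), "PE", 1.0)

    def test_auto_threshold_is_background_quantile(self):
        cfg = eb.SimConfig(n_cells=50_000, seed=5)
        thresh = background_threshold(cfg, "AF647")
        # the background carries no antigen signal: its quantile is the
        # q_gate point of the clipped noise distribution
        rng_free = 2.576 * cfg.noise_sd  # 99.5th pct of N(0, sd)
        assert thresh == pytest.approx(rng_free, rel=0.05)


class TestQuadrants:
    def _two_channel(self, xy):
        import pandas as pd

        return pd.DataFrame(
            {"clone_id": "c", "A": 1.0, "Q": 1.0,
             "AF647": [p[0] for p in xy], "AF488": [p[1] for p in xy]}
        )

    def test_single_quadrant_degenerate(self):
        ev = self._two_channel([(0.0, 10.0)] * 5)
        q = eb.quadrant_percentages(ev, "AF647", "AF488", 1.0, 1.0)
        assert q["-/+"] == 100.0
        assert q["-/-"] == q["+/-"] == q["+/+"] == 0.0

    def test_one_event_per_quadrant(self):
        ev = self._two_channel([(0, 0), (0, 9), (9, 0), (9, 9)])
        q = eb.quadrant_percentages(ev, "AF647", "AF488", 1.0, 1.0)
        assert all(v == 25.0 for v in q.values())

    def test_empty_events_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            eb.quadrant_percentages(
                pd.DataFrame(columns=["clone_id", "A", "Q", "AF647", "AF488"]),
                "AF647", "AF488", 1.0, 1.0,
            )

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_quadrant_percentages_sum_to_100(self, xy):
        q = eb.quadrant_percentages(self._two_channel(xy), "AF647", "AF488", 50.0, 50.0)
        assert sum(q.values()) == pytest.approx(100.0, abs=1e-9)


# Methods-printed saturation titration ladder (nM)
KD_LADDER = [0.5, 1, 5, 10, 25, 50, 100, 200, 400, 800, 1600]


class TestFitKd:
    def test_exact_model_recovery(self):
        c = np.array(KD_LADDER, dtype=float)
        y = 100.0 + 5000.0 * c / (10.0 + c)
        fit = eb.fit_kd(c, y)
        assert fit.converged
        assert fit.kd == pytest.approx(10.0, rel=1e-6)
        assert fit.fmax == pytest.approx(5000.0, rel=1e-6)
        assert fit.baseline == pytest.approx(100.0, rel=1e-4)

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(42)
        c = np.array(KD_LADDER, dtype=float)
        y = (50.0 + 3000.0 * c / (50.0 + c)) * (1.0 + 0.05 * rng.standard_normal(len(c)))
        fit = eb.fit_kd(c, y)
        assert fit.converged
        assert abs(fit.kd - 50.0) / 50.0 < 0.20

    def test_flat_response_flags_non_binder(self):
        c = np.array(KD_LADDER, dtype=float)
        fit = eb.fit_kd(c, np.full(len(c), 123.0))
        assert not fit.converged

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            eb.fit_kd([1.0, 2.0, 4.0, 8.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            eb.fit_kd([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])


class TestPopulationBlockingBehaviour:
    """Population-level behaviours of the competitive staining model."""

    def test_percent_negative_monotone_in_rab_concentration(self, library_by_id, rabs):
        cfg = eb.SimConfig(n_cells=50_000)
        pert = rabs["Pert-AF647"]
        pcts = [
            eb.percent_rab_negative(cfg, library_by_id["Per"], pert.at(c), seed=2)
            for c in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))
        # 100 nM strongly reduces the non-binding population vs 0.1 nM
        assert pcts[-1] < pcts[0] / 3

    def test_higher_antigen_expression_reduces_percent_negative(self, library_by_id, rabs):
        lo = eb.SimConfig(n_cells=50_000, log10_antigen_median=4.5)
        hi = eb.SimConfig(n_cells=50_000, log10_antigen_median=5.5)
        pert = rabs["Pert-AF647"].at(0.1)
        p_lo = eb.percent_rab_negative(lo, library_by_id["Per"], pert, seed=3)
        p_hi = eb.percent_rab_negative(hi, library_by_id["Per"], pert, seed=3)
        assert p_hi < p_lo

    def test_sorted_population_has_higher_qab_and_lower_antigen(self, library_by_id, rabs):
        from dataclasses import replace as _replace

        cfg = eb.SimConfig(n_cells=50_000, seed=9)
        per = _replace(library_by_id["Per"], library_frequency=1.0)
        pert = rabs["Pert-AF647"].at(0.1)
        events = eb.simulate_cell_events(cfg, [per], [pert])
        gate = eb.gate_and_sort(events, "AF647", "auto", cfg, seed=10)
        neg = events["AF647"] < gate.threshold
        assert events.loc[neg, "Q"].mean() > events.loc[~neg, "Q"].mean()
        assert events.loc[neg, "A"].mean() < events.loc[~neg, "A"].mean()

    def test_non_binder_indistinguishable_from_antigen_only_control(
        self, library_by_id, rabs
    ):
        # Dac/Niv display an irrelevant scFv: their rAb staining must match
        # a displayed-but-non-blocking population at every concentration
        cfg = eb.SimConfig(n_cells=50_000)
        tra_as_control = library_by_id["Tra"]  # does not block the pert epitope
        pert = rabs["Pert-AF647"]
        for conc in (0.1, 1.0, 10.0, 100.0):
            p_dac = eb.percent_rab_negative(cfg, library_by_id["Dac"], pert.at(conc), seed=4)
            p_ctl = eb.percent_rab_negative(cfg, tra_as_control, pert.at(conc), seed=5)
            n = cfg.n_cells
            pooled = (p_dac + p_ctl) / 200.0
            se = math.sqrt(max(pooled * (1 - pooled) * 2 / n, 1e-12)) * 100
            assert abs(p_dac - p_ctl) < 4 * se + 0.05

    def test_dual_rab_quadrant_pattern(self, library_by_id, rabs):
        from dataclasses import replace as _replace

        cfg = eb.SimConfig(n_cells=50_000, seed=21)
        pert = rabs["Pert-AF647"].at(0.1)
        tras488 = rabs["Tras-AF488"].at(0.1)
        thresholds = {
            ch: background_threshold(cfg, ch, seed=22) for ch in ("AF647", "AF488")
        }

        per = _replace(library_by_id["Per"], library_frequency=1.0)
        ev = eb.simulate_cell_events(cfg, [per], [pert, tras488])
        q = eb.quadrant_percentages(
            ev, "AF647", "AF488", thresholds["AF647"], thresholds["AF488"]
        )
        # the pert-epitope blocker is depleted of pert staining only:
        # (pert-, tras+) dominates every other quadrant
        assert q["-/+"] == max(q.values())
        assert q["-/+"] > 40.0

        dac = _replace(library_by_id["Dac"], library_frequency=1.0)
        ev = eb.simulate_cell_events(cfg, [dac], [pert, tras488], seed=23)
        q = eb.quadrant_percentages(
            ev, "AF647", "AF488", thresholds["AF647"], thresholds["AF488"]
        )
        # non-blocking clone: doubly stained, no single-negative asymmetry
        assert q["+/+"] == max(q.values())
        assert abs(q["-/+"] - q["+/-"]) < 5.0
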