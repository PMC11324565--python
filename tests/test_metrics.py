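"""Dechlorination metrics: averages, rates, positional accounting, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcbdechlor.congeners import get_table
from pcbdechlor.metrics import (
    CongenerProfile,
    DechlorTimeCourse,
    average_chlorine,
    dechlorination_rate,
    fold_change,
    homolog_distribution,
    positional_removal,
    read_timecourses,
    total_molar_concentration,
    write_timecourses,
)


def profile(entries, system="s", t=0.0):
    return CongenerProfile.from_mapping(system, t, entries)


def timecourse(profiles, conc=25.0):
    return DechlorTimeCourse(system=profiles[0].system, profiles=tuple(profiles),
                             mass_conc_mg_l=conc)


class TestAverageChlorine:
    def test_pure_deca(self):
        assert average_chlorine(profile({209: 100.0})) == pytest.approx(10.0)

    def test_linearity_across_homologs(self):
        p = profile({47: 50.0, 153: 50.0})
        assert average_chlorine(p) == pytest.approx(5.0)

    def test_weighted_example(self):
        p = profile({47: 20.0, 153: 80.0})
        assert average_chlorine(p) == pytest.approx(0.2 * 4 + 0.8 * 6)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            profile({})

    @given(
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        bzs=st.lists(st.integers(1, 209), min_size=8, max_size=8, unique=True),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_refinement_within_homolog_preserves_average(self, weights, bzs):
        """Splitting mass among congeners of equal n_cl leaves the average fixed."""
        table = get_table()
        congeners = [table.by_bz(bz) for bz in bzs[: len(weights)]]
        total = sum(weights)
        p = profile({c: 100.0 * w / total for c, w in zip(congeners, weights)})
        # refine: move each congener's share onto the first congener of its homolog
        by_homolog = {}
        for c, w in zip(congeners, weights):
            rep = table.homolog(c.n_cl)[0]
            by_homolog[rep] = by_homolog.get(rep, 0.0) + 100.0 * w / total
        q = profile(by_homolog)
        assert average_chlorine(q) == pytest.approx(average_chlorine(p), abs=1e-9)


class TestHomologDistribution:
    def test_pure_hepta(self):
        d = homolog_distribution(profile({180: 100.0}))
        assert d[7] == pytest.approx(100.0)
        assert d.sum() == pytest.approx(100.0)

    def test_mixture_bins(self):
        d = homolog_distribution(profile({47: 30.0, 153: 70.0}))
        assert d[4] == pytest.approx(30.0)
        assert d[6] == pytest.approx(70.0)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bins_conserve_total(self, weights):
        table = get_table()
        congeners = table.homolog(6)[: len(weights)]
        total = sum(weights[: len(congeners)])
        p = profile({c: 100.0 * w / total
                     for c, w in zip(congeners, weights)})
        assert homolog_distribution(p).sum() == pytest.approx(100.0, abs=1e-9)


class TestNormalization:
    def test_small_drift_renormalized(self):
        p = profile({153: 99.7})
        assert p.mole_percent(153) == pytest.approx(100.0)

    def test_large_drift_rejected(self):
        with pytest.raises(ValueError):
            profile({153: 98.0})

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            profile({153: 101.0, 47: -1.0})


class TestMolarConcentration:
    def test_pure_hexa(self):
        tc = timecourse([profile({153: 100.0})])
        # 25 mg/L / 360.9 g/mol -> ~69.3 uM
        assert total_molar_concentration(tc) == pytest.approx(69.3, abs=0.1)

    def test_aroclor_like_mean_mw(self):
        from pcbdechlor.simulate import pseudo_aroclor

        p = pseudo_aroclor(6.34, seed=0)
        tc = DechlorTimeCourse(system=p.system, profiles=(p,), mass_conc_mg_l=25.0)
        # average 6.34 Cl -> mean MW ~372.6 -> ~67.1 uM
        assert total_molar_concentration(tc) == pytest.approx(67.1, abs=0.1)

    def test_linearity_in_mass(self):
        p = profile({153: 100.0})
        c1 = total_molar_concentration(timecourse([p], conc=25.0))
        c2 = total_molar_concentration(timecourse([p], conc=50.0))
        assert c2 == pytest.approx(2 * c1)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            timecourse([profile({153: 100.0})], conc=0.0)


class TestDechlorinationRate:
    def test_identical_profiles_zero_rate(self):
        tc = timecourse([profile({153: 100.0}, t=0.0),
                         profile({153: 100.0}, t=15.0)])
        assert dechlorination_rate(tc, 0, 15).rate_um_cl_per_d == pytest.approx(0.0)

    def test_worked_delta_example(self):
        """A 0.35-chlorine drop over 15 d at ~67.1 uM is ~1.57 uM Cl-/d."""
        from pcbdechlor.simulate import pseudo_aroclor

        p0 = pseudo_aroclor(6.34, seed=0)
        p1 = pseudo_aroclor(5.99, seed=0)
        p1 = CongenerProfile(system=p0.system, time_d=15.0, entries=p1.entries)
        tc = timecourse([p0, p1])
        r = dechlorination_rate(tc, 0, 15)
        conc = total_molar_concentration(tc, at=0)
        assert r.rate_um_cl_per_d == pytest.approx(0.35 * conc / 15, rel=1e-9)
        assert r.rate_um_cl_per_d == pytest.approx(1.566, abs=0.01)

    def test_bad_window_rejected(self):
        tc = timecourse([profile({153: 100.0}, t=0.0)])
        with pytest.raises(ValueError):
            dechlorination_rate(tc, 5, 5)
        with pytest.raises(KeyError):
            dechlorination_rate(tc, 0, 30)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(1.98, 0.62, 3.19), (1.05, 0.62, 1.69), (2.3, 1.9, 1.21)],
    )
    def test_printed_rate_ratios(self, a, b, expected):
        assert round(fold_change(a, b), 2) == expected

    def test_identity(self):
        assert fold_change(0.7, 0.7) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestPositionalRemoval:
    def test_no_change_zero_removal(self):
        tc = timecourse([profile({153: 100.0}, t=0.0),
                         profile({153: 100.0}, t=10.0)])
        pr = positional_removal(tc, 0, 10)
        assert pr.removal_fraction == {"ortho": pytest.approx(0.0),
                                       "meta": pytest.approx(0.0),
                                       "para": pytest.approx(0.0)}

    def test_full_meta_stripping_153_to_47(self):
        """PCB153 -> PCB47 removes both meta chlorines and nothing else."""
        tc = timecourse([profile({153: 100.0}, t=0.0),
                         profile({47: 100.0}, t=10.0)])
        pr = positional_removal(tc, 0, 10)
        assert pr.removal_fraction["meta"] == pytest.approx(1.0)
        assert pr.removal_fraction["ortho"] == pytest.approx(0.0)
        assert pr.removal_fraction["para"] == pytest.approx(0.0)

    def test_absent_class_flagged(self):
        tc = timecourse([profile({47: 100.0}, t=0.0),
                         profile({47: 100.0}, t=10.0)])
        pr = positional_removal(tc, 0, 10)
        assert pr.removal_fraction["meta"] is None

    def test_printed_meta_removal_ratio(self):
        assert round(0.627 / 0.524, 1) == 1.2

    def test_closure_delta_avg_equals_sum_of_positional_deltas(self):
        tc = timecourse([profile({180: 60.0, 153: 40.0}, t=0.0),
                         profile({153: 30.0, 99: 30.0, 47: 40.0}, t=20.0)])
        pr = positional_removal(tc, 0, 20)
        d_avg = average_chlorine(tc.at(0)) - average_chlorine(tc.at(20))
        d_pos = sum(pr.per_biphenyl_t0[c] - pr.per_biphenyl_t[c]
                    for c in ("ortho", "meta", "para"))
        assert d_avg == pytest.approx(d_pos, abs=1e-12)


class TestTimecourseIO:
    def test_round_trip(self, tmp_path):
        tc = timecourse([profile({153: 60.0, 180: 40.0}, system="M-HM", t=0.0),
                         profile({153: 50.0, 180: 30.0, 99: 20.0}, system="M-HM", t=15.0)])
        path = tmp_path / "tc.csv"
        write_timecourses({"M-HM": tc}, path)
        back = read_timecourses(path)
        assert set(back) == {"M-HM"}
        assert back["M-HM"].times == (0.0, 15.0)
        assert average_chlorine(back["M-HM"].at(15.0)) == pytest.approx(
            average_chlorine(tc.at(15.0)))

    def test_congener_column_accepts_structures(self, tmp_path):
        df = pd.DataFrame(
            {"system": ["a"] * 2, "time_d": [0.0] * 2,
             "congener": ["2,2',4,4',5,5'", "PCB180"], "mole_percent": [55.0, 45.0]}
        )
        path = tmp_path / "tc.csv"
        df.to_csv(path, index=False)
        tc = read_timecourses(path)["a"]
        assert tc.at(0.0).mole_percent(153) == pytest.approx(55.0)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"system": [], "time_d": []}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_timecourses(path)

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            DechlorTimeCourse(system="s", profiles=(
                profile({153: 100.0}, t=5.0), profile({153: 100.0}, t=5.0)))
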