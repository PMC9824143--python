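import numpy as np
import pytest

from bilayerlab.curves import Curve
from bilayerlab.dsc import (
    PeakRegion,
    Thermogram,
    analyze_thermogram,
    build_phase_diagram,
    detect_immiscibility,
    detect_transitions,
    enthalpy,
    onset_completion,
    subtract_baseline,
)
from bilayerlab.synth import ThermogramTruth, generate_thermogram

MAIN = (23.1, 0.4, 27.2)   # pure-lipid main transition: onset 22.3 °C
PRE = (10.0, 0.5, 2.0)     # weakly energetic pretransition


def make_thermo(peaks, baseline=(0.0, 0.0), noise_sd=0.0, seed=0,
                composition=0.0):
    truth = ThermogramTruth(peaks=list(peaks), baseline=baseline,
                            noise_sd=noise_sd)
    return Thermogram(generate_thermogram(truth, seed),
                      composition=composition)


class TestSubtractBaseline:
    def test_sloped_baseline_removed_exactly(self):
        thermo = make_thermo([MAIN], baseline=(1.0, 0.1))
        corr = subtract_baseline(thermo, (3, 7), (30, 34))
        T = corr.curve.x
        for lo, hi in [(3, 7), (30, 34)]:
            m = (T >= lo) & (T <= hi)
            assert np.mean(np.abs(corr.curve.y[m])) < 1e-6

    def test_idempotent(self):
        thermo = make_thermo([MAIN], baseline=(1.0, 0.1), noise_sd=0.01)
        once = subtract_baseline(thermo, (3, 7), (30, 34))
        twice = subtract_baseline(once, (3, 7), (30, 34))
        assert np.max(np.abs(twice.curve.y - once.curve.y)) < 1e-9

    def test_window_beyond_data_rejected(self):
        thermo = make_thermo([MAIN])
        with pytest.raises(ValueError, match="outside"):
            subtract_baseline(thermo, (3, 7), (36, 40))

    def test_window_overlapping_peak_rejected(self):
        thermo = make_thermo([MAIN])
        with pytest.raises(ValueError, match="peak"):
            subtract_baseline(thermo, (3, 7), (22, 25))


class TestDetectTransitions:
    def test_two_separated_peaks_in_order(self):
        regions = detect_transitions(make_thermo([PRE, MAIN]), 0.5)
        assert len(regions) == 2
        assert regions[0].i_lo < regions[1].i_lo
        assert not regions[0].overlapping

    def test_flat_signal_gives_no_regions(self):
        T = np.arange(2.0, 35.0, 0.01)
        thermo = Thermogram(Curve(T, np.zeros_like(T)))
        assert detect_transitions(thermo, 0.5) == []

    def test_close_peaks_merge_into_flagged_region(self):
        # 3σ apart: two resolvable maxima whose tail regions overlap
        regions = detect_transitions(
            make_thermo([(22.5, 0.4, 10.0), (23.7, 0.4, 10.0)]), 0.5)
        assert len(regions) == 1
        assert regions[0].overlapping
        assert len(regions[0].peak_indices) == 2


class TestOnsetCompletion:
    def test_tangent_onset_of_planted_gaussian(self):
        """Gaussian (23.1, σ 0.4) → onset c − 2σ = 22.3, completion 23.9."""
        thermo = make_thermo([MAIN])
        region = detect_transitions(thermo, 0.5)[0]
        onset, completion = onset_completion(thermo, region)
        assert onset == pytest.approx(22.3, abs=0.05)
        assert completion == pytest.approx(23.9, abs=0.05)

    def test_symmetric_peak_has_symmetric_construction(self):
        thermo = make_thermo([MAIN])
        region = detect_transitions(thermo, 0.5)[0]
        onset, completion = onset_completion(thermo, region)
        T_peak = 23.1
        assert (T_peak - onset) == pytest.approx(completion - T_peak,
                                                 abs=0.02)

    @pytest.mark.parametrize("sd", [0.2, 0.5, 1.0, 2.0])
    def test_onset_is_center_minus_two_sd_across_widths(self, sd):
        truth = ThermogramTruth(peaks=[(20.0, sd, 10.0)],
                                T_grid=np.arange(0.0, 40.0001, 0.01))
        thermo = Thermogram(generate_thermogram(truth, 0))
        region = detect_transitions(thermo, 0.1)[0]
        onset, completion = onset_completion(thermo, region)
        assert onset == pytest.approx(20.0 - 2 * sd, abs=0.05)
        assert completion == pytest.approx(20.0 + 2 * sd, abs=0.05)

    def test_monotone_region_rejected(self):
        T = np.arange(0, 10, 0.01)
        thermo = Thermogram(Curve(T, T.copy()))
        with pytest.raises(ValueError, match="maximum"):
            onset_completion(thermo, PeakRegion(0, T.size - 1, []))


class TestEnthalpy:
    def test_planted_area_recovered(self):
        thermo = make_thermo([MAIN])
        region = detect_transitions(thermo, 0.5)[0]
        assert enthalpy(thermo, region) == pytest.approx(27.2, abs=0.05)

    def test_two_peaks_add(self):
        thermo = make_thermo([(10.0, 0.5, 5.0), MAIN])
        regions = detect_transitions(thermo, 0.5)
        total = sum(enthalpy(thermo, r) for r in regions)
        assert total == pytest.approx(5.0 + 27.2, abs=0.05)

    def test_zero_signal_integrates_to_zero(self):
        T = np.arange(0, 10, 0.01)
        thermo = Thermogram(Curve(T, np.zeros_like(T)))
        assert enthalpy(thermo, PeakRegion(0, T.size - 1, [])) == 0.0

    def test_region_outside_data_rejected(self):
        thermo = make_thermo([MAIN])
        with pytest.raises(ValueError):
            enthalpy(thermo, PeakRegion(0, 10**6, []))


class TestAnalyzeThermogram:
    def test_labels_pretransition_and_main(self):
        events = analyze_thermogram(make_thermo([PRE, MAIN]),
                                    min_prominence=0.5)
        assert [e.label for e in events] == ["pretransition", "main"]
        assert events[1].delta_H == pytest.approx(27.2, abs=0.05)
        assert events[1].T_onset == pytest.approx(22.3, abs=0.05)


class TestPhaseDiagram:
    def test_single_composition_point(self):
        pd = build_phase_diagram([(0.0, 22.3, 23.9)], T_tolerance=None)
        assert pd.points == [(0.0, 22.3, 23.9)]

    def test_sorted_by_mole_fraction(self):
        pd = build_phase_diagram(
            [(0.2, 20.0, 23.9), (0.0, 22.3, 23.9), (0.1, 21.0, 23.9)])
        assert [p[0] for p in pd.points] == [0.0, 0.1, 0.2]

    def test_onset_above_completion_rejected(self):
        with pytest.raises(ValueError):
            build_phase_diagram([(0.0, 24.0, 23.0)])

    def test_coexistence_width_grows_then_plateaus(self):
        xs = [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3]
        onsets = [22.3, 21.5, 20.7, 20.0, 19.4, 19.4, 19.4]
        pd = build_phase_diagram(
            [(x, on, 23.9) for x, on in zip(xs, onsets)])
        w = pd.coexistence_width
        assert np.all(np.diff(w[:5]) > 0)
        assert np.allclose(w[4:], w[4])

    def test_fluidus_never_below_solidus(self):
        pd = build_phase_diagram(
            [(x, 22.3 - 10 * x, 23.9) for x in (0, 0.1, 0.2, 0.3)])
        assert np.all(pd.coexistence_width >= 0)


class TestImmiscibility:
    def test_constant_fluidus_flagged_across_all_compositions(self):
        xs = [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3]
        segs = detect_immiscibility([(x, 23.9) for x in xs], 0.3)
        assert len(segs) == 1
        assert segs[0]["flag"] == "immiscible"
        assert segs[0]["x_range"] == (0.0, 0.3)

    def test_strictly_decreasing_solidus_not_flagged(self):
        segs = detect_immiscibility(
            [(x, 22.3 - 10 * x) for x in (0, 0.1, 0.2, 0.3)], 0.3)
        assert all(s["flag"] == "mixing" for s in segs)

    def test_solidus_constant_only_above_threshold_composition(self):
        """Mixing at low content, gel immiscibility from x = 0.2 on."""
        xs = [0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3]
        ts = [22.3, 21.3, 20.3, 19.3, 18.4, 18.4, 18.4]
        segs = detect_immiscibility(list(zip(xs, ts)), 0.3)
        imm = [s for s in segs if s["flag"] == "immiscible"]
        assert len(imm) == 1
        assert imm[0]["x_range"][0] == pytest.approx(0.2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            detect_immiscibility([(0.0, 23.9), (0.1, 23.9)], 0.3)
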