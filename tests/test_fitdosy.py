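import math

import numpy as np
import pytest

from dosykit import fitdosy, process, seqmodel, simulate
from dosykit.fitdosy import (
    DosyPeakList,
    PeakEntry,
    Pick,
    build_peak_list,
    extract_decay,
    fit_stejskal_tanner,
    pick_peaks,
    synthesize_dosy_matrix,
)
from dosykit.simulate import Multiplet, Phantom, Species, simulate_dataset

from conftest import species_line_table
from test_simulate import tiny_water


@pytest.fixture(scope="module")
def trad_b(trad_params):
    ramp = seqmodel.gradient_ramp(trad_params)
    return seqmodel.b_value(trad_params, ramp.amplitudes), ramp.fractions


class TestPickPeaks:
    def test_noiseless_doublet_two_picks(self, grid_fine, trad_params):
        sp = Species("d", (Multiplet(2.5, 8.0, 2),), D=5.0, T2=1.0, linewidth=1.5, amplitude=1.0)
        ph = Phantom("p", [sp], water=tiny_water(), noise_sigma=0.0)
        ds = simulate_dataset(ph, trad_params, grid_fine, seed=0)
        m = process.apodize_and_transform(ds, gw=1.0, target_points=4 * grid_fine.points)
        picks = pick_peaks(m)
        assert len(picks) == 2
        expected = [2.5 - 4.0 / 600.13, 2.5 + 4.0 / 600.13]
        got = sorted(p.ppm for p in picks)
        dppm = abs(m.ppm_axis[1] - m.ppm_axis[0])
        for g, e in zip(got, expected):
            assert abs(g - e) <= 1.5 * dppm

    def test_threshold_above_signal_empty(self, urine_matrix):
        tall = float(np.max(urine_matrix.rows[0].real))
        picks = pick_peaks(urine_matrix, threshold_multiple=2 * tall / urine_matrix.noise_sd)
        assert picks == []

    def test_urine_phantom_picks_most_lines(self, urine_matrix, urine_phantom):
        picks = pick_peaks(urine_matrix)
        lines = [ppm for ppm, _name in species_line_table(urine_phantom)]
        found = sum(
            1 for ppm in lines if any(abs(p.ppm - ppm) <= 0.005 for p in picks)
        )
        assert found / len(lines) >= 0.90


class TestExtractDecay:
    def test_noiseless_species_matches_decay_curve(self, grid_fine, trad_params):
        sp = Species("s", (Multiplet(2.0, 0.0, 1),), D=6.0, T2=0.7, linewidth=1.5, amplitude=1.0)
        ph = Phantom("p", [sp], water=tiny_water(), noise_sigma=0.0)
        ds = simulate_dataset(ph, trad_params, grid_fine, seed=0)
        m = process.apodize_and_transform(ds, gw=1.0, target_points=2 * grid_fine.points)
        pick = pick_peaks(m)[0]
        intens, flags = extract_decay(m, pick)
        assert flags == []
        expected = seqmodel.decay_curve(trad_params, 6.0e-10, 0.7)
        assert intens / intens[0] == pytest.approx(expected / expected[0], rel=1e-6)

    def test_zero_D_constant_vector(self, grid, trad_params):
        sp = Species("s", (Multiplet(2.0, 0.0, 1),), D=0.0, T2=0.7, linewidth=1.5, amplitude=1.0)
        ph = Phantom("p", [sp], water=tiny_water(), noise_sigma=0.0)
        ds = simulate_dataset(ph, trad_params, grid, seed=0)
        m = process.apodize_and_transform(ds, gw=1.0, target_points=2 * grid.points)
        intens, _ = extract_decay(m, pick_peaks(m)[0])
        assert intens == pytest.approx(np.full_like(intens, intens[0]), rel=1e-12)

    def test_overlapping_species_additive(self, grid_fine, trad_params):
        mk = lambda name, d: Species(
            name, (Multiplet(2.0, 0.0, 1),), D=d, T2=0.7, linewidth=1.5, amplitude=1.0
        )
        w = tiny_water()
        both = simulate_dataset(
            Phantom("p", [mk("a", 1.0), mk("b", 8.0)], water=w, noise_sigma=0.0),
            trad_params, grid_fine, seed=0,
        )
        one = simulate_dataset(
            Phantom("p", [mk("a", 1.0)], water=w, noise_sigma=0.0),
            trad_params, grid_fine, seed=0,
        )
        two = simulate_dataset(
            Phantom("p", [mk("b", 8.0)], water=w, noise_sigma=0.0),
            trad_params, grid_fine, seed=0,
        )
        def decay(ds):
            m = process.apodize_and_transform(ds, gw=1.0, target_points=2 * grid_fine.points)
            i = int(np.argmin(np.abs(m.ppm_axis - 2.0)))
            return m.rows[:, i].real
        assert decay(both) == pytest.approx(decay(one) + decay(two), rel=1e-9)

    def test_window_truncated_by_mask_flagged(self, urine_matrix):
        # a pick adjacent to the pruned water region
        edge_ppm = 4.905
        i = int(np.argmin(np.abs(urine_matrix.ppm_axis - edge_ppm)))
        pick = Pick(ppm=float(urine_matrix.ppm_axis[i]), index=i, height=1.0)
        _intens, flags = extract_decay(urine_matrix, pick, window_ppm=0.05)
        assert "window_truncated" in flags


class TestFitStejskalTanner:
    def test_exact_recovery_noiseless(self, trad_b):
        b, fr = trad_b
        y = 50.0 * np.exp(-7.20 * b * 1e-10)
        fit = fit_stejskal_tanner(y, b, fractions=fr)
        assert fit.D == pytest.approx(7.20, rel=1e-6)
        assert fit.I0 == pytest.approx(50.0, rel=1e-6)
        assert fit.ok

    def test_two_point_closed_form_oracle(self, trad_b):
        # independent closed form: D = ln(I1/I2) / (b2 - b1)
        b, fr = trad_b
        y = 10.0 * np.exp(-3.3 * b * 1e-10)
        fit = fit_stejskal_tanner(y, b, fractions=fr)
        oracle = math.log(y[0] / y[-1]) / ((b[-1] - b[0]) * 1e-10)
        assert fit.D == pytest.approx(oracle, rel=1e-9)

    def test_t2_scaling_leaves_D_unchanged(self, trad_b):
        b, fr = trad_b
        y = 100.0 * np.exp(-5.5 * b * 1e-10)
        f1 = fit_stejskal_tanner(y, b, fractions=fr)
        f2 = fit_stejskal_tanner(0.037 * y, b, fractions=fr)
        assert f2.D == pytest.approx(f1.D, rel=1e-9)

    def test_overlap_average_strictly_between(self, trad_b):
        b, fr = trad_b
        y = 10.0 * np.exp(-1.0 * b * 1e-10) + 10.0 * np.exp(-8.0 * b * 1e-10)
        fit = fit_stejskal_tanner(y, b, fractions=fr)
        assert 1.0 < fit.D < 8.0

    def test_ramp_limit_contract(self, trad_b):
        b, fr = trad_b
        y = 10.0 * np.exp(-5.0 * b * 1e-10)
        fit = fit_stejskal_tanner(y, b, fractions=fr, ramp_limits_pct=(25.0, 95.0))
        assert all(fr[i] * 100.0 >= 25.0 - 1e-9 for i in fit.ramp_indices_used)
        assert 0 not in fit.ramp_indices_used  # the 5% increment is excluded

    def test_too_few_points_flagged(self, trad_b):
        b, fr = trad_b
        y = 10.0 * np.exp(-5.0 * b * 1e-10)
        fit = fit_stejskal_tanner(y[:2], b[:2])
        assert not fit.ok
        assert "too_few_points" in fit.flags

    def test_negative_D_clamped_and_flagged(self, trad_b):
        b, fr = trad_b
        rng = np.random.default_rng(0)
        y = 10.0 * np.exp(+0.05 * b * 1e-10) + rng.normal(scale=1e-3, size=b.size)
        fit = fit_stejskal_tanner(y, b, fractions=fr)
        assert fit.D == 0.0
        assert "clamped_negative" in fit.flags

    def test_grid_fallback_for_nonpositive_tail(self, trad_b):
        b, fr = trad_b
        y = 10.0 * np.exp(-9.0 * b * 1e-10)
        y[2:] = -1e-6  # only two positive points: log-init must fall back
        fit = fit_stejskal_tanner(y, b, fractions=fr)
        assert fit.n_points_used == len(b)

    def test_monte_carlo_coverage(self):
        # 100 noisy fits at 2% noise: truth inside +-1 stderr >= 60%
        # and inside +-2 stderr >= 90% (16-increment ramp keeps the
        # covariance-based stderr close to Gaussian calibration)
        params = seqmodel.sequence_params("traditional", n_increments=16)
        ramp = seqmodel.gradient_ramp(params)
        b = seqmodel.b_value(params, ramp.amplitudes)
        rng = np.random.default_rng(1)
        in1 = in2 = 0
        for _ in range(100):
            y = 100.0 * np.exp(-7.20 * b * 1e-10) + rng.normal(scale=2.0, size=b.size)
            fit = fit_stejskal_tanner(y, b, fractions=ramp.fractions)
            if abs(fit.D - 7.20) <= fit.stderr_D:
                in1 += 1
            if abs(fit.D - 7.20) <= 2 * fit.stderr_D:
                in2 += 1
        assert in1 >= 60
        assert in2 >= 90


class TestBuildPeakList:
    def test_urine_fits_match_ground_truth(self, urine_matrix, urine_phantom):
        pl = build_peak_list(urine_matrix, "urine")
        assert len(pl) > 30
        lines = species_line_table(urine_phantom)
        truth_D = {name: sp.D for sp in urine_phantom.species for name in [sp.name]}
        truth_D["tsp"] = urine_phantom.reference.D
        errs = []
        for p in pl.peaks:
            ppm0, name = min(lines, key=lambda t: abs(t[0] - p.ppm))
            if abs(ppm0 - p.ppm) > 0.004 or not np.isfinite(p.relative_error):
                continue
            # skip peaks whose window overlaps a line of another species
            close = {n for q, n in lines if abs(q - p.ppm) <= 0.01}
            if close != {name}:
                continue
            errs.append(abs(p.D - truth_D[name]))
        assert len(errs) > 20
        assert np.median(errs) < 0.15
        assert np.quantile(errs, 0.9) < 0.5

    def test_empty_spectrum_empty_list(self, trad_params):
        n = 2000
        ppm = np.linspace(12.0, -2.0, n)
        m = process.SpectrumMatrix(
            ppm_axis=ppm,
            rows=np.zeros((trad_params.n_increments, n), dtype=complex),
            params=trad_params,
        )
        m.noise_sd = 1.0
        pl = build_peak_list(m, "empty")
        assert len(pl) == 0

    def test_failed_fits_kept_with_flags(self, grid, trad_params):
        # very fast-decaying species: almost no signal after increment 1
        sp = Species("fast", (Multiplet(2.0, 0.0, 1),), D=9.9, T2=0.5, linewidth=1.5, amplitude=1.0)
        ph = Phantom("p", [sp], water=tiny_water(), noise_sigma=0.0)
        ds = simulate_dataset(ph, trad_params.with_(n_increments=3), grid, seed=0)
        m = process.apodize_and_transform(ds, gw=1.0, target_points=2 * grid.points)
        pl = build_peak_list(m, "x", ramp_limits_pct=(50.0, 95.0))
        assert len(pl) >= 1
        assert all("fit_failed" in p.flags for p in pl.peaks)


class TestPeakListIO:
    def _peaklist(self):
        return DosyPeakList(
            spectrum_id="s1",
            peaks=[
                PeakEntry(1.47, 6.8, 0.012, 420.0),
                PeakEntry(5.23, 7.2, 0.05, 88.0, ("window_truncated",)),
                PeakEntry(9.1, 0.0, math.inf, 12.0, ("fit_failed", "too_few_points")),
            ],
            params_hash="abc123",
        )

    def test_write_read_round_trip(self, tmp_path):
        pl = self._peaklist()
        path = tmp_path / "s1.tsv"
        pl.write(path)
        back, warnings = DosyPeakList.read(path)
        assert warnings == []
        assert back.spectrum_id == "s1"
        assert back.params_hash == "abc123"
        assert back.peaks == pl.peaks

    def test_malformed_line_warned_not_dropped(self, tmp_path):
        pl = self._peaklist()
        path = tmp_path / "s1.tsv"
        pl.write(path)
        lines = path.read_text().splitlines()
        lines.insert(5, "garbage\twithout\tenough")
        path.write_text("\n".join(lines) + "\n")
        back, warnings = DosyPeakList.read(path)
        assert len(warnings) == 1
        assert ":6:" in warnings[0]
        assert len(back.peaks) == len(pl.peaks)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("# dosykit peak list v1\n" + DosyPeakList.HEADER + "\n")
        back, warnings = DosyPeakList.read(path)
        assert back.peaks == [] and warnings == []

    def test_missing_header_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1.0\t2.0\t0.1\t5.0\tok\n")
        with pytest.raises(ValueError, match="header"):
            DosyPeakList.read(path)


class TestSynthesizeDosyMatrix:
    def test_single_peak_single_maximum(self):
        pl = DosyPeakList("s", [PeakEntry(3.0, 5.0, 0.01, 10.0)])
        ppm = np.linspace(10.0, -1.0, 800)
        mat, d_axis, _ = synthesize_dosy_matrix(pl, ppm)
        id, ip = np.unravel_index(np.argmax(mat), mat.shape)
        assert d_axis[id] == pytest.approx(5.0, abs=0.1)
        assert ppm[ip] == pytest.approx(3.0, abs=0.02)

    def test_column_integral_normalization(self):
        pl = DosyPeakList("s", [PeakEntry(3.0, 5.0, 0.01, 10.0)])
        ppm = np.linspace(10.0, -1.0, 800)
        mat, d_axis, _ = synthesize_dosy_matrix(pl, ppm)
        dd = d_axis[1] - d_axis[0]
        ip = int(np.argmin(np.abs(ppm - 3.0)))
        assert mat[:, ip].sum() * dd == pytest.approx(10.0, rel=0.05)

    def test_two_D_values_resolved(self):
        pl = DosyPeakList(
            "s",
            [PeakEntry(3.0, 2.0, 0.01, 10.0), PeakEntry(3.0, 8.0, 0.01, 10.0)],
        )
        ppm = np.linspace(10.0, -1.0, 400)
        mat, d_axis, _ = synthesize_dosy_matrix(pl, ppm, d_width_floor=0.2)
        ip = int(np.argmin(np.abs(ppm - 3.0)))
        col = mat[:, ip]
        maxima = [
            i
            for i in range(1, len(col) - 1)
            if col[i] > col[i - 1] and col[i] >= col[i + 1] and col[i] > 0.1 * col.max()
        ]
        assert len(maxima) == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            synthesize_dosy_matrix(DosyPeakList("s", []), np.linspace(10, -1, 100))
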