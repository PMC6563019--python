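"""Peak extraction, drift correction and alignment."""

import numpy as np
import pandas as pd
import pytest

from glycoms import (AlignmentParams, CohortConfig, Peak, align_runs,
                     apply_drift, detect_peaks, extract_eics, fit_drift,
                     generate_cohort, pick_run_peaks, smooth)
from glycoms.containers import RawRun
from glycoms.peakproc import DriftFitError, EicTrace, estimate_noise
from glycoms.simdata import internal_standard_references


def gaussian_trace(height=1000.0, mu=5.0, sigma=0.05, step=0.01, span=(3.0, 7.0),
                   mz=1000.0):
    t = np.arange(*span, step)
    y = height * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return EicTrace(mz, 0.0, t, y)


def make_run(peaks, step=0.01, span=(0.0, 10.0), sigma=0.05, run_id="R1",
             run_type="study"):
    """Build a RawRun from (rt, mz, height) triples of Gaussian peaks."""
    grid = np.arange(*span, step)
    rows = []
    for rt0, mz0, h in peaks:
        sel = np.abs(grid - rt0) < 4 * sigma
        t = grid[sel]
        y = h * np.exp(-0.5 * ((t - rt0) / sigma) ** 2)
        rows.append(pd.DataFrame({"scan_rt_min": t, "mz": mz0, "intensity": y}))
    ions = pd.concat(rows, ignore_index=True).sort_values(
        ["scan_rt_min", "mz"], ignore_index=True)
    return RawRun(run_id=run_id, run_type=run_type, ions=ions)


class TestExtractEics:
    def test_single_series_single_trace(self):
        run = make_run([(5.0, 1000.0, 500.0)])
        traces = extract_eics(run)
        assert len(traces) == 1
        assert traces[0].mz_center == pytest.approx(1000.0, abs=1e-6)

    def test_half_dalton_apart_two_traces(self):
        run = make_run([(5.0, 1000.0, 500.0), (5.0, 1000.5, 500.0)])
        traces = extract_eics(run, mz_cluster_gap=0.1)
        assert len(traces) == 2

    def test_every_ion_assigned_once(self):
        run = make_run([(3.0, 1000.0, 500.0), (5.0, 1200.0, 800.0)])
        traces = extract_eics(run)
        total = sum(tr.intensity.sum() for tr in traces)
        assert total == pytest.approx(run.ions.intensity.sum())
        for tr in traces:
            assert len(tr.rt) == len(run.scan_times)

    def test_cohort_features_covered(self):
        cfg = CohortConfig(seed=4, n_features=40, n_cancer=2, n_control=2,
                           n_blanks=1, n_noise=0)
        runs, _, truth = generate_cohort(cfg)
        run = next(r for r in runs if r.run_type == "study")
        traces = extract_eics(run)
        centers = np.array([tr.mz_center for tr in traces])
        present = truth.areas[run.run_id].dropna().index
        drift = truth.drift.loc[run.run_id, "mz_offset"]
        for fid in present:
            mz = truth.features.loc[fid, "mz"] + drift
            assert np.min(np.abs(centers - mz)) < 0.05

    def test_empty_run_rejected(self):
        run = RawRun("X", "study", pd.DataFrame(
            {"scan_rt_min": [1.0], "mz": [1000.0], "intensity": [5.0]}))
        with pytest.raises(ValueError):
            extract_eics(run)


class TestSmooth:
    def test_constant_trace_unchanged(self):
        tr = EicTrace(1000.0, 0.0, np.arange(0, 1, 0.01), np.full(100, 7.0))
        out = smooth(tr)
        assert np.allclose(out.intensity, 7.0)

    def test_line_unchanged(self):
        t = np.arange(0, 1, 0.01)
        tr = EicTrace(1000.0, 0.0, t, 3.0 + 2.0 * t)
        out = smooth(tr)
        assert np.allclose(out.intensity, tr.intensity, atol=1e-9)

    def test_noise_reduced_on_gaussian(self):
        rng = np.random.default_rng(0)
        clean = gaussian_trace()
        noisy = EicTrace(clean.mz_center, 0.0, clean.rt,
                         clean.intensity + rng.normal(0, 30.0, clean.rt.size))
        out = smooth(noisy, 7, 2)
        resid_in = np.std(noisy.intensity - clean.intensity)
        resid_out = np.std(out.intensity - clean.intensity)
        assert resid_out < resid_in

    @pytest.mark.parametrize("window,polyorder", [(6, 2), (3, 3), (9999, 2)])
    def test_bad_window_rejected(self, window, polyorder):
        with pytest.raises(ValueError):
            smooth(gaussian_trace(), window, polyorder)


class TestDetectPeaks:
    def test_all_zero_no_peaks(self):
        tr = EicTrace(1000.0, 0.0, np.arange(0, 1, 0.01), np.zeros(100))
        assert detect_peaks(tr) == []

    def test_monotone_rise_no_peaks(self):
        t = np.arange(0, 1, 0.01)
        tr = EicTrace(1000.0, 0.0, t, t * 100.0)
        assert detect_peaks(tr) == []

    def test_gaussian_apex_and_area(self):
        """Quadrature oracle: area of h*exp(-(t-mu)^2/2s^2) = h*s*sqrt(2pi)."""
        tr = smooth(gaussian_trace(height=1000.0, mu=5.0, sigma=0.05, step=0.01))
        peaks = detect_peaks(tr)
        assert len(peaks) == 1
        p = peaks[0]
        fine = np.arange(3.0, 7.0, 0.0001)
        truth_area = np.trapezoid(1000.0 * np.exp(-0.5 * ((fine - 5.0) / 0.05) ** 2), fine)
        assert abs(p.rt_apex - 5.0) <= 0.01
        assert p.area == pytest.approx(truth_area, rel=0.02)
        assert p.rt_start < p.rt_apex < p.rt_end

    def test_overlapping_peaks_split_at_valley(self):
        t = np.arange(0, 2, 0.005)
        y = (900 * np.exp(-0.5 * ((t - 0.8) / 0.05) ** 2)
             + 700 * np.exp(-0.5 * ((t - 1.05) / 0.05) ** 2))
        peaks = detect_peaks(smooth(EicTrace(1000.0, 0.0, t, y)))
        assert len(peaks) == 2
        assert peaks[0].rt_apex == pytest.approx(0.8, abs=0.02)
        assert peaks[1].rt_apex == pytest.approx(1.05, abs=0.02)

    def test_zero_valley_split_preserves_peaks(self):
        """Detecting two well-separated peaks on one trace equals detecting
        them on the two halves split at the zero valley."""
        t = np.arange(0, 4, 0.01)
        y = (900 * np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
             + 700 * np.exp(-0.5 * ((t - 3.0) / 0.05) ** 2))
        full = detect_peaks(smooth(EicTrace(1000.0, 0.0, t, y)))
        cut = np.searchsorted(t, 2.0)
        left = detect_peaks(smooth(EicTrace(1000.0, 0.0, t[:cut], y[:cut])))
        right = detect_peaks(smooth(EicTrace(1000.0, 0.0, t[cut:], y[cut:])))
        halves = left + right
        assert len(full) == len(halves) == 2
        for a, b in zip(full, sorted(halves, key=lambda p: p.rt_apex)):
            assert a.rt_apex == pytest.approx(b.rt_apex, abs=1e-9)
            # smoothing treats the trace boundary slightly differently, so
            # areas agree to ~1e-5 relative rather than exactly
            assert a.area == pytest.approx(b.area, rel=1e-3)

    def test_sn_uses_noise_level(self):
        tr = smooth(gaussian_trace(height=1000.0))
        (p_inf,) = detect_peaks(tr, noise=None)
        (p_sn,) = detect_peaks(tr, noise=10.0)
        assert np.isinf(p_inf.sn)
        assert p_sn.sn == pytest.approx(p_sn.height / 10.0)


class TestDrift:
    def refs(self):
        return pd.DataFrame({"rt": [2.0, 5.0, 8.0], "mz": [1000.0, 1500.0, 2000.0]})

    def std_peaks(self, rt_shift=0.0, mz_shift=0.0):
        return [Peak(rt_start=r - 0.1 + rt_shift, rt_apex=r + rt_shift,
                     rt_end=r + 0.1 + rt_shift, mz=m + mz_shift, height=1e5,
                     area=1e4, sn=np.inf, run_id="R")
                for r, m in zip(self.refs().rt, self.refs().mz)]

    def test_identity_when_already_at_reference(self):
        model = fit_drift(self.std_peaks(), self.refs())
        assert model.rt_offset == pytest.approx(0.0, abs=1e-9)
        assert model.rt_slope == pytest.approx(1.0, abs=1e-9)
        assert model.mz_offset == pytest.approx(0.0, abs=1e-9)

    def test_uniform_rt_shift_recovered(self):
        model = fit_drift(self.std_peaks(rt_shift=0.10), self.refs())
        assert model.rt_offset == pytest.approx(-0.10, abs=1e-6)
        assert model.rt_slope == pytest.approx(1.0, abs=1e-6)

    def test_uniform_mz_shift_recovered(self):
        model = fit_drift(self.std_peaks(mz_shift=0.02), self.refs())
        assert model.mz_offset == pytest.approx(-0.02, abs=1e-6)

    def test_roundtrip_restores_standards(self):
        shifted = self.std_peaks(rt_shift=0.08, mz_shift=-0.01)
        model = fit_drift(shifted, self.refs())
        corrected = apply_drift(shifted, model)
        for p, r, m in zip(corrected, self.refs().rt, self.refs().mz):
            assert p.rt_apex == pytest.approx(r, abs=1e-6)
            assert p.mz == pytest.approx(m, abs=1e-6)

    def test_apply_preserves_areas(self):
        shifted = self.std_peaks(rt_shift=0.05)
        model = fit_drift(shifted, self.refs())
        for before, after in zip(shifted, apply_drift(shifted, model)):
            assert after.area == before.area and after.height == before.height

    def test_too_few_matches_errors_with_run_id(self):
        with pytest.raises(DriftFitError, match="R7"):
            fit_drift(self.std_peaks()[:1], self.refs(), run_id="R7")

    def test_correction_reduces_rt_error_on_cohort(self):
        cfg = CohortConfig(seed=6, n_features=50, n_cancer=3, n_control=3,
                           n_blanks=1, n_noise=0, isotope_prob=0, adduct_prob=0,
                           fragment_prob=0)
        runs, _, truth = generate_cohort(cfg)
        refs = internal_standard_references(truth)
        run = next(r for r in runs if r.run_type == "study")
        peaks = pick_run_peaks(run)
        model = fit_drift(peaks, refs, run_id=run.run_id)
        corrected = apply_drift(peaks, model)
        true_rt = truth.features["rt"]

        def med_err(pks):
            errs = []
            for fid in truth.areas[run.run_id].dropna().index:
                d = [abs(p.rt_apex - true_rt[fid]) for p in pks
                     if abs(p.mz - truth.features.loc[fid, "mz"]) < 0.1]
                if d:
                    errs.append(min(d))
            return np.median(errs)

        assert med_err(corrected) < med_err(peaks)


class TestAlignment:
    def pk(self, rt, mz, run_id, height=1000.0, area=100.0):
        return Peak(rt_start=rt - 0.1, rt_apex=rt, rt_end=rt + 0.1, mz=mz,
                    height=height, area=area, sn=np.inf, run_id=run_id)

    def test_within_tolerance_merges(self):
        table = align_runs({"A": [self.pk(5.00, 1000.00, "A")],
                            "B": [self.pk(5.29, 1000.05, "B")]})
        assert len(table) == 1
        assert table.areas.notna().sum().sum() == 2

    @pytest.mark.parametrize("drt,dmz,expected", [
        (0.29, 0.0, 1), (0.31, 0.0, 2), (0.0, 0.05, 1), (0.0, 0.07, 2),
    ])
    def test_tolerance_boundaries(self, drt, dmz, expected):
        table = align_runs({"A": [self.pk(5.0, 1000.0, "A")],
                            "B": [self.pk(5.0 + drt, 1000.0 + dmz, "B")]})
        assert len(table) == expected

    def test_single_run_identity(self):
        peaks = [self.pk(1.0 + i, 1000.0 + 10 * i, "A") for i in range(5)]
        table = align_runs({"A": peaks})
        assert len(table) == 5
        assert table.areas["A"].notna().all()

    def test_one_peak_per_run_per_cluster(self):
        # two same-run peaks inside one tolerance window cannot share a cluster
        table = align_runs({"A": [self.pk(5.0, 1000.0, "A", height=1000),
                                  self.pk(5.1, 1000.01, "A", height=900)],
                            "B": [self.pk(5.05, 1000.0, "B")]})
        assert len(table) == 2

    def test_permutation_stable(self):
        rng = np.random.default_rng(0)
        per_run = {}
        for rid in ["A", "B", "C", "D"]:
            per_run[rid] = [self.pk(rt + rng.normal(0, 0.05),
                                    mz + rng.normal(0, 0.005), rid,
                                    height=float(rng.uniform(100, 1000)))
                            for rt, mz in [(2.0, 1000.0), (4.0, 1200.0), (6.0, 1500.0)]]
        t1 = align_runs(per_run)
        t2 = align_runs(dict(reversed(list(per_run.items()))))
        pd.testing.assert_frame_equal(t1.areas, t2.areas)

    def test_noiseless_cohort_full_recovery(self):
        """Drift inside tolerance: >= 99% of monoisotopic features come back
        as exactly one cluster covering every non-blank run."""
        cfg = CohortConfig(seed=5, n_features=150, n_cancer=6, n_control=6,
                           n_blanks=1, noise_sd_rel=0.0, bio_cv=0.0,
                           scan_noise_sd=0.0, isotope_prob=0, adduct_prob=0,
                           fragment_prob=0, n_noise=0)
        runs, manifest, truth = generate_cohort(cfg)
        refs = internal_standard_references(truth)
        per = {}
        for r in runs:
            pks = pick_run_peaks(r)
            per[r.run_id] = apply_drift(pks, fit_drift(pks, refs, run_id=r.run_id))
        table = align_runs(per)
        n_present = (manifest.run_type != "blank").sum()
        counts = table.areas.notna().sum(axis=1).to_numpy()
        frt = table.features["rt"].to_numpy()
        fmz = table.features["mz"].to_numpy()
        mono = truth.features[truth.features.role == "monoisotopic"]
        exact = 0
        for _, m in mono.iterrows():
            hits = np.where((np.abs(frt - m.rt) <= 0.3) & (np.abs(fmz - m.mz) <= 0.06))[0]
            if len(hits) == 1 and counts[hits[0]] == n_present:
                exact += 1
        assert exact / len(mono) >= 0.99
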