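"""Windowed F_ST scan: filtering, profiles, window statistics, IBD calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hornscan as hs
from hornscan.scan import SiteProfile


def matrix_from_calls(calls, positions=None, n_case=None, region=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    n_case = n_case if n_case is not None else n_samples // 2
    positions = positions if positions is not None else np.arange(1, n_sites + 1) * 100
    samples = [f"case_{i}" for i in range(n_case)] + \
              [f"ctrl_{i}" for i in range(n_samples - n_case)]
    return hs.SiteMatrix("chr", np.asarray(positions), [("A", "G")] * n_sites,
                         calls, np.array([True] * n_case + [False] * (n_samples - n_case)),
                         samples, region=region)


class TestFilterInformative:
    def test_monomorphic_site_removed(self):
        m = matrix_from_calls([[0, 0, 0, 0], [0, 1, 1, 0]])
        assert hs.filter_informative(m).positions.tolist() == [200]

    def test_maf_just_above_cutoff_retained(self):
        # 24 samples, 3 alt alleles of 48 -> MAF 0.0625 > 0.05
        calls = np.zeros((1, 24), dtype=np.int8)
        calls[0, :3] = 1
        m = matrix_from_calls(calls, n_case=12)
        assert hs.filter_informative(m, maf_min=0.05).n_sites == 1
        # 2 alt alleles of 48 -> MAF ~0.0417 <= 0.05 -> removed
        calls2 = np.zeros((1, 24), dtype=np.int8)
        calls2[0, :2] = 1
        assert hs.filter_informative(matrix_from_calls(calls2, n_case=12),
                                     maf_min=0.05).n_sites == 0

    def test_zero_cutoff_removes_only_monomorphic(self):
        m = matrix_from_calls([[0, 0, 0, 0], [2, 2, 2, 2], [0, 0, 0, 1]])
        kept = hs.filter_informative(m, maf_min=0.0)
        assert kept.positions.tolist() == [300]

    def test_low_call_rate_dropped(self):
        miss = hs.MISSING
        m = matrix_from_calls([[miss, miss, miss, 1], [0, 1, 1, 0]])
        assert hs.filter_informative(m, maf_min=0.0).positions.tolist() == [200]


class TestCaseMajorProfile:
    def test_major_allele_and_both_group_freqs(self):
        # cases 0.9 alt, controls 0.1 alt
        calls = np.array([[2, 2, 2, 2, 1, 0, 0, 0, 0, 1]], dtype=np.int8)
        m = matrix_from_calls(calls, n_case=5)
        prof = hs.case_major_profile(m)
        assert prof.major_is_alt[0]
        assert prof.freq_case[0] == pytest.approx(0.9)
        assert prof.freq_control[0] == pytest.approx(0.1)

    def test_tie_resolves_to_reference_allele(self):
        calls = np.array([[1, 1, 0, 2]], dtype=np.int8)  # case freq(alt) = 0.5
        prof = hs.case_major_profile(matrix_from_calls(calls, n_case=2))
        assert not prof.major_is_alt[0]
        assert prof.freq_case[0] == pytest.approx(0.5)

    def test_fixed_difference(self):
        calls = np.array([[2, 2, 0, 0]], dtype=np.int8)
        prof = hs.case_major_profile(matrix_from_calls(calls, n_case=2))
        assert prof.freq_case[0] == 1.0 and prof.freq_control[0] == 0.0


class TestWindowFst:
    @pytest.mark.parametrize("p_case,p_ctrl,expected", [
        (0.4, 0.4, 0.0),
        (1.0, 0.0, 1.0),
        (0.9, 0.1, (0.5 - 0.18) / 0.5),  # closed-form hand evaluation
    ])
    def test_estimator_closed_form(self, p_case, p_ctrl, expected):
        assert hs.fst_from_window_means(p_case, p_ctrl) == pytest.approx(expected)

    def test_fixed_groups_have_zero_heterozygosity_fst_zero(self):
        assert hs.fst_from_window_means(1.0, 1.0) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_symmetry(self, p, q):
        fst = hs.fst_from_window_means(p, q)
        assert 0.0 <= fst <= 1.0 + 1e-12
        assert fst == pytest.approx(hs.fst_from_window_means(q, p))
        assert fst == pytest.approx(hs.fst_from_window_means(1 - p, 1 - q))

    def test_invalid_window_size(self, scan_matrix):
        prof = hs.case_major_profile(scan_matrix)
        with pytest.raises(ValueError):
            hs.window_fst(prof, window_size=0)

    def test_agrees_with_brute_force_oracle(self):
        # naive per-site recomputation on small random matrices
        rng = np.random.default_rng(17)
        for _ in range(10):
            n_sites = rng.integers(5, 50)
            calls = rng.integers(0, 3, size=(n_sites, 12)).astype(np.int8)
            positions = np.sort(rng.choice(np.arange(1, 5000), n_sites, replace=False))
            m = matrix_from_calls(calls, positions=positions, n_case=6,
                                  region=(1, 5000))
            prof = hs.case_major_profile(m)
            windows = hs.window_fst(prof, window_size=1000, step=500)
            for w in windows:
                exp = _oracle_window(calls, positions, 6, w.start, w.end)
                if exp is None:
                    assert w.n_sites == 0
                else:
                    assert w.freq_case == pytest.approx(exp[0])
                    assert w.freq_control == pytest.approx(exp[1])
                    assert w.fst == pytest.approx(exp[2])


def _oracle_window(calls, positions, n_case, start, end):
    """Independent loop-based recomputation of one window's statistics."""
    fc, fh = [], []
    for i, pos in enumerate(positions):
        if not (start <= pos < end):
            continue
        case = calls[i, :n_case]
        ctrl = calls[i, n_case:]
        f_case_alt = case.sum() / (2 * len(case))
        f_ctrl_alt = ctrl.sum() / (2 * len(ctrl))
        if f_case_alt > 0.5:
            fc.append(f_case_alt)
            fh.append(f_ctrl_alt)
        else:
            fc.append(1 - f_case_alt)
            fh.append(1 - f_ctrl_alt)
    if not fc:
        return None
    pc = sum(fc) / len(fc)
    ph = sum(fh) / len(fh)
    pbar = (pc + ph) / 2
    ht = 2 * pbar * (1 - pbar)
    hs_ = (2 * pc * (1 - pc) + 2 * ph * (1 - ph)) / 2
    return pc, ph, 0.0 if ht == 0 else (ht - hs_) / ht


class TestCallIbd:
    def _windows(self, fsts, start=0, size=10, step=10):
        return [hs.WindowStat(start + i * step, start + i * step + size,
                              5, 0.5, 0.5, f) for i, f in enumerate(fsts)]

    def test_equal_fst_everywhere_yields_no_intervals(self):
        res = hs.call_ibd(self._windows([0.2] * 10))
        assert res.threshold == pytest.approx(0.2)
        assert res.ibd_intervals == []

    def test_single_spike_yields_single_window_interval(self):
        res = hs.call_ibd(self._windows([0.1] * 9 + [0.9]))
        assert res.ibd_intervals == [(90, 99)]

    def test_adjacent_windows_merge(self):
        res = hs.call_ibd(self._windows([0.0] * 8 + [0.9, 0.9]))
        assert res.ibd_intervals == [(80, 99)]

    def test_threshold_is_mean_plus_k_population_sd(self):
        fsts = [0.1, 0.2, 0.3, 0.4]
        res = hs.call_ibd(self._windows(fsts), k_sd=1.5)
        arr = np.array(fsts)
        assert res.threshold == pytest.approx(arr.mean() + 1.5 * arr.std())

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            hs.call_ibd(self._windows([0.5]))

    def test_synthetic_defaults_recover_ibd_interval(self, scan_matrix):
        result = hs.run_scan(scan_matrix)
        truth = hs.ScanSimParams().ibd_interval
        assert len(result.ibd_intervals) == 1
        (lo, hi), step = result.ibd_intervals[0], 5000
        assert abs(lo - truth[0]) <= step
        assert abs(hi - truth[1]) <= step

    def test_label_swap_with_rederived_convention(self):
        # Swapping case/control labels and re-deriving the major allele leaves
        # per-site F_ST invariant: the re-derived allele is either the same or
        # the complement, and the estimator is symmetric under both changes.
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(40, 12)).astype(np.int8)
        positions = np.arange(1, 41) * 10
        m = matrix_from_calls(calls, positions=positions, n_case=6, region=(1, 400))
        swapped = hs.SiteMatrix(m.contig, m.positions, m.alleles, m.calls,
                                ~m.is_case, m.samples, region=m.region)
        w = hs.window_fst(hs.case_major_profile(m), window_size=10, step=10)
        w_sw = hs.window_fst(hs.case_major_profile(swapped), window_size=10, step=10)
        for a, b in zip(w, w_sw):
            assert a.n_sites == b.n_sites
            if a.n_sites:
                assert a.fst == pytest.approx(b.fst, abs=1e-12)
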