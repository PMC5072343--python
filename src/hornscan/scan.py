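"""Case/control windowed F_ST selection scan with IBD-interval calling.

The scan mirrors the mapping logic used to localise the polled haplotype:
sites are filtered to informative SNPs (pooled MAF above a cutoff), the major
allele within the case (polled) group is identified per site, both groups'
frequencies of that same allele are averaged over sliding windows, a
Nei-style G_ST is computed from the two window-mean frequencies, and the
identical-by-descent (IBD) region is called as the maximal run of windows whose
F_ST exceeds mean + k·SD over all non-empty windows.

The F_ST estimator operates on window-mean allele frequencies with equal group
weights: with p̄ = (p̄_case + p̄_control)/2, H_T = 2·p̄·(1−p̄) and
H_S = [2·p̄_case·(1−p̄_case) + 2·p̄_control·(1−p̄_control)]/2,

    F_ST = (H_T − H_S) / H_T,  defined as 0 when H_T = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, SiteMatrix, logger


@dataclass
class SiteProfile:
    """Per-site case-major allele and the two group frequencies of it."""

    positions: np.ndarray     # (n,) 1-based
    major_is_alt: np.ndarray  # (n,) bool — which allele is the case-major one
    freq_case: np.ndarray     # (n,) frequency of that allele among case calls
    freq_control: np.ndarray  # (n,) same allele's frequency among control calls
    region: tuple[int, int] | None = None


@dataclass
class WindowStat:
    start: int        # 1-based, window is [start, start + size) half-open
    end: int          # exclusive bound
    n_sites: int
    freq_case: float
    freq_control: float
    fst: float


@dataclass
class ScanResult:
    windows: list[WindowStat]
    threshold: float
    k_sd: float
    ibd_intervals: list[tuple[int, int]]  # 1-based inclusive


# ---------------------------------------------------------------------------

def filter_informative(matrix: SiteMatrix, maf_min: float = 0.05,
                       min_call_rate: float = 0.8) -> SiteMatrix:
    """Retain informative SNPs: pooled-sample MAF strictly above ``maf_min``.

    Sites with call rate below ``min_call_rate`` are dropped first.  MAF is
    computed over all non-missing calls of cases and controls pooled.
    """
    calls = matrix.calls
    ok = calls != MISSING
    call_rate = ok.mean(axis=1)
    alt = np.where(ok, calls, 0).sum(axis=1)
    total = 2.0 * ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt / total, np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (call_rate >= min_call_rate) & (maf > maf_min)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_informative: removed %d of %d sites (MAF<=%g or call rate<%g)",
                    n_drop, matrix.n_sites, maf_min, min_call_rate)
    if not keep.any():
        logger.warning("filter_informative: no sites remain")
    return matrix.subset_sites(keep)


def case_major_profile(matrix: SiteMatrix) -> SiteProfile:
    """Identify per site the major allele among cases and both group frequencies.

    The case-major allele is the allele whose frequency among non-missing case
    calls is >= 0.5; an exact 0.5 tie resolves to the reference allele.  Sites
    with no non-missing case call are dropped (logged).
    """
    calls = matrix.calls
    case = matrix.is_case
    ok = calls != MISSING

    def group_freq(mask: np.ndarray) -> np.ndarray:
        sub_ok = ok[:, mask]
        alt = np.where(sub_ok, calls[:, mask], 0).sum(axis=1)
        tot = 2.0 * sub_ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)

    f_case_alt = group_freq(case)
    f_ctrl_alt = group_freq(~case)
    informative = ~np.isnan(f_case_alt)
    n_drop = int((~informative).sum())
    if n_drop:
        logger.info("case_major_profile: dropped %d site(s) with no case calls", n_drop)

    f_case_alt = f_case_alt[informative]
    f_ctrl_alt = np.where(np.isnan(f_ctrl_alt), 0.0, f_ctrl_alt)[informative]
    # tie at 0.5 -> reference allele (major_is_alt False)
    major_is_alt = f_case_alt > 0.5
    freq_case = np.where(major_is_alt, f_case_alt, 1.0 - f_case_alt)
    freq_control = np.where(major_is_alt, f_ctrl_alt, 1.0 - f_ctrl_alt)
    return SiteProfile(matrix.positions[informative], major_is_alt,
                       freq_case, freq_control, region=matrix.region)


def fst_from_window_means(p_case: float, p_control: float) -> float:
    """Nei-style G_ST on two window-mean frequencies with equal group weights."""
    p_bar = (p_case + p_control) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return 0.0
    h_s = (2.0 * p_case * (1.0 - p_case) + 2.0 * p_control * (1.0 - p_control)) / 2.0
    return (h_t - h_s) / h_t


def window_fst(profile: SiteProfile, window_size: int = 20_000,
               step: int = 5_000) -> list[WindowStat]:
    """Slide windows over the profile and compute per-window mean freqs + F_ST.

    The window grid is anchored at the profile's declared region start (falling
    back to the first site) and advances by ``step``; windows are half-open
    ``[start, start + window_size)``.  Empty windows carry ``n_sites = 0`` and
    NaN statistics; they are excluded from threshold statistics downstream.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    if profile.positions.size == 0:
        raise ValueError("profile is empty")
    lo, hi = profile.region if profile.region else (
        int(profile.positions[0]), int(profile.positions[-1]))
    out: list[WindowStat] = []
    pos = profile.positions
    start = lo
    while start <= hi:
        end = start + window_size
        i0, i1 = np.searchsorted(pos, [start, end])
        n = int(i1 - i0)
        if n:
            p_c = float(profile.freq_case[i0:i1].mean())
            p_h = float(profile.freq_control[i0:i1].mean())
            fst = fst_from_window_means(p_c, p_h)
        else:
            p_c = p_h = fst = float("nan")
        out.append(WindowStat(start, end, n, p_c, p_h, fst))
        start += step
    return out


def call_ibd(windows: list[WindowStat], k_sd: float = 1.0) -> ScanResult:
    """Threshold windows at mean + k_sd·SD (population SD) and merge runs.

    IBD intervals are maximal unions of overlapping or adjacent windows with
    F_ST strictly above the threshold, reported 1-based inclusive.
    """
    filled = [w for w in windows if w.n_sites > 0]
    if len(filled) < 2:
        raise ValueError("need at least two non-empty windows to set a threshold")
    fst = np.array([w.fst for w in filled])
    threshold = float(fst.mean() + k_sd * fst.std())  # population SD (n divisor)

    intervals: list[tuple[int, int]] = []
    for w in filled:
        if not (w.fst > threshold):
            continue
        lo, hi = w.start, w.end - 1
        if intervals and lo <= intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
        else:
            intervals.append((lo, hi))
    logger.info("call_ibd: threshold=%.4f, %d interval(s)", threshold, len(intervals))
    return ScanResult(windows, threshold, k_sd, intervals)


def run_scan(matrix: SiteMatrix, *, maf_min: float = 0.05,
             window_size: int = 20_000, step: int = 5_000,
             k_sd: float = 1.0) -> ScanResult:
    """Full scan: MAF filter → case-major profile → window F_ST → IBD call."""
    filtered = filter_informative(matrix, maf_min=maf_min)
    profile = case_major_profile(filtered)
    windows = window_fst(profile, window_size=window_size, step=step)
    return call_ibd(windows, k_sd=k_sd)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def windows_to_tsv(result: ScanResult, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(w.start, w.end, w.n_sites, w.freq_case, w.freq_control, w.fst)
         for w in result.windows],
        columns=["start", "end", "n_sites", "freq_case", "freq_control", "fst"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def intervals_to_bed(result: ScanResult, contig: str, path) -> None:
    """Write called intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for lo, hi in result.ibd_intervals:
            fh.write(f"{contig}\t{lo - 1}\t{hi}\tIBD\n")


def plot_scan(result: ScanResult, path, contig: str = "") -> None:
    """Two group-frequency curves plus the F_ST curve and threshold band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    filled = [w for w in result.windows if w.n_sites > 0]
    mid = np.array([(w.start + w.end) / 2 for w in filled])
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(mid, [w.freq_case for w in filled], color="black", label="polled (case)")
    ax.plot(mid, [w.freq_control for w in filled], color="gray", label="horned (control)")
    ax.plot(mid, [w.fst for w in filled], color="red", label="$F_{ST}$")
    ax.axhline(result.threshold, color="red", ls="--", lw=0.8,
               label=f"threshold {result.threshold:.4f}")
    for lo, hi in result.ibd_intervals:
        ax.axvspan(lo, hi, color="0.85", zorder=0)
    ax.set_xlabel(f"position on {contig}" if contig else "position (bp)")
    ax.set_ylabel("frequency / $F_{ST}$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
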