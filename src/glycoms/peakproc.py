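"""Chromatographic peak extraction, drift correction and cross-run alignment.

The extraction follows the classic derivative scheme: extracted ion
chromatograms (EICs) are smoothed with a local least-squares polynomial
(Savitzky-Golay) filter and differentiated; a peak starts where the
derivative crosses from zero to positive, tops where it crosses from
positive to negative and ends where it returns from negative to zero.
Areas are trapezoidal integrals from start to end.  Run-level retention
time and m/z errors are corrected by an affine fit against
internal-standard reference peaks, and corrected peaks are aligned across
runs under fixed tolerances (default 0.3 min and 0.06 Da).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .containers import FeatureTable, RawRun

PEAK_COLUMNS = ["run_id", "rt_start", "rt_apex", "rt_end", "mz", "height", "area", "sn"]


@dataclass(frozen=True)
class EicTrace:
    """One extracted ion chromatogram on the run's scan grid."""

    mz_center: float
    mz_halfwidth: float
    rt: np.ndarray          # minutes, strictly increasing
    intensity: np.ndarray   # counts, >= 0

    def __post_init__(self):
        if len(self.rt) != len(self.intensity):
            raise ValueError("rt and intensity must have equal length")
        if len(self.rt) >= 2 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt grid must be strictly increasing")


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak."""

    rt_start: float
    rt_apex: float
    rt_end: float
    mz: float
    height: float
    area: float
    sn: float
    run_id: str = ""

    def __post_init__(self):
        if not (self.rt_start < self.rt_apex < self.rt_end):
            raise ValueError("require rt_start < rt_apex < rt_end")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("area and height must be positive")


@dataclass(frozen=True)
class DriftModel:
    """Affine per-run coordinate correction: x_ref = offset + slope * x_obs."""

    rt_offset: float = 0.0
    rt_slope: float = 1.0
    mz_offset: float = 0.0
    mz_slope: float = 1.0

    def correct_rt(self, rt):
        return self.rt_offset + self.rt_slope * np.asarray(rt)

    def correct_mz(self, mz):
        return self.mz_offset + self.mz_slope * np.asarray(mz)


@dataclass(frozen=True)
class AlignmentParams:
    """Cross-run matching tolerances."""

    rt_tol: float = 0.3   # minutes
    mz_tol: float = 0.06  # Da

    def __post_init__(self):
        if self.rt_tol <= 0 or self.mz_tol <= 0:
            raise ValueError("tolerances must be strictly positive")


class DriftFitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# EIC construction


def extract_eics(run: RawRun, mz_cluster_gap: float = 0.02) -> list[EicTrace]:
    """Partition a run's ions into EIC traces by m/z proximity.

    Ions are sorted by m/z and split wherever consecutive ions are more
    than ``mz_cluster_gap`` apart, so every ion belongs to exactly one
    trace.  Each trace lives on the run's full scan grid with zero fill;
    co-eluting ions falling in the same scan are summed.  The trace center
    is the intensity-weighted mean m/z of its member ions.
    """
    grid = run.scan_times
    if len(grid) < 2:
        raise ValueError(f"run {run.run_id} has fewer than 2 scans")
    ions = run.ions.sort_values("mz", kind="mergesort")
    mz = ions["mz"].to_numpy()
    rt = ions["scan_rt_min"].to_numpy()
    inten = ions["intensity"].to_numpy()

    breaks = np.where(np.diff(mz) > mz_cluster_gap)[0] + 1
    traces: list[EicTrace] = []
    scan_index = {t: i for i, t in enumerate(grid)}
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, len(mz)]):
        if hi <= lo:
            continue
        seg_i = inten[lo:hi]
        seg_rt = rt[lo:hi]
        seg_mz = mz[lo:hi]
        y = np.zeros(len(grid))
        idx = np.fromiter((scan_index[t] for t in seg_rt), dtype=int, count=hi - lo)
        np.add.at(y, idx, seg_i)
        w = seg_i.sum()
        center = float((seg_mz * seg_i).sum() / w) if w > 0 else float(seg_mz.mean())
        halfwidth = float((seg_mz.max() - seg_mz.min()) / 2.0)
        traces.append(EicTrace(center, halfwidth, grid.astype(float), y))
    return traces


def smooth(trace: EicTrace, window: int = 7, polyorder: int = 2) -> EicTrace:
    """Savitzky-Golay smoothing on the trace's own grid."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if window > len(trace.rt):
        raise ValueError(f"window {window} exceeds trace length {len(trace.rt)}")
    y = savgol_filter(trace.intensity, window_length=window, polyorder=polyorder)
    return replace(trace, intensity=y)


def estimate_noise(raw: EicTrace, smoothed: EicTrace) -> float:
    """Robust per-trace noise level: 1.4826 * MAD of the raw-minus-smoothed
    residual over scans with nonzero raw signal.  Returns 0.0 when the trace
    carries no residual (noiseless data)."""
    mask = raw.intensity > 0
    if mask.sum() < 3:
        return 0.0
    resid = raw.intensity[mask] - smoothed.intensity[mask]
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


# ---------------------------------------------------------------------------
# peak detection


def detect_peaks(trace: EicTrace, zero_eps: float = 1e-3, noise: float | None = None,
                 run_id: str = "") -> list[Peak]:
    """Derivative sign-change peak bounding on a (smoothed) trace.

    The derivative is assigned a dead-zone sign: |d| below ``zero_eps`` times
    the trace's maximum |d| counts as zero.  A peak is a complete
    zero->positive (start), positive->negative (apex), negative->zero (end)
    triple; a negative->positive transition at a valley closes one peak and
    opens the next.  Incomplete triples are discarded.  The apex is refined
    to the intensity maximum inside the span; the area is the trapezoidal
    integral of the trace between start and end.

    ``noise`` is the trace's noise level for S/N = height / noise
    (S/N = inf when the noise estimate is zero or not supplied).
    """
    y = trace.intensity
    t = trace.rt
    if len(t) < 3 or np.all(y == 0):
        return []
    d = np.gradient(y, t)
    dmax = np.max(np.abs(d))
    if dmax == 0:
        return []
    thr = zero_eps * dmax
    sign = np.zeros(len(d), dtype=int)
    sign[d > thr] = 1
    sign[d < -thr] = -1

    # three phases: idle (before a start), rising (start seen, waiting for
    # the positive->negative apex crossing, possibly through a flat zero
    # stretch at the top), falling (apex seen, waiting for negative->zero)
    IDLE, RISING, FALLING = 0, 1, 2
    peaks: list[Peak] = []
    state = IDLE
    start: int | None = None
    for i in range(1, len(sign)):
        s = sign[i]
        if state == IDLE:
            if s > 0 and sign[i - 1] <= 0:
                start = i - 1
                state = RISING
        elif state == RISING:
            if s < 0:
                state = FALLING
        else:  # FALLING
            if s == 0:
                peaks.extend(_finalize(trace, start, i, noise, run_id))
                state, start = IDLE, None
            elif s > 0:
                # valley between overlapping peaks: close one, open the next
                peaks.extend(_finalize(trace, start, i - 1, noise, run_id))
                start = i - 1
                state = RISING
    return peaks


def _finalize(trace: EicTrace, i0: int, i1: int, noise, run_id) -> list[Peak]:
    y = trace.intensity
    t = trace.rt
    if i1 - i0 < 2:
        return []
    seg = y[i0 : i1 + 1]
    k = int(np.argmax(seg)) + i0
    if k <= i0 or k >= i1:
        return []
    height = float(y[k])
    area = float(np.trapezoid(seg, t[i0 : i1 + 1]))
    if height <= 0 or area <= 0:
        return []
    sn = float("inf") if not noise else height / noise
    return [Peak(rt_start=float(t[i0]), rt_apex=float(t[k]), rt_end=float(t[i1]),
                 mz=trace.mz_center, height=height, area=area, sn=sn, run_id=run_id)]


def pick_run_peaks(run: RawRun, window: int = 7, polyorder: int = 2,
                   zero_eps: float = 1e-3, mz_cluster_gap: float = 0.02,
                   min_points: int = 5) -> list[Peak]:
    """Full per-run extraction: EICs -> smooth -> noise -> detect."""
    peaks: list[Peak] = []
    for raw in extract_eics(run, mz_cluster_gap=mz_cluster_gap):
        if np.count_nonzero(raw.intensity) < min_points or len(raw.rt) < window:
            continue
        sm = smooth(raw, window=window, polyorder=polyorder)
        noise = estimate_noise(raw, sm)
        peaks.extend(detect_peaks(sm, zero_eps=zero_eps, noise=noise, run_id=run.run_id))
    return peaks


# ---------------------------------------------------------------------------
# drift correction


def fit_drift(run_peaks: list[Peak], references: pd.DataFrame,
              match_rt_tol: float = 0.5, match_mz_tol: float = 0.1,
              run_id: str = "") -> DriftModel:
    """Affine correction mapping observed internal-standard coordinates onto
    their references.

    ``references`` has columns ``rt``/``mz`` (one row per standard).  Each
    reference is matched to the nearest observed peak within the (loose)
    match tolerances; at least two matches are required.
    """
    if len(run_peaks) == 0:
        raise DriftFitError(f"run {run_id or '?'}: no peaks to match standards against")
    rt = np.array([p.rt_apex for p in run_peaks])
    mz = np.array([p.mz for p in run_peaks])
    height = np.array([p.height for p in run_peaks])

    obs_rt, obs_mz, ref_rt, ref_mz = [], [], [], []
    for _, ref in references.iterrows():
        cand = np.where(
            (np.abs(rt - ref.rt) <= match_rt_tol) & (np.abs(mz - ref.mz) <= match_mz_tol)
        )[0]
        if len(cand) == 0:
            continue
        dist = ((rt[cand] - ref.rt) / match_rt_tol) ** 2 + ((mz[cand] - ref.mz) / match_mz_tol) ** 2
        best = cand[np.lexsort((-height[cand], dist))[0]]
        obs_rt.append(rt[best]); obs_mz.append(mz[best])
        ref_rt.append(ref.rt); ref_mz.append(ref.mz)
    if len(obs_rt) < 2:
        raise DriftFitError(
            f"run {run_id or '?'}: only {len(obs_rt)} internal-standard matches (need >= 2)"
        )

    rt_slope, rt_offset = _affine_fit(np.array(obs_rt), np.array(ref_rt))
    mz_slope, mz_offset = _affine_fit(np.array(obs_mz), np.array(ref_mz))
    return DriftModel(rt_offset=rt_offset, rt_slope=rt_slope,
                      mz_offset=mz_offset, mz_slope=mz_slope)


def _affine_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # degenerate spread -> pure offset with unit slope
    if np.ptp(x) < 1e-12:
        return 1.0, float(np.mean(y - x))
    slope, offset = np.polyfit(x, y, 1)
    return float(slope), float(offset)


def apply_drift(peaks: list[Peak], model: DriftModel) -> list[Peak]:
    """Coordinate-only transform; areas, heights and S/N untouched."""
    out = []
    for p in peaks:
        out.append(replace(
            p,
            rt_start=float(model.correct_rt(p.rt_start)),
            rt_apex=float(model.correct_rt(p.rt_apex)),
            rt_end=float(model.correct_rt(p.rt_end)),
            mz=float(model.correct_mz(p.mz)),
        ))
    return out


# ---------------------------------------------------------------------------
# alignment


def align_runs(per_run_peaks: dict[str, list[Peak]],
               params: AlignmentParams = AlignmentParams()) -> FeatureTable:
    """Greedy centroid clustering of drift-corrected peaks across runs.

    All runs' peaks are pooled and visited in canonical order (descending
    height, then RT, m/z, run id), so the result is independent of the
    order runs are supplied in.  Each peak joins the nearest existing
    cluster whose centroid is within both tolerances and whose slot for
    the peak's run is still free; otherwise it seeds a new cluster.  Cell
    values are peak areas (NaN where a run contributed no peak); feature
    coordinates are member centroids and feature S/N is the member median.
    """
    rows = []
    for rid, peaks in per_run_peaks.items():
        for p in peaks:
            rows.append((p.height, p.rt_apex, p.mz, rid, p.area, p.sn))
    run_ids = sorted(per_run_peaks)
    if not rows:
        return FeatureTable(pd.DataFrame(columns=run_ids),
                            pd.DataFrame(columns=["rt", "mz", "sn"]))
    pool = sorted(rows, key=lambda r: (-r[0], r[1], r[2], r[3]))

    rt_tol, mz_tol = params.rt_tol, params.mz_tol
    clusters: list[dict] = []
    cell_map: dict[tuple[int, int], list[int]] = defaultdict(list)

    def cell(rt, mz):
        return (int(np.floor(rt / rt_tol)), int(np.floor(mz / mz_tol)))

    for height, rt, mz, rid, area, sn in pool:
        c0 = cell(rt, mz)
        cand = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                cand.extend(cell_map.get((c0[0] + di, c0[1] + dj), ()))
        best = None
        best_d = np.inf
        for ci in cand:
            cl = clusters[ci]
            drt = rt - cl["rt"]
            dmz = mz - cl["mz"]
            if abs(drt) <= rt_tol and abs(dmz) <= mz_tol and rid not in cl["runs"]:
                d = (drt / rt_tol) ** 2 + (dmz / mz_tol) ** 2
                if d < best_d:
                    best_d, best = d, ci
        if best is None:
            clusters.append({"rt": rt, "mz": mz, "sum_rt": rt, "sum_mz": mz, "n": 1,
                             "runs": {rid: (area, sn)}})
            cell_map[c0].append(len(clusters) - 1)
        else:
            cl = clusters[best]
            old_cell = cell(cl["rt"], cl["mz"])
            cl["runs"][rid] = (area, sn)
            cl["sum_rt"] += rt
            cl["sum_mz"] += mz
            cl["n"] += 1
            cl["rt"] = cl["sum_rt"] / cl["n"]
            cl["mz"] = cl["sum_mz"] / cl["n"]
            new_cell = cell(cl["rt"], cl["mz"])
            if new_cell != old_cell:
                cell_map[old_cell].remove(best)
                cell_map[new_cell].append(best)

    order = np.lexsort(([c["mz"] for c in clusters], [c["rt"] for c in clusters]))
    fids = [f"FT{k+1:05d}" for k in range(len(clusters))]
    areas = pd.DataFrame(np.nan, index=fids, columns=run_ids)
    meta = pd.DataFrame(index=pd.Index(fids, name="feature_id"),
                        columns=["rt", "mz", "sn", "n_members"], dtype=float)
    for k, ci in enumerate(order):
        cl = clusters[ci]
        fid = fids[k]
        for rid, (area, sn) in cl["runs"].items():
            areas.loc[fid, rid] = area
        meta.loc[fid, "rt"] = cl["rt"]
        meta.loc[fid, "mz"] = cl["mz"]
        sns = [v[1] for v in cl["runs"].values()]
        finite = [s for s in sns if np.isfinite(s)]
        meta.loc[fid, "sn"] = float(np.median(finite)) if finite else np.inf
        meta.loc[fid, "n_members"] = cl["n"]
    areas.index.name = "feature_id"
    return FeatureTable(areas, meta)


# ---------------------------------------------------------------------------
# io helpers


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.run_id, p.rt_start, p.rt_apex, p.rt_end, p.mz, p.height, p.area, p.sn)
         for p in peaks],
        columns=PEAK_COLUMNS,
    )


def frame_to_peaks(df: pd.DataFrame) -> list[Peak]:
    return [
        Peak(rt_start=r.rt_start, rt_apex=r.rt_apex, rt_end=r.rt_end, mz=r.mz,
             height=r.height, area=r.area, sn=r.sn, run_id=str(r.run_id))
        for r in df.itertuples(index=False)
    ]
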