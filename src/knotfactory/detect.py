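"""Knot detection and classification in kymographs.

Knots appear on the extended molecule as bright, localized, persistent spots.
Three criteria separate true knots from transient entanglements (unknot
events): a knot (1) is a persistent, localized, bright feature; (2) shows no
large-scale size fluctuations once settled; and (3) can unravel only at the
molecule ends -- a feature that loses its intensity mid-chain is not counted.

The pipeline is: per-frame chain-extent estimation (threshold crossing),
spot detection (local maxima of the baseline-subtracted intensity), track
linking (optimal-assignment nearest neighbour with gap closing), track
classification by the three criteria, and event summary -- the knot count and
the knot positions 2 s after pressure release, normalized to the relaxing
extension r_relax measured on the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, grey_opening, median_filter
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from .synthetic import Kymograph

__all__ = [
    "DetectionConfig",
    "KnotTrack",
    "EventRecord",
    "chain_extent",
    "detect_spots",
    "link_tracks",
    "classify_tracks",
    "summarize_event",
    "analyze_kymograph",
    "EmptyFrameError",
]


class EmptyFrameError(ValueError):
    """Frame has no above-background signal."""


@dataclass(frozen=True)
class DetectionConfig:
    """Detection thresholds.  The criteria are qualitative in origin; these
    numeric defaults are the package's operating point and all are adjustable."""

    k_edge: float = 3.0      # chain-edge threshold, in noise sd above background
    k_spot: float = 3.0      # spot threshold, in noise sd
    min_separation_px: int = 5
    merge_radius_um: float = 0.7  # candidates closer than this are one spot
    baseline_window_um: float = 2.6   # grey-opening window for the chain baseline
    psf_sigma_um: float = 0.3  # optical PSF width used to convert peak height to area
    gate_px: float = 5.0     # max per-frame displacement when linking
    gap_max: int = 2         # frames a track may skip
    T_persist: float = 5.0   # s a knot must survive after release
    settle: float = 1.5      # s after release before size stability is judged
    cv_max: float = 0.45     # max coefficient of variation of settled excess intensity
    f_loss: float = 0.5      # fractional intensity loss that counts as unraveling
    d_edge: float = 1.0      # um from a chain end within which unraveling is allowed
    measure_delay: float = 2.0  # s after release at which positions are recorded
    min_mean_area: float = 0.3  # camera units * um; the "bright" part of criterion (1)


@dataclass
class KnotTrack:
    """One linked bright feature through time."""

    times: np.ndarray
    positions: np.ndarray          # um, image coordinates
    areas: np.ndarray              # excess integrated intensity per frame
    classification: str = "unclassified"   # knot | unknot-event
    end_fate: str = "unknown"      # persists | unraveled-at-end | unraveled-mid-chain

    def alive_at(self, t: float, slack: float) -> bool:
        return bool(np.any(np.abs(self.times - t) <= slack))

    def position_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.positions[i])


@dataclass
class EventRecord:
    """Outcome of one compression-relaxation event."""

    R_b: float
    t_w: float
    m: int
    positions: list          # normalized to r_relax, ascending (lower knot first)
    r_relax: float
    tracks: list = field(default_factory=list, repr=False)

    def to_row(self) -> dict:
        row = {"R_b": self.R_b, "t_w": self.t_w, "m": self.m, "r_relax": self.r_relax}
        for i in range(3):
            row[f"x{i + 1}_norm"] = self.positions[i] if i < len(self.positions) else np.nan
        return row


def _noise_stats(frame: np.ndarray, edge_frac: float = 0.1):
    k = max(3, int(edge_frac * frame.size / 2))
    edges = np.concatenate([frame[:k], frame[-k:]])
    bg = float(np.median(edges))
    sd = float(1.4826 * np.median(np.abs(edges - bg)))
    return bg, max(sd, 1e-12)


def chain_extent(frame: np.ndarray, x: np.ndarray, config: DetectionConfig = DetectionConfig()):
    """Chain edges by threshold crossing at background + k_edge * noise sd.

    Returns ((x_left, x_right), background, noise_sd).  The first and last
    above-threshold pixels bound the chain (robust to interior dips).
    """
    bg, sd = _noise_stats(frame)
    smooth = median_filter(frame, size=3)
    above = smooth > bg + config.k_edge * sd
    if not np.any(above):
        raise EmptyFrameError("no above-background signal in frame")
    # anchor the crossing to the chain level as well: at very low noise a
    # pure k*sd threshold would land far out in the PSF tail
    chain_level = float(np.median(smooth[above]))
    thr = bg + max(config.k_edge * sd, 0.35 * (chain_level - bg))
    idx = np.flatnonzero(smooth > thr)
    return (float(x[idx[0]]), float(x[idx[-1]])), bg, sd


def detect_spots(frame: np.ndarray, x: np.ndarray,
                 config: DetectionConfig = DetectionConfig()):
    """Candidate knot spots: local maxima of (intensity - chain baseline).

    The chain baseline is a grey-scale opening wider than the PSF, so
    localized spots stand out while the box/ramp envelope (including its
    edges) is preserved.  Candidates must exceed k_spot * noise sd and lie
    within the chain extent.  Returns a list of dicts with centroid position
    (um) and excess integrated intensity (from the peak height and the PSF
    width, which is robust against nearby spots).
    """
    try:
        (xl, xr), bg, sd = chain_extent(frame, x, config)
    except EmptyFrameError:
        return []
    px = float(x[1] - x[0])
    win = max(3, int(round(config.baseline_window_um / px)) | 1)
    # grey opening removes bumps narrower than the window but preserves the
    # box/ramp envelope (including its edges), so the residual isolates the
    # spots; light pre-smoothing keeps the opening off the noise floor
    smooth = gaussian_filter1d(frame, 1.0)
    baseline = grey_opening(smooth, size=win)
    excess = smooth - baseline
    peaks, props = find_peaks(excess, height=config.k_spot * sd,
                              distance=config.min_separation_px)
    peaks = [p for p in peaks if xl - px <= x[p] <= xr + px]
    # merge-suppress: spots co-localized within one PSF-scale radius are one
    # feature (baseline subtraction can leave side-lobes around bright spots)
    peaks = sorted(peaks, key=lambda p: -excess[p])
    accepted = []
    for p in peaks:
        if all(abs(x[p] - x[q]) > config.merge_radius_um for q in accepted):
            accepted.append(p)
    out = []
    # spots are diffraction-limited, so excess area = height * sigma * sqrt(2 pi)
    # with sigma the PSF width (plus the smoothing kernel); a height-based
    # estimate is far more stable than window summation near neighbours
    sigma_eff = float(np.hypot(config.psf_sigma_um, px))
    for p in sorted(accepted):
        lo, hi = max(p - 2, 0), min(p + 3, frame.size)
        seg = np.clip(excess[lo:hi], 0, None)
        centroid = float(np.sum(seg * x[lo:hi]) / seg.sum()) if seg.sum() > 0 else float(x[p])
        area = float(excess[p] * sigma_eff * np.sqrt(2.0 * np.pi))
        out.append({"position": centroid, "area": area, "height": float(excess[p]),
                    "pixel": int(p)})
    return out


def link_tracks(spots_per_frame, times, pixel_size: float,
                config: DetectionConfig = DetectionConfig()):
    """Link per-frame candidates into tracks.

    Frame-to-frame association minimizes total displacement (optimal
    assignment), gated at gate_px pixels per elapsed frame; a track survives
    gaps of up to gap_max frames.
    """
    gate0 = config.gate_px * pixel_size
    active = []   # dicts: t, x, area lists + last frame index
    done = []
    for fi, (t, spots) in enumerate(zip(times, spots_per_frame)):
        # retire stale tracks
        still = []
        for tr in active:
            if fi - tr["last"] > config.gap_max + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        if spots:
            if active:
                cost = np.full((len(active), len(spots)), 1e6)
                for i, tr in enumerate(active):
                    gate = gate0 * (fi - tr["last"])
                    for j, sp in enumerate(spots):
                        d = abs(sp["position"] - tr["x"][-1])
                        if d <= gate:
                            cost[i, j] = d
                ri, ci = linear_sum_assignment(cost)
                used = set()
                for i, j in zip(ri, ci):
                    if cost[i, j] < 1e6:
                        tr = active[i]
                        tr["t"].append(t)
                        tr["x"].append(spots[j]["position"])
                        tr["a"].append(spots[j]["area"])
                        tr["last"] = fi
                        used.add(j)
            else:
                used = set()
            for j, sp in enumerate(spots):
                if j not in used:
                    active.append({"t": [t], "x": [sp["position"]],
                                   "a": [sp["area"]], "last": fi})
    done.extend(active)
    return [
        KnotTrack(np.asarray(tr["t"]), np.asarray(tr["x"]), np.asarray(tr["a"]))
        for tr in done
    ]


def classify_tracks(tracks, release_start: float, movie_end: float,
                    extent_at, config: DetectionConfig = DetectionConfig()):
    """Apply the three knot criteria to each track.

    ``extent_at(t) -> (x_left, x_right)`` supplies the chain edges for the
    mid-chain test.  A track is a knot iff it survives at least T_persist
    after release, its settled excess intensity has a coefficient of
    variation below cv_max, and it never loses more than f_loss of its
    intensity while farther than d_edge from both chain ends.
    """
    for tr in tracks:
        sel = tr.times >= release_start
        if not np.any(sel):
            tr.classification = "unknot-event"
            tr.end_fate = "unraveled-mid-chain"
            continue
        t_rel = tr.times[sel]
        x_rel = tr.positions[sel]
        # median-smooth the noisy per-frame excess areas before judging
        # stability: single-frame estimation dips are not size fluctuations
        a_rel = median_filter(tr.areas[sel], size=3, mode="nearest")
        persists = (t_rel[-1] - release_start) >= config.T_persist

        # size-stability statistics use only the settled window: in the first
        # moments after release the chain is still compact and nearby spots
        # can be blended, so early excess-intensity estimates are unreliable
        settled = t_rel >= release_start + config.settle
        cv_ok = True
        bright = np.mean(a_rel) >= config.min_mean_area
        mid_loss = False
        if np.sum(settled) >= 3:
            a = a_rel[settled]
            cv_ok = (np.std(a) / max(np.mean(a), 1e-12)) < config.cv_max
            bright = np.mean(a) >= config.min_mean_area
            # mid-chain unraveling: sustained intensity loss away from both ends
            ref = np.median(a[: max(3, a.size // 3)])
            low = a < (1.0 - config.f_loss) * ref
            run = 0
            for tt, xx, lo in zip(t_rel[settled], x_rel[settled], low):
                if lo:
                    xl, xr = extent_at(tt)
                    if (xx - xl) > config.d_edge and (xr - xx) > config.d_edge:
                        run += 1
                        if run >= 2:
                            mid_loss = True
                            break
                        continue
                run = 0
        ended_early = (movie_end - t_rel[-1]) > 1.0
        if ended_early:
            xl, xr = extent_at(t_rel[-1])
            near_end = min(x_rel[-1] - xl, xr - x_rel[-1]) <= config.d_edge
            tr.end_fate = "unraveled-at-end" if near_end else "unraveled-mid-chain"
        else:
            tr.end_fate = "persists"

        is_knot = (persists and cv_ok and bright and not mid_loss
                   and tr.end_fate != "unraveled-mid-chain")
        tr.classification = "knot" if is_knot else "unknot-event"
        # internal consistency: a knot never unravels mid-chain
        assert not (tr.classification == "knot" and tr.end_fate == "unraveled-mid-chain")
    return tracks


def _barrier_on_left(kymo: Kymograph, hold_bounds) -> bool:
    """The barrier is the chain edge adjacent to the concentration maximum
    during hold (the ramp peaks at the barrier)."""
    t0, t1 = hold_bounds
    sel = (kymo.times >= t0) & (kymo.times < t1)
    mean_frame = kymo.data[sel].mean(axis=0)
    try:
        (xl, xr), bg, _ = chain_extent(mean_frame, kymo.x)
    except EmptyFrameError:
        return True
    inside = (kymo.x >= xl) & (kymo.x <= xr)
    xs = kymo.x[inside]
    w = np.clip(mean_frame[inside] - bg, 0, None)
    centroid = np.sum(w * xs) / max(np.sum(w), 1e-12)
    return centroid < 0.5 * (xl + xr)


def summarize_event(tracks, kymo: Kymograph, R_b: float = np.nan, t_w: float = np.nan,
                    config: DetectionConfig = DetectionConfig()) -> EventRecord:
    """Knot count and normalized positions 2 s after pressure release.

    m counts tracks classified as knots and alive at the measurement frame;
    positions are measured from the barrier edge and normalized by the chain
    extension r_relax on that same frame, then sorted ascending (lower knot
    first).
    """
    phases = dict((n, tuple(b)) for n, b in kymo.truth["phases"])
    if "release" not in phases:
        raise ValueError("protocol error: no release phase in kymograph")
    release_start = phases["release"][0]
    t_meas = release_start + config.measure_delay
    fi = int(np.argmin(np.abs(kymo.times - t_meas)))
    (xl, xr), _, _ = chain_extent(kymo.data[fi], kymo.x, config)
    r_relax = xr - xl
    left = _barrier_on_left(kymo, phases["hold"])
    slack = 1.5 * kymo.frame_interval
    positions = []
    m = 0
    for tr in tracks:
        # knots can only unravel after release, never form, so a knot track
        # is alive at the measurement time iff it has not yet ended (a track
        # first resolved later was merged with a neighbour at 2 s)
        if tr.classification != "knot" or tr.times[-1] < kymo.times[fi] - slack:
            continue
        m += 1
        xpos = tr.position_at(kymo.times[fi])
        d = (xpos - xl) if left else (xr - xpos)
        positions.append(float(np.clip(d / r_relax, 0.0, 1.0)))
    positions.sort()
    return EventRecord(R_b=R_b, t_w=t_w, m=m, positions=positions,
                       r_relax=float(r_relax), tracks=list(tracks))


def analyze_kymograph(kymo: Kymograph, R_b: float = np.nan, t_w: float = np.nan,
                      config: DetectionConfig = DetectionConfig()) -> EventRecord:
    """Full detection pipeline on one kymograph.

    Detection and classification run on the release phase (the chain must be
    extended for spots to be resolvable); the phase boundaries come from the
    acquisition protocol stored alongside the movie.
    """
    phases = dict((n, tuple(b)) for n, b in kymo.truth["phases"])
    if "release" not in phases:
        raise ValueError("protocol error: no release phase in kymograph")
    release_start, movie_end = phases["release"]

    spots = []
    extents = {}
    for fi, t in enumerate(kymo.times):
        if t < release_start + 0.5:  # chain still too compact to resolve spots
            spots.append([])
            continue
        frame = kymo.data[fi]
        spots.append(detect_spots(frame, kymo.x, config))
        try:
            (xl, xr), _, _ = chain_extent(frame, kymo.x, config)
            extents[float(t)] = (xl, xr)
        except EmptyFrameError:
            pass

    def extent_at(t):
        ts = np.array(sorted(extents))
        return extents[float(ts[np.argmin(np.abs(ts - t))])]

    tracks = link_tracks(spots, kymo.times, kymo.pixel_size, config)
    tracks = [tr for tr in tracks if tr.times.size >= 5]
    classify_tracks(tracks, release_start, movie_end, extent_at, config)
    return summarize_event(tracks, kymo, R_b=R_b, t_w=t_w, config=config)


def records_to_frame(records) -> pd.DataFrame:
    """EventRecord list -> tidy CSV-ready table."""
    return pd.DataFrame([r.to_row() for r in records])
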