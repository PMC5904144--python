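"""Synthetic data generation with known ground truth.

Everything the analysis pipeline consumes can be generated here: equilibrium
and compressed intensity profiles, piston-scaling series, multinomial
event-count tables, kymographs of compression-hold-release events with 0-3
knots, and knot-position samples.  Each generator is deterministic given its
seed and records the generating truth alongside the data, so every downstream
stage can be scored exactly.

Conventions
-----------
* x = 0 at the slit barrier, increasing away from it; positions in um.
* Normalized profile variables: C = c/c_o, X = x/r_o, R_c = r/r_o.
* Noise model: Gaussian with variance ``(floor^2 + shot^2 * I/c_o) * c_o^2``
  (shot-like, proportional to local intensity, plus a constant camera floor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry, T4_CHANNEL
from .profiles import IntensityProfile, box_psf_model, ramp_psf_model
from .kinetics import KnotCountTable

__all__ = [
    "TrueProfileSpec",
    "KnotSpec",
    "KymographSpec",
    "Kymograph",
    "gen_equilibrium_profile",
    "gen_compressed_profile",
    "gen_piston_series",
    "gen_event_counts",
    "gen_kymograph",
    "gen_knot_positions",
    "solve_R_c",
    "DEFAULT_NOISE",
    "InvalidSpecError",
]

#: (floor, shot) noise scales relative to c_o; conventional EMCCD-like choice.
DEFAULT_NOISE = (0.03, 0.08)


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


def solve_R_c(C_b: float, alpha: float) -> float:
    """Solve the mass-conservation constraint C_b*R_c - alpha*R_c^2/2 = 1 for R_c.

    Takes the smaller quadratic root (the physical extension; the larger root
    lies beyond the zero crossing of the ramp).  Raises if no root in (0, 1].
    """
    if alpha == 0:
        R_c = 1.0 / C_b
    else:
        disc = C_b**2 - 2.0 * alpha
        if disc < 0:
            raise InvalidSpecError(f"no real extension for C_b={C_b}, alpha={alpha}")
        R_c = (C_b - np.sqrt(disc)) / alpha
    if not (0 < R_c <= 1.0):
        raise InvalidSpecError(f"extension R_c={R_c:.4g} outside (0, 1]")
    return float(R_c)


@dataclass
class TrueProfileSpec:
    """Ground-truth parameters of a concentration profile.

    C_b and alpha are in normalized units (c_o and c_o per X respectively);
    R_c in units of r_o; r_o, sigma_psf in um; V in um/s; t_w in s.
    """

    C_b: float = 1.0
    alpha: float = 0.0
    R_c: float = 1.0
    r_o: float = 14.3
    c_o: float = 1.0
    sigma_psf: float = 0.3
    V: float = 0.0
    t_w: float = 0.0

    mass_tol: float = 1e-3

    @classmethod
    def compressed(cls, C_b: float, R_c: float | None = None, alpha: float | None = None,
                   **kw) -> "TrueProfileSpec":
        """Build a mass-conserving compressed spec from two of (C_b, R_c, alpha)."""
        if R_c is None and alpha is not None:
            R_c = solve_R_c(C_b, alpha)
        elif alpha is None and R_c is not None:
            alpha = 2.0 * (C_b * R_c - 1.0) / R_c**2
        else:
            raise ValueError("give exactly one of R_c or alpha")
        return cls(C_b=C_b, alpha=alpha, R_c=R_c, **kw)

    @property
    def R_b(self) -> float:
        return 1.0 / self.C_b

    @property
    def ramp_area(self) -> float:
        return self.C_b * self.R_c - self.alpha * self.R_c**2 / 2.0

    def validate(self) -> None:
        if self.r_o <= 0 or self.sigma_psf <= 0 or self.c_o <= 0:
            raise InvalidSpecError("r_o, c_o and sigma_psf must be positive")
        if not (0 < self.R_c <= 1.0):
            raise InvalidSpecError(f"R_c={self.R_c} outside (0, 1]")
        if self.C_b - self.alpha * self.R_c < -1e-9:
            raise InvalidSpecError("ramp concentration negative at the free edge")
        if abs(self.ramp_area - 1.0) > self.mass_tol:
            raise InvalidSpecError(
                f"mass conservation violated: ramp area {self.ramp_area:.6f} != 1"
            )


def _grid(extent: float, sigma: float, pixels: int):
    pad = max(5.0 * sigma, 1.0)
    return np.linspace(-pad, extent + pad, pixels)


def _add_noise(intensity: np.ndarray, c_o: float, noise, rng: np.random.Generator):
    floor, shot = noise
    if floor == 0 and shot == 0:
        return intensity
    var = (floor**2 + shot**2 * np.clip(intensity, 0, None) / c_o) * c_o**2
    return intensity + rng.normal(0.0, np.sqrt(var))


def gen_equilibrium_profile(spec: TrueProfileSpec, pixels: int = 256, seed: int = 0,
                            noise=(0.0, 0.0)) -> IntensityProfile:
    """Uniform box of extension r_o and amplitude c_o, convolved with the PSF.

    The closed-form convolution conserves the integral r_o * c_o exactly.
    """
    if pixels < 64:
        raise ValueError("pixels must be >= 64")
    if spec.r_o <= 0 or spec.sigma_psf <= 0:
        raise InvalidSpecError("r_o and sigma_psf must be positive")
    x = _grid(spec.r_o, spec.sigma_psf, pixels)
    clean = box_psf_model(x, 0.0, spec.r_o, spec.c_o, spec.sigma_psf)
    rng = np.random.default_rng(seed)
    return IntensityProfile(x, _add_noise(clean, spec.c_o, noise, rng))


def gen_compressed_profile(spec: TrueProfileSpec, pixels: int = 256, seed: int = 0,
                           noise=(0.0, 0.0)) -> IntensityProfile:
    """Linear ramp C(X) = C_b - alpha*X on [0, R_c] (barrier at X = 0),
    convolved with the PSF, in absolute units (x in um, intensity in camera
    units)."""
    if pixels < 64:
        raise ValueError("pixels must be >= 64")
    spec.validate()
    r = spec.R_c * spec.r_o
    x = _grid(r, spec.sigma_psf, pixels)
    # ramp in absolute units: c(x) = c_o * (C_b - alpha * x/r_o) on [0, r]
    clean = ramp_psf_model(
        x, spec.c_o * spec.C_b, spec.c_o * spec.alpha / spec.r_o, r, spec.sigma_psf
    )
    rng = np.random.default_rng(seed)
    return IntensityProfile(x, _add_noise(clean, spec.c_o, noise, rng))


def gen_piston_series(a: float, b: float, V_list, noise: float = 0.0, seed: int = 0,
                      **spec_kw) -> list[tuple[float, TrueProfileSpec]]:
    """Piston-theory series: for each flow speed V, C_b = b*sqrt(V), alpha = a*V,
    with R_c solved from mass conservation.

    ``noise`` applies optional multiplicative Gaussian scatter (relative sd) to
    C_b and alpha before re-solving R_c, emulating experimental spread about
    the scaling laws.
    """
    if a <= 0 or b <= 0:
        raise ValueError("scaling coefficients a, b must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for V in V_list:
        if V <= 0:
            raise ValueError(f"flow speed must be positive, got V={V}")
        C_b = b * np.sqrt(V)
        alpha = a * V
        if noise > 0:
            C_b *= 1.0 + noise * rng.standard_normal()
            alpha *= 1.0 + noise * rng.standard_normal()
        try:
            R_c = solve_R_c(C_b, alpha)
        except InvalidSpecError as err:
            raise InvalidSpecError(f"no valid extension at V={V}: {err}") from err
        out.append((float(V), TrueProfileSpec(
            C_b=float(C_b), alpha=float(alpha), R_c=R_c, V=float(V),
            mass_tol=np.inf, **spec_kw,
        )))
    return out


# ---------------------------------------------------------------------------
# event-count tables
# ---------------------------------------------------------------------------


def gen_event_counts(conditions, probs, seed: int = 0) -> KnotCountTable:
    """Multinomial event tallies per condition.

    Parameters
    ----------
    conditions : sequence of (R_b, t_w, n_events)
    probs : callable or sequence
        Probability vector P(m), m = 0..n_k, per condition: either a callable
        ``probs(R_b, t_w) -> array`` or a sequence aligned with ``conditions``.
    seed : int
        Seed for the multinomial draws.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, (R_b, t_w, n_events) in enumerate(conditions):
        if n_events < 0:
            raise ValueError("n_events must be >= 0")
        p = np.asarray(probs(R_b, t_w) if callable(probs) else probs[i], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError(f"probabilities must be nonnegative and sum to 1, got {p}")
        counts = rng.multinomial(int(n_events), p) if n_events else np.zeros(p.size, int)
        for m, c in enumerate(counts):
            rows.append({"R_b": R_b, "t_w": t_w, "m": m, "count": int(c)})
    return KnotCountTable(pd.DataFrame(rows, columns=["R_b", "t_w", "m", "count"]))


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------


@dataclass
class KnotSpec:
    """One programmed bright feature in a kymograph.

    ``fate`` distinguishes true knots (persist, or unravel only at a chain
    end) from unknot events (transient entanglements that decay mid-chain
    shortly after release).
    """

    birth_time: float          # s, must fall in compression or hold
    birth_position: float      # um from barrier, within compressed extent
    L_k: float                 # stored contour, um
    diffusivity: float = 0.01  # um^2/s
    fate: str = "persist"      # persist | unravel_at_end | decay_mid_chain
    fate_time: float = np.inf  # s after release start at which the fate acts

    @property
    def is_knot(self) -> bool:
        return self.fate in ("persist", "unravel_at_end")


@dataclass
class KymographSpec:
    """Specification of one compression-hold-release movie."""

    profile: TrueProfileSpec
    phases: tuple = (("equilibrium", 3.0), ("compression", 3.0),
                     ("hold", 10.0), ("release", 12.0))
    knots: list = field(default_factory=list)
    frame_interval: float = 0.25   # s
    pixel_size: float = 0.16       # um
    n_pixels: int = 128
    noise_model: tuple = DEFAULT_NOISE
    tau_relax: float = 10.0        # s, extension relaxation time after release
    hardcore_gap: float = 0.5      # um, no-passing separation between knots
    seed: int = 0

    def validate(self, channel: ChannelGeometry) -> None:
        names = [p[0] for p in self.phases]
        if any(d <= 0 for _, d in self.phases):
            raise InvalidSpecError("phase durations must be positive")
        if "hold" not in names or "release" not in names:
            raise InvalidSpecError("phases must include hold and release")
        bounds = dict(self.phase_bounds())
        r = self.profile.R_c * self.profile.r_o
        if 2.0 * self.profile.sigma_psf >= r:
            raise InvalidSpecError("knot spot (PSF) wider than compressed chain extent")
        for k in self.knots:
            ok = any(
                bounds[n][0] <= k.birth_time < bounds[n][1]
                for n in ("compression", "hold") if n in bounds
            )
            if not ok:
                raise InvalidSpecError("knot birth times must fall in compression or hold")
            if k.L_k >= channel.contour_L / 4.0:
                raise InvalidSpecError("stored contour per knot must be < contour_L/4")

    def phase_bounds(self):
        t = 0.0
        out = []
        for name, dur in self.phases:
            out.append((name, (t, t + dur)))
            t += dur
        return out

    @property
    def total_time(self) -> float:
        return sum(d for _, d in self.phases)


@dataclass
class Kymograph:
    """Position x time intensity matrix of one event, with ground truth.

    ``data`` has shape (n_frames, n_pixels); ``truth`` is a JSON-serializable
    dict carrying phase boundaries, per-frame chain extents and per-knot
    tracks, sufficient to score detection exactly.
    """

    data: np.ndarray
    times: np.ndarray
    x: np.ndarray
    truth: dict

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def pixel_size(self) -> float:
        return float(self.x[1] - self.x[0])

    def to_tiff(self, path, sidecar: str | None = None) -> None:
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))
        meta = dict(self.truth)
        meta["times"] = self.times.tolist()
        meta["x"] = self.x.tolist()
        with open(sidecar or str(path) + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def from_tiff(cls, path, sidecar: str | None = None) -> "Kymograph":
        import tifffile

        data = tifffile.imread(path)
        with open(sidecar or str(path) + ".json") as fh:
            meta = json.load(fh)
        times = np.asarray(meta.pop("times"))
        x = np.asarray(meta.pop("x"))
        return cls(np.asarray(data, float), times, x, meta)


def _extent_at(spec: KymographSpec, t: float) -> float:
    """Chain extension (um) at absolute time t."""
    p = spec.profile
    r = p.R_c * p.r_o
    for name, (t0, t1) in spec.phase_bounds():
        if t0 <= t < t1 or (t == spec.total_time and t1 == t):
            if name == "equilibrium":
                return p.r_o
            if name == "compression":
                f = (t - t0) / (t1 - t0)
                return p.r_o + f * (r - p.r_o)
            if name == "hold":
                return r
            # release: exponential approach of extension toward r_o
            return p.r_o - (p.r_o - r) * np.exp(-(t - t0) / spec.tau_relax)
    return p.r_o


def _chain_profile(spec: KymographSpec, t: float, x: np.ndarray) -> np.ndarray:
    """Noiseless chain intensity at time t: box except during hold (ramp)."""
    p = spec.profile
    name = next(n for n, (t0, t1) in spec.phase_bounds()
                if t0 <= t < t1 or (t == spec.total_time and t1 == t))
    if name == "hold":
        r = p.R_c * p.r_o
        return ramp_psf_model(x, p.c_o * p.C_b, p.c_o * p.alpha / p.r_o, r, p.sigma_psf)
    e = _extent_at(spec, t)
    # box at current extension, amplitude conserving total intensity c_o * r_o
    return box_psf_model(x, 0.0, e, p.c_o * p.r_o / e, p.sigma_psf)


def gen_kymograph(spec: KymographSpec, channel: ChannelGeometry = T4_CHANNEL) -> Kymograph:
    """Render a compression-hold-release kymograph with programmed knots.

    Knots appear as localized Gaussian bright spots of PSF width whose excess
    integrated intensity equals c_o * L_k.  During hold they random-walk with
    reflection at the chain edges; during release they are advected with the
    affinely stretching chain, plus diffusion.  Fate scripts let a feature
    decay mid-chain (unknot event) or drift to the far chain end and unravel.
    """
    spec.validate(channel)
    rng = np.random.default_rng(spec.seed)
    p = spec.profile
    n_frames = int(round(spec.total_time / spec.frame_interval))
    times = np.arange(n_frames) * spec.frame_interval
    x = np.arange(spec.n_pixels) * spec.pixel_size - 2.0  # 2 um margin below barrier
    bounds = dict(spec.phase_bounds())
    release_start = bounds["release"][0]

    data = np.empty((n_frames, spec.n_pixels))
    pos = np.full(len(spec.knots), np.nan)      # current positions, um
    area = np.zeros(len(spec.knots))            # current excess areas
    tracks = [{"t": [], "x": [], "area": []} for _ in spec.knots]
    extents = []

    for fi, t in enumerate(times):
        e_prev = _extent_at(spec, max(t - spec.frame_interval, 0.0))
        e = _extent_at(spec, t)
        extents.append(e)
        # births
        for ki, k in enumerate(spec.knots):
            if np.isnan(pos[ki]) and t >= k.birth_time:
                pos[ki] = min(k.birth_position, e - spec.pixel_size)
                area[ki] = p.c_o * k.L_k
        # motion and fates
        in_release = t >= release_start
        stretch = e / e_prev if e_prev > 0 else 1.0
        for ki, k in enumerate(spec.knots):
            if np.isnan(pos[ki]) or area[ki] <= 0:
                continue
            if in_release:
                pos[ki] *= stretch  # advected with the relaxing chain
                t_rel = t - release_start
                if k.fate == "decay_mid_chain" and t_rel >= k.fate_time:
                    area[ki] *= np.exp(-spec.frame_interval / 0.6)
                    if area[ki] < 0.05 * p.c_o * k.L_k:
                        area[ki] = 0.0
                if k.fate == "unravel_at_end" and t_rel >= k.fate_time:
                    pos[ki] += 1.5 * spec.frame_interval * e / spec.tau_relax + 0.4
                    if pos[ki] > e - 1.0:
                        pos[ki] = e - 0.2
                        area[ki] *= np.exp(-spec.frame_interval / 0.4)
                        if area[ki] < 0.05 * p.c_o * k.L_k:
                            area[ki] = 0.0
            step = np.sqrt(2.0 * k.diffusivity * spec.frame_interval)
            pos[ki] += step * rng.standard_normal()
            # reflect at the evolving chain edges
            if pos[ki] < 0:
                pos[ki] = -pos[ki]
            if pos[ki] > e:
                pos[ki] = 2 * e - pos[ki]
            pos[ki] = np.clip(pos[ki], 0.0, e)
        # single-file no-passing: knots cannot cross in the channel, so
        # enforce the hard-core gap between neighbours after each step
        alive = [i for i in range(len(spec.knots))
                 if not np.isnan(pos[i]) and area[i] > 0]
        alive.sort(key=lambda i: pos[i])
        for a_prev, a_next in zip(alive, alive[1:]):
            if pos[a_next] < pos[a_prev] + spec.hardcore_gap:
                pos[a_next] = pos[a_prev] + spec.hardcore_gap
        for a_next, a_prev in zip(alive[::-1], alive[-2::-1]):
            if pos[a_next] > e:
                pos[a_next] = e
            if pos[a_prev] > pos[a_next] - spec.hardcore_gap:
                pos[a_prev] = max(pos[a_next] - spec.hardcore_gap, 0.0)
        # render
        frame = _chain_profile(spec, t, x)
        for ki in range(len(spec.knots)):
            if not np.isnan(pos[ki]) and area[ki] > 0:
                frame = frame + area[ki] * np.exp(
                    -0.5 * ((x - pos[ki]) / p.sigma_psf) ** 2
                ) / (p.sigma_psf * np.sqrt(2 * np.pi))
                tracks[ki]["t"].append(float(t))
                tracks[ki]["x"].append(float(pos[ki]))
                tracks[ki]["area"].append(float(area[ki]))
        data[fi] = _add_noise(frame, p.c_o, spec.noise_model, rng)

    truth = {
        "phases": [(n, b) for n, b in spec.phase_bounds()],
        "release_start": release_start,
        "extent": [float(v) for v in extents],
        "knots": [
            {
                "is_knot": k.is_knot,
                "fate": k.fate,
                "L_k": k.L_k,
                "track": tracks[ki],
            }
            for ki, k in enumerate(spec.knots)
        ],
        "m_true": int(sum(k.is_knot for k in spec.knots)),
        "c_o": p.c_o,
        "sigma_psf": p.sigma_psf,
        "barrier_pixel": float(np.argmin(np.abs(x))),
    }
    return Kymograph(data, times, x, truth)


def spec_to_json(spec, path) -> None:
    """Serialize a generator spec (TrueProfileSpec or KymographSpec) to JSON."""
    d = asdict(spec)
    d["__type__"] = type(spec).__name__
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, default=float)


def spec_from_json(path):
    """Load a generator spec written by :func:`spec_to_json`."""
    with open(path) as fh:
        d = json.load(fh)
    kind = d.pop("__type__")
    if kind == "TrueProfileSpec":
        return TrueProfileSpec(**d)
    if kind == "KymographSpec":
        d["profile"] = TrueProfileSpec(**d["profile"])
        d["knots"] = [KnotSpec(**k) for k in d["knots"]]
        d["phases"] = tuple((n, float(dur)) for n, dur in d["phases"])
        d["noise_model"] = tuple(d["noise_model"])
        return KymographSpec(**d)
    raise ValueError(f"unknown spec type {kind!r}")


def sample_event_spec(m: int, seed: int, C_b: float = 8.0, R_c: float = 0.2,
                      fates=None, min_separation: float = 0.5,
                      L_k_range=(1.0, 2.5), **kym_kw) -> KymographSpec:
    """Draw a random m-knot compression event.

    Knot positions are uniform over the compressed extent subject to a
    hard-core minimum separation (knots cannot pass each other in the
    channel, so they never co-localize closer than about twice a gyration
    radius); stored contours are uniform on ``L_k_range``.  ``fates`` lists
    per-knot fate scripts (default all persist).
    """
    rng = np.random.default_rng(seed)
    prof = TrueProfileSpec.compressed(C_b=C_b, R_c=R_c)
    r = prof.R_c * prof.r_o
    pos = np.array([])
    if m > 0:
        for _ in range(10_000):
            pos = np.sort(rng.uniform(0.1, r - 0.3, m))
            if m < 2 or np.min(np.diff(pos)) > min_separation:
                break
        else:
            raise InvalidSpecError("cannot place knots with requested separation")
    knots = []
    for i in range(m):
        fate = fates[i] if fates else "persist"
        knots.append(KnotSpec(
            birth_time=6.5 + rng.uniform(0, 2.0),
            birth_position=float(pos[i]),
            L_k=float(rng.uniform(*L_k_range)),
            fate=fate,
            fate_time=0.3 if fate == "decay_mid_chain" else 6.0,
        ))
    return KymographSpec(profile=prof, knots=knots, seed=seed, **kym_kw)


# ---------------------------------------------------------------------------
# knot position samples
# ---------------------------------------------------------------------------


def _trunc_exp_sample(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Exponential with decay length ``lam`` truncated to [0, 1], by inverse CDF."""
    u = rng.random(size)
    if np.isinf(lam):
        return u
    z = 1.0 - np.exp(-1.0 / lam)
    return -lam * np.log1p(-u * z)


def gen_knot_positions(lambda_decay: float, gap: float = 0.0, m: int = 1,
                       n_events: int = 100, seed: int = 0) -> np.ndarray:
    """Knot positions from truncated exponentials with a hard-core gap.

    For m = 1 returns an (n_events,) array of positions in [0, 1] (units of
    the relaxed extension).  For m = 2 returns an (n_events, 2) array of
    (lower, upper) pairs drawn from the product of two truncated exponentials
    conditioned on upper > lower + gap (rejection sampling).
    """
    if m not in (1, 2):
        raise ValueError("m must be 1 or 2")
    if lambda_decay <= 0:
        raise ValueError("lambda_decay must be positive")
    if gap < 0:
        raise ValueError("gap must be nonnegative")
    rng = np.random.default_rng(seed)
    if m == 1:
        return _trunc_exp_sample(lambda_decay, n_events, rng)
    if gap >= 1.0:
        raise InvalidSpecError("gap >= 1 leaves no room for two knots on [0, 1]")
    out = np.empty((n_events, 2))
    got = 0
    while got < n_events:
        batch = max(2 * (n_events - got), 64)
        a = _trunc_exp_sample(lambda_decay, batch, rng)
        b = _trunc_exp_sample(lambda_decay, batch, rng)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        keep = hi - lo > gap
        take = min(int(keep.sum()), n_events - got)
        out[got:got + take, 0] = lo[keep][:take]
        out[got:got + take, 1] = hi[keep][:take]
        got += take
    return out
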