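"""Synthetic herd generator.

Each cow's behaviour is a continuous-time semi-Markov chain over five zone
states (FEED, CUBICLE_1..3, PASSAGE) with exponential dwell times. Within a
zone visit the position follows a reflected random walk confined to a
wander box inside the zone rectangle; isotropic Gaussian sensor noise is
added on top. Samples falling in the daily milking windows are deleted
(the cows are out of the barn). Health covariates shift the state
probabilities (lame cows feed less, rest more), the preferred x position
(parity pushes cows toward the parlour side) and the wander radius (shrunk
for lame cows, trending with days in milk with an opposite sign under
lameness).

All randomness derives from one integer seed; per-cow streams use
independent child generators keyed by (seed, cow index) so output is
reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import BarnGeometry, ConfigurationError, MilkingWindow, Rect
from .prep import Trajectory

#: behavioural states and the zone each occupies
STATES = ("FEED", "CUBICLE_1", "CUBICLE_2", "CUBICLE_3", "PASSAGE")
STATE_ZONE = {
    "FEED": "F",
    "CUBICLE_1": "C1",
    "CUBICLE_2": "C2",
    "CUBICLE_3": "C3",
    "PASSAGE": "P",
}

_EPOCH = pd.Timestamp("2021-03-01 00:00:00")


@dataclass(frozen=True)
class CowMetadata:
    """Per-animal covariates: lameness, parity, days in milk, daily yield."""

    cow_id: str
    lame: int
    parity: int
    dim: int
    yield_lpd: float = math.nan

    def __post_init__(self) -> None:
        if self.lame not in (0, 1):
            raise ValueError("lame must be 0 or 1")
        if self.parity < 1:
            raise ValueError("parity must be >= 1")
        if self.dim < 0:
            raise ValueError("days in milk must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for the synthetic herd; defaults mimic the 20-cow study."""

    n_cows: int = 20
    n_days: int = 5
    sample_rate: float = 0.125  # Hz
    milking: tuple[MilkingWindow, ...] | None = None  # None -> geometry schedule

    # semi-Markov behaviour model
    dwell_min: dict[str, float] = field(
        default_factory=lambda: {
            "FEED": 14.0,
            "CUBICLE_1": 16.0,
            "CUBICLE_2": 16.0,
            "CUBICLE_3": 16.0,
            "PASSAGE": 10.0,
        }
    )
    base_probs: dict[str, float] = field(
        default_factory=lambda: {
            "FEED": 0.32,
            "CUBICLE_1": 0.16,
            "CUBICLE_2": 0.16,
            "CUBICLE_3": 0.16,
            "PASSAGE": 0.20,
        }
    )
    prob_jitter_sd: float = 0.04  # per-cow heterogeneity on state probs
    day_jitter_sd: float = 0.03  # day-to-day redraw of each cow's state probs
    passage_jitter_sd: float = 0.05  # extra per-cow jitter on the PASSAGE prob
    radius_jitter_sd: float = 0.06  # per-cow lognormal sd on wander radius
    y_anchor_jitter_sd: float = 1.2  # metres, per-cow preferred-y offset
    cubicle_pref_conc: float = 8.0  # Dirichlet concentration of block preference
    step_jitter_sd: float = 0.35  # per-cow lognormal sd on walk step size
    hotspot_count: float = 3.0  # mean preferred spots per zone (per-cow Poisson)
    hotspot_share_logit_mean: float = 0.8  # mean of the hotspot-preference logit
    hotspot_share_logit_sd: float = 0.5  # per-cow spread of hotspot preference
    hotspot_day_conc: float = 1.5  # Dirichlet concentration of daily spot weights
    hotspot_extent: float = 5.0  # metres, half-width of the preferred-spot region
    hotspot_step_frac: float = 0.25  # resting visits wander far less
    day_drift_sd: float = 1.2  # metres, typical day-to-day range-centre drift

    # covariate effects (signs chosen to match the observed directions)
    lame_feed_shift: float = -0.14  # additive on FEED probability
    lame_cubicle_shift: float = 0.005  # additive, split over the cubicle states
    lame_radius_mult: float = 0.60  # multiplier on wander radius (< 1)
    parity_x_shift: float = 1.5  # metres of preferred-x shift per parity unit
    base_x_target: float = 18.0
    dim_radius_slope: float = 0.002  # per day in milk, on the radius factor
    dim_center: float = 125.0
    lame_dim_sign: float = -1.0  # lameness flips the days-in-milk trend

    # movement and measurement
    wander_radius: float = 8.0  # metres, half-width of the wander box
    step_sd: float = 0.30  # metres per 8 s step
    noise_sd: float = 1.0  # isotropic sensor noise, metres

    # metadata sampling
    lame_fraction: float = 0.5
    parity_range: tuple[int, int] = (1, 6)
    dim_range: tuple[int, int] = (44, 220)
    yield_mean: float = 42.5
    yield_sd: float = 6.88

    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2 (site fidelity needs 2 days)")
        if self.n_cows < 1:
            raise ValueError("n_cows must be >= 1")
        if set(self.dwell_min) != set(STATES) or set(self.base_probs) != set(STATES):
            raise ValueError(f"dwell_min and base_probs must cover states {STATES}")
        if any(v <= 0 for v in self.dwell_min.values()):
            raise ValueError("dwell means must be positive")
        p = np.array([self.base_probs[s] for s in STATES])
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("base state probabilities must form a simplex")

    def with_null_effects(self) -> "SimulationParams":
        """Copy with every covariate effect switched off."""
        return replace(
            self,
            lame_feed_shift=0.0,
            lame_cubicle_shift=0.0,
            lame_radius_mult=1.0,
            parity_x_shift=0.0,
            dim_radius_slope=0.0,
        )


@dataclass(frozen=True)
class EffectProfile:
    """Per-cow behavioural profile after applying covariate effects."""

    state_probs: dict[str, float]
    wander_radius: float
    mean_x_target: float


def _renormalize(probs: np.ndarray) -> np.ndarray:
    clamped = np.clip(probs, 0.0, 1.0)
    s = clamped.sum()
    if s <= 0:
        raise ValueError("state probabilities collapsed to zero after clamping")
    return clamped / s


def effect_profile(metadata: CowMetadata, params: SimulationParams) -> EffectProfile:
    """Deterministic covariate-to-behaviour map.

    FEED probability decreases with lameness; the preferred x position is
    ``base_x_target + parity_x_shift * parity``; the wander radius carries
    the lameness multiplier and a days-in-milk trend whose sign flips under
    lameness. Probabilities are clamped to [0, 1] and renormalized.
    """
    L = metadata.lame
    probs = np.array([params.base_probs[s] for s in STATES])
    probs[STATES.index("FEED")] += params.lame_feed_shift * L
    for cub in ("CUBICLE_1", "CUBICLE_2", "CUBICLE_3"):
        probs[STATES.index(cub)] += params.lame_cubicle_shift / 3.0 * L
    probs = _renormalize(probs)

    slope = params.dim_radius_slope * (params.lame_dim_sign if L else 1.0)
    factor = float(np.clip(1.0 + slope * (metadata.dim - params.dim_center), 0.2, 3.0))
    radius = params.wander_radius * (params.lame_radius_mult if L else 1.0) * factor

    x_target = params.base_x_target + params.parity_x_shift * metadata.parity
    return EffectProfile(
        state_probs=dict(zip(STATES, probs.tolist())),
        wander_radius=radius,
        mean_x_target=x_target,
    )


def nominal_sample_slots(params: SimulationParams) -> int:
    """Theoretical per-cow sample count for continuous 24 h recording."""
    return int(round(params.sample_rate * 86400.0)) * params.n_days


def _fold(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect a free walk into [lo, hi] (triangle-wave folding)."""
    w = hi - lo
    if w <= 0:
        return np.full_like(values, lo)
    m = np.mod(values - lo, 2.0 * w)
    return lo + (w - np.abs(m - w))


def _wander_box(
    zone: Rect, radius: float, x_target: float, y_offset: float = 0.0
) -> Rect:
    ax = min(max(x_target, zone.xmin), zone.xmax)
    ay = min(max(0.5 * (zone.ymin + zone.ymax) + y_offset, zone.ymin), zone.ymax)
    lox, hix = max(zone.xmin, ax - radius), min(zone.xmax, ax + radius)
    loy, hiy = max(zone.ymin, ay - radius), min(zone.ymax, ay + radius)
    if hix <= lox:  # target pinned at a zone edge
        lox, hix = ax - 1e-6, ax + 1e-6
        lox, hix = max(zone.xmin, lox), min(zone.xmax, hix)
    return Rect(lox, max(hix, lox + 1e-9), loy, max(hiy, loy + 1e-9))


def _simulate_cow(
    meta: CowMetadata,
    profile: EffectProfile,
    jitter: np.ndarray,
    params: SimulationParams,
    geometry: BarnGeometry,
    rng: np.random.Generator,
    *,
    add_noise: bool = True,
) -> pd.DataFrame:
    probs = _renormalize(
        np.array([profile.state_probs[s] for s in STATES]) + jitter
    )
    # per-cow preference over the three cubicle blocks: redistributes the
    # cubicle probability mass without changing its total
    cub_idx = [STATES.index(c) for c in ("CUBICLE_1", "CUBICLE_2", "CUBICLE_3")]
    if params.cubicle_pref_conc > 0:
        w = rng.dirichlet([params.cubicle_pref_conc] * 3)
        probs[cub_idx] = probs[cub_idx].sum() * w
    dwell_s = np.array([params.dwell_min[s] * 60.0 for s in STATES])
    step_sd = params.step_sd * (
        float(np.exp(rng.normal(0.0, params.step_jitter_sd)))
        if params.step_jitter_sd > 0
        else 1.0
    )
    y_offset = (
        rng.normal(0.0, params.y_anchor_jitter_sd)
        if params.y_anchor_jitter_sd > 0
        else 0.0
    )

    dt = 1.0 / params.sample_rate
    n_slots = nominal_sample_slots(params)
    t = np.arange(n_slots) * dt

    # draw visits day by day (behaviour redrawn daily around the cow's own
    # profile) until they cover the study window; visits truncate at
    # midnight so each day is governed by its own state probabilities
    states: list[int] = []
    dwells: list[float] = []
    visit_day: list[int] = []
    for day in range(params.n_days):
        day_probs = probs
        if params.day_jitter_sd > 0:
            day_probs = _renormalize(
                probs + rng.normal(0.0, params.day_jitter_sd, len(STATES))
            )
        covered = 0.0
        while covered < 86400.0:
            s = int(rng.choice(len(STATES), p=day_probs))
            d = float(rng.exponential(dwell_s[s]))
            d = min(d, 86400.0 - covered)
            states.append(s)
            dwells.append(d)
            visit_day.append(day)
            covered += d
    edges = np.cumsum(dwells)
    visit_of_sample = np.searchsorted(edges, t, side="right")

    # per-cow preferred spots within each zone's wander box (stable across
    # days): visits enter at a preferred spot with probability
    # ``hotspot_share``, otherwise anywhere in the box, so the core of the
    # distribution concentrates independently of the box extent
    boxes = {}
    hotspots = {}
    for si, state in enumerate(STATES):
        zone = geometry.zones[STATE_ZONE[state]]
        box = _wander_box(zone, profile.wander_radius, profile.mean_x_target, y_offset)
        boxes[si] = box
        k = 1 + int(rng.poisson(max(params.hotspot_count - 1.0, 0.0)))
        # preferred spots live in a fixed-size region around the box centre,
        # so the core of the distribution does not scale with wander radius
        hcx, hcy = 0.5 * (box.xmin + box.xmax), 0.5 * (box.ymin + box.ymax)
        hx_lo = max(box.xmin, hcx - params.hotspot_extent)
        hx_hi = min(box.xmax, hcx + params.hotspot_extent)
        hy_lo = max(box.ymin, hcy - params.hotspot_extent)
        hy_hi = min(box.ymax, hcy + params.hotspot_extent)
        hotspots[si] = np.column_stack(
            [rng.uniform(hx_lo, hx_hi, k), rng.uniform(hy_lo, hy_hi, k)]
        )
    # some cows shift their whole range slightly from day to day; the
    # per-cow drift magnitude is itself heterogeneous
    drift_scale = params.day_drift_sd * float(np.exp(rng.normal(0.0, 0.5)))
    day_shift = {
        day: (rng.normal(0.0, drift_scale), rng.normal(0.0, drift_scale))
        for day in range(params.n_days)
    }
    # hotspot preference weights are redrawn each day: real day-to-day
    # variation in where each cow concentrates, shared by every cow
    day_weights = {
        (day, si): rng.dirichlet([params.hotspot_day_conc] * len(hotspots[si]))
        for day in range(params.n_days)
        for si in range(len(STATES))
    }
    hotspot_share = (
        float(
            1.0
            / (
                1.0
                + np.exp(
                    -rng.normal(
                        params.hotspot_share_logit_mean,
                        params.hotspot_share_logit_sd,
                    )
                )
            )
        )
        if params.hotspot_share_logit_sd > 0
        else 0.0
    )

    x = np.empty(n_slots)
    y = np.empty(n_slots)
    start = 0
    for v in range(len(states)):
        stop = int(np.searchsorted(visit_of_sample, v, side="right"))
        if stop <= start:
            continue
        n = stop - start
        si = states[v]
        box = boxes[si]
        zone = geometry.zones[STATE_ZONE[STATES[si]]]
        ddx, ddy = day_shift[visit_day[v]]
        # translate the wander box by the day's drift, kept inside the zone
        ddx = min(max(ddx, zone.xmin - box.xmin), zone.xmax - box.xmax)
        ddy = min(max(ddy, zone.ymin - box.ymin), zone.ymax - box.ymax)
        box = Rect(box.xmin + ddx, box.xmax + ddx, box.ymin + ddy, box.ymax + ddy)
        if rng.uniform() < hotspot_share:
            j = int(rng.choice(len(hotspots[si]), p=day_weights[(visit_day[v], si)]))
            hx, hy = hotspots[si][j]
            cx = float(np.clip(hx + rng.normal(0.0, 0.8), box.xmin, box.xmax))
            cy = float(np.clip(hy + rng.normal(0.0, 0.8), box.ymin, box.ymax))
            visit_step = step_sd * params.hotspot_step_frac
        else:
            cx = rng.uniform(box.xmin, box.xmax)
            cy = rng.uniform(box.ymin, box.ymax)
            visit_step = step_sd
        walk_x = cx + np.cumsum(rng.normal(0.0, visit_step, n))
        walk_y = cy + np.cumsum(rng.normal(0.0, visit_step, n))
        x[start:stop] = _fold(walk_x, box.xmin, box.xmax)
        y[start:stop] = _fold(walk_y, box.ymin, box.ymax)
        start = stop

    if add_noise and params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n_slots)
        y = y + rng.normal(0.0, params.noise_sd, n_slots)

    # delete samples inside milking windows (cows are out of the barn)
    windows = params.milking if params.milking is not None else geometry.milking
    sod = np.mod(t, 86400.0)
    absent = np.zeros(n_slots, dtype=bool)
    for w in windows:
        absent |= (sod >= w.start_s) & (sod < w.end_s)

    ts = _EPOCH + pd.to_timedelta(t[~absent], unit="s")
    return pd.DataFrame({"timestamp": ts, "x": x[~absent], "y": y[~absent]})


def generate_metadata(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> list[CowMetadata]:
    """Draw per-cow covariates with a fixed lame/non-lame split."""
    if rng is None:
        rng = np.random.default_rng([params.seed, 0xBEEF])
    n = params.n_cows
    n_lame = int(round(n * params.lame_fraction))
    lame = np.zeros(n, dtype=int)
    lame[:n_lame] = 1
    lame = rng.permutation(lame)
    p_lo, p_hi = params.parity_range
    d_lo, d_hi = params.dim_range
    out = []
    for i in range(n):
        out.append(
            CowMetadata(
                cow_id=f"{1001 + i}",
                lame=int(lame[i]),
                parity=int(rng.integers(p_lo, p_hi + 1)),
                dim=int(rng.integers(d_lo, d_hi + 1)),
                yield_lpd=float(
                    np.clip(rng.normal(params.yield_mean, params.yield_sd), 20.0, 65.0)
                ),
            )
        )
    return out


def generate_herd(
    params: SimulationParams,
    geometry: BarnGeometry | None = None,
    *,
    add_noise: bool = True,
) -> tuple[list[Trajectory], list[CowMetadata]]:
    """Generate one trajectory per cow plus metadata; deterministic per seed."""
    if geometry is None:
        geometry = BarnGeometry()
    for state, zone in STATE_ZONE.items():
        if zone not in geometry.zones:
            raise ConfigurationError(f"zone {zone!r} (state {state}) missing")
    metadata = generate_metadata(params)
    trajectories = []
    for i, meta in enumerate(metadata):
        rng = np.random.default_rng([params.seed, 1, i])
        jitter = (
            rng.normal(0.0, params.prob_jitter_sd, len(STATES))
            if params.prob_jitter_sd > 0
            else np.zeros(len(STATES))
        )
        # extra passage-occupancy heterogeneity decouples the cubicle-time
        # share from being a pure mirror of the feeding-time share
        jitter[STATES.index("PASSAGE")] += rng.normal(0.0, params.passage_jitter_sd)
        profile = effect_profile(meta, params)
        if params.radius_jitter_sd > 0:
            profile = EffectProfile(
                profile.state_probs,
                profile.wander_radius
                * float(np.exp(rng.normal(0.0, params.radius_jitter_sd))),
                profile.mean_x_target,
            )
        df = _simulate_cow(
            meta, profile, jitter, params, geometry, rng, add_noise=add_noise
        )
        trajectories.append(Trajectory(meta.cow_id, df))
    return trajectories, metadata


def write_metadata(metadata: list[CowMetadata], path) -> None:
    pd.DataFrame(
        [
            {
                "cow_id": m.cow_id,
                "lame": m.lame,
                "parity": m.parity,
                "dim": m.dim,
                "yield": m.yield_lpd,
            }
            for m in metadata
        ]
    ).to_csv(path, index=False, float_format="%.2f")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cow_id": str})
    required = {"cow_id", "lame", "parity", "dim"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing column(s): {sorted(missing)}")
    return df
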