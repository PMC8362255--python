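"""Synthetic study generator with known ground truth.

Every input of the analysis pipeline can be generated here from a panel
of strain profiles sharing a latent muscle-health variable ``health`` in
[0, 1]: per-frame maximal force traces (right-skewed lognormal), whole
burrowing time courses (Bernoulli success x exponential arrival),
ordinal sarcomere site scores (latent Gaussian rounded to 0.5 steps),
and rendered micropillar arena frames for the tracker.  Because the
same profile drives strength, burrowing, and structure, downstream
estimates can be checked against exact ground truth: rank order of
estimated muscle function scores should recover the rank order of
health, and the regression of function on disorganization should have a
negative slope.

All generators are pure functions of (parameters, seed); identical
seeds give identical outputs, and no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import stats

from .pillar_tracking import DeflectionFrame, PillarArena
from .scoring import MDSRecord, mds
from .strength_assay import ForceTrace, StrengthRecord, f95
from .burrowing_assay import BurrowTrial

#: Default trace length: one minute of video at 5 frames per second.
DEFAULT_N_FRAMES = 300
#: Default burrowing protocol: scored every 15 min for 2 h.
DEFAULT_INTERVAL_MIN = 15.0
DEFAULT_TOTAL_MIN = 120.0

# Background / foreground gray levels of rendered frames (8-bit).
_BG_LEVEL = 230.0
_DISK_DEPTH = 180.0


@dataclass(frozen=True)
class StrainProfile:
    """Generative parameters for one strain.

    ``health`` is the shared latent muscle-health scalar; the remaining
    fields parameterize the three assay generators.  ``strength_scale``
    is the mean per-frame maximal force (uN), ``burrow_rate`` the mean
    surface-arrival rate (1/min) of worms able to reach the surface,
    ``burrow_success`` the asymptotic fraction able to reach it, and
    ``site_bias`` the five mean disorganization levels in [0, 3].
    """

    name: str
    health: float
    strength_scale: float
    strength_cv: float
    diameter_mean: float
    diameter_cv: float
    burrow_rate: float
    burrow_success: float
    site_bias: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.health <= 1.0:
            raise ValueError("health must lie in [0, 1]")
        if self.strength_scale <= 0:
            raise ValueError("strength_scale must be positive")
        if self.strength_cv < 0 or self.diameter_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if not 0.0 <= self.burrow_success <= 1.0:
            raise ValueError("burrow_success must lie in [0, 1]")
        if self.burrow_rate < 0:
            raise ValueError("burrow_rate must be >= 0")
        if len(self.site_bias) != 5 or any(
                not 0.0 <= b <= 3.0 for b in self.site_bias):
            raise ValueError("site_bias must be 5 values in [0, 3]")


@dataclass
class GroundTruth:
    """Per-strain true values underlying one simulated study."""

    seed: int
    f95: dict[str, float] = field(default_factory=dict)
    endpoint_fraction: dict[str, float] = field(default_factory=dict)
    mds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "f95": self.f95,
                       "endpoint_fraction": self.endpoint_fraction,
                       "mds": self.mds}, fh, indent=2)


def _lognormal_params(scale: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with given mean and coefficient of variation."""
    sigma2 = np.log1p(cv**2)
    return np.log(scale) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_force_trace(
    profile: StrainProfile,
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int = 0,
    worm_id: str = "worm-0",
    frame_rate: float = 5.0,
) -> ForceTrace:
    """Draw a per-frame maximal-force trace.

    Frames are i.i.d. lognormal with mean ``strength_scale`` and
    coefficient of variation ``strength_cv`` (a zero CV yields a
    constant trace) — positive and right-skewed, like observed maximal
    pillar force series.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if profile.strength_cv == 0:
        forces = np.full(n_frames, profile.strength_scale, dtype=float)
    else:
        mu, sigma = _lognormal_params(profile.strength_scale,
                                      profile.strength_cv)
        forces = rng.lognormal(mean=mu, sigma=sigma, size=n_frames)
    return ForceTrace(worm_id=worm_id, strain=profile.name, forces=forces,
                      frame_rate=frame_rate)


def expected_f95(profile: StrainProfile) -> float:
    """Analytic 95th percentile of the per-frame force distribution (uN)."""
    if profile.strength_cv == 0:
        return profile.strength_scale
    mu, sigma = _lognormal_params(profile.strength_scale, profile.strength_cv)
    return float(np.exp(mu + stats.norm.ppf(0.95) * sigma))


def simulate_diameter(profile: StrainProfile, seed: int = 0) -> float:
    """Draw a body diameter (um), lognormal around ``diameter_mean``."""
    rng = np.random.default_rng(seed)
    if profile.diameter_cv == 0:
        return profile.diameter_mean
    mu, sigma = _lognormal_params(profile.diameter_mean, profile.diameter_cv)
    return float(rng.lognormal(mean=mu, sigma=sigma))


def simulate_burrow_trial(
    profile: StrainProfile,
    n_worms: int = 30,
    interval_min: float = DEFAULT_INTERVAL_MIN,
    total_min: float = DEFAULT_TOTAL_MIN,
    seed: int = 0,
    replicate: int = 0,
) -> BurrowTrial:
    """Simulate one burrowing well.

    Each worm independently succeeds with probability ``burrow_success``;
    succeeders draw an exponential arrival time with rate
    ``burrow_rate`` (1/min).  Counts at each scoring interval are the
    number of arrivals at or before that time — non-decreasing by
    construction.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if interval_min <= 0 or total_min <= 0:
        raise ValueError("durations must be positive")
    n_intervals = total_min / interval_min
    if not np.isclose(n_intervals, round(n_intervals)):
        raise ValueError("total_min must be divisible by interval_min")

    rng = np.random.default_rng(seed)
    succeeds = rng.random(n_worms) < profile.burrow_success
    n_succ = int(succeeds.sum())
    if profile.burrow_rate > 0 and np.isfinite(profile.burrow_rate):
        arrivals = rng.exponential(scale=1.0 / profile.burrow_rate,
                                   size=n_succ)
    elif np.isinf(profile.burrow_rate):
        arrivals = np.zeros(n_succ)
    else:  # rate 0: succeeders never arrive within any finite window
        arrivals = np.full(n_succ, np.inf)

    times = interval_min * np.arange(1, int(round(n_intervals)) + 1)
    counts = np.array([(arrivals <= t).sum() for t in times], dtype=float)
    return BurrowTrial(strain=profile.name, replicate=replicate,
                       n_total=n_worms, times=times, counts=counts)


def expected_endpoint_fraction(
    profile: StrainProfile, t: float = DEFAULT_TOTAL_MIN
) -> float:
    """True fraction at the surface by time t: success * (1 - exp(-rate t))."""
    if np.isinf(profile.burrow_rate):
        return profile.burrow_success
    return profile.burrow_success * (1.0 - np.exp(-profile.burrow_rate * t))


def simulate_site_scores(
    profile: StrainProfile, noise_sd: float = 0.25, seed: int = 0
) -> MDSRecord:
    """Draw the five ordinal site scores.

    Gaussian noise is added to each site's mean level on the latent
    scale, then rounded to the nearest 0.5 and clamped to [0, 3] — the
    half-point granularity observed in real by-eye scoring.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    latent = np.asarray(profile.site_bias, dtype=float)
    latent = latent + rng.normal(0.0, noise_sd, size=latent.size)
    scores = np.clip(np.round(latent * 2.0) / 2.0, 0.0, 3.0)
    return mds(tuple(scores), strain=profile.name)


def true_mds(profile: StrainProfile) -> float:
    """Noise-free MDS implied by the profile's site biases."""
    scores = np.clip(np.round(np.asarray(profile.site_bias) * 2.0) / 2.0,
                     0.0, 3.0)
    return float(scores.sum())


# ---------------------------------------------------------------------------
# Arena frame rendering


def render_arena_frame(
    arena: PillarArena,
    deflections: DeflectionFrame | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render one brightfield-like frame of the pillar arena.

    Pillars are dark anti-aliased disks at rest-plus-deflection
    positions on a bright background; additive Gaussian noise with
    standard deviation ``noise_sd`` (gray levels) is applied before
    quantization to 8-bit.  Deflections beyond half the lattice pitch
    are refused: the nearest-lattice tracker could no longer identify
    such a pillar unambiguously.
    """
    if isinstance(deflections, DeflectionFrame):
        dxy = deflections.deflections
    else:
        dxy = np.asarray(deflections, dtype=float)
    if dxy.shape != (arena.lattice_rows, arena.lattice_cols, 2):
        raise ValueError("deflections must be (rows, cols, 2) in um")
    mags = np.hypot(dxy[..., 0], dxy[..., 1])
    if np.any(mags > 0.5 * arena.pitch):
        raise ValueError("deflection exceeds half the lattice pitch; "
                         "tracking would be ambiguous by construction")

    h, w = arena.image_shape
    img = np.full((h, w), _BG_LEVEL, dtype=float)
    centers = arena.rest_lattice_px() + dxy / arena.pixel_size
    radius = arena.pillar_radius_px
    pad = int(np.ceil(radius)) + 2
    for r in range(arena.lattice_rows):
        for c in range(arena.lattice_cols):
            cx, cy = centers[r, c]
            x0, x1 = int(np.floor(cx)) - pad, int(np.ceil(cx)) + pad + 1
            y0, y1 = int(np.floor(cy)) - pad, int(np.ceil(cy)) + pad + 1
            if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
                raise ValueError("deflected pillar lies outside image bounds")
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, w), min(y1, h)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(xx - cx, yy - cy)
            coverage = np.clip(radius - dist + 0.5, 0.0, 1.0)
            img[y0:y1, x0:x1] -= _DISK_DEPTH * coverage
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def random_deflection_frame(
    arena: PillarArena,
    n_active: int = 5,
    max_magnitude: float | None = None,
    seed: int = 0,
    frame_index: int = 0,
) -> DeflectionFrame:
    """Random ground-truth deflection field for round-trip tests.

    ``n_active`` pillars get a deflection with uniform direction and
    magnitude uniform in (noise floor, ``max_magnitude``]; the default
    ceiling is a quarter pitch, safely inside the tracker's
    unambiguous range.
    """
    if max_magnitude is None:
        max_magnitude = arena.pitch / 4.0
    rng = np.random.default_rng(seed)
    n_sites = arena.lattice_rows * arena.lattice_cols
    n_active = min(n_active, n_sites)
    chosen = rng.choice(n_sites, size=n_active, replace=False)
    dxy = np.zeros((arena.lattice_rows, arena.lattice_cols, 2))
    mags = rng.uniform(2.0 * arena.noise_floor_um, max_magnitude,
                       size=n_active)
    angles = rng.uniform(0, 2 * np.pi, size=n_active)
    for site, mag, ang in zip(chosen, mags, angles):
        r, c = divmod(int(site), arena.lattice_cols)
        dxy[r, c] = mag * np.array([np.cos(ang), np.sin(ang)])
    contact = np.hypot(dxy[..., 0], dxy[..., 1]) >= arena.noise_floor_um
    return DeflectionFrame(frame_index=frame_index, deflections=dxy,
                           contact_mask=contact)


# ---------------------------------------------------------------------------
# Strain panels and whole-study simulation


def default_strain_panel(n_mutants: int = 20, wt_label: str = "wild_type"
                         ) -> list[StrainProfile]:
    """Wild type plus ``n_mutants`` strains spanning the health range.

    Health maps monotonically to every phenotype: strength scale falls
    to ~40% of wild type for the sickest strain, burrowing endpoint
    falls from ~100% to ~7% (success and arrival rate both decline),
    and site disorganization rises toward the 0-3 ceiling with slightly
    different severity per site.  Diameters shrink mildly with illness.
    """
    site_weights = np.array([1.0, 0.9, 0.8, 1.1, 1.0])

    def profile(name: str, health: float) -> StrainProfile:
        return StrainProfile(
            name=name,
            health=health,
            strength_scale=3.0 * (0.4 + 0.6 * health),
            strength_cv=0.3,
            diameter_mean=55.0 + 10.0 * health,
            diameter_cv=0.05,
            burrow_rate=0.01 + 0.06 * health,
            burrow_success=0.1 + 0.9 * health,
            site_bias=tuple(float(b) for b in
                            np.clip(3.0 * (1.0 - health) * site_weights,
                                    0.0, 3.0)),
        )

    panel = [profile(wt_label, 1.0)]
    healths = np.linspace(0.05, 0.95, n_mutants)
    for i, h in enumerate(healths):
        panel.append(profile(f"mut-{i:02d}", float(h)))
    return panel


@dataclass
class StudyData:
    """All simulated inputs for one study, plus their ground truth."""

    profiles: list[StrainProfile]
    strength_records: list[StrengthRecord]
    force_traces: list[ForceTrace]
    burrow_trials: list[BurrowTrial]
    mds_records: list[MDSRecord]
    ground_truth: GroundTruth


def simulate_study(
    profiles: list[StrainProfile],
    n_worms_strength: int = 25,
    n_frames: int = DEFAULT_N_FRAMES,
    burrow_replicates: int = 3,
    n_worms_burrow: int = 30,
    site_noise_sd: float = 0.25,
    seed: int = 0,
) -> StudyData:
    """Simulate the complete three-assay study for a strain panel.

    Defaults mirror a realistic study: ~25 animals per strain with
    one-minute force videos, three burrowing wells of 30 worms scored
    every 15 min for 2 h, and one structural score set per strain.
    Ground-truth f95 is the mean of the per-worm f95 values computed by
    the strength analyzer on the generated traces, so generator and
    analyzer agree by construction.
    """
    root = np.random.SeedSequence(seed)
    truth = GroundTruth(seed=seed)
    strength_records: list[StrengthRecord] = []
    force_traces: list[ForceTrace] = []
    burrow_trials: list[BurrowTrial] = []
    mds_records: list[MDSRecord] = []

    for profile, strain_ss in zip(profiles, root.spawn(len(profiles))):
        child_seeds = strain_ss.generate_state(
            2 * n_worms_strength + burrow_replicates + 1) % (2**31)
        worm_f95 = []
        for w in range(n_worms_strength):
            trace = simulate_force_trace(
                profile, n_frames=n_frames, seed=int(child_seeds[2 * w]),
                worm_id=f"{profile.name}-w{w:03d}")
            diameter = simulate_diameter(profile,
                                         seed=int(child_seeds[2 * w + 1]))
            record = StrengthRecord.from_trace(trace, diameter)
            force_traces.append(trace)
            strength_records.append(record)
            worm_f95.append(record.f95)
        for rep in range(burrow_replicates):
            burrow_trials.append(simulate_burrow_trial(
                profile, n_worms=n_worms_burrow,
                seed=int(child_seeds[2 * n_worms_strength + rep]),
                replicate=rep))
        mds_records.append(simulate_site_scores(
            profile, noise_sd=site_noise_sd,
            seed=int(child_seeds[-1])))

        truth.f95[profile.name] = float(np.mean(worm_f95))
        truth.endpoint_fraction[profile.name] = expected_endpoint_fraction(profile)
        truth.mds[profile.name] = true_mds(profile)

    return StudyData(profiles=list(profiles),
                     strength_records=strength_records,
                     force_traces=force_traces,
                     burrow_trials=burrow_trials,
                     mds_records=mds_records,
                     ground_truth=truth)


# ---------------------------------------------------------------------------
# File interfaces


def write_tiff_stack(frames: list[np.ndarray], path) -> None:
    """Write rendered frames as an 8-bit grayscale TIFF stack."""
    tifffile.imwrite(path, np.stack(frames).astype(np.uint8),
                     photometric="minisblack")


def centroid_table(
    arena: PillarArena, frames: list[DeflectionFrame]
) -> pd.DataFrame:
    """Ground-truth centroid table (frame, pillar_row, pillar_col, x_px, y_px)."""
    rest = arena.rest_lattice_px()
    rows = []
    for fr in frames:
        pos = rest + fr.deflections / arena.pixel_size
        for r in range(arena.lattice_rows):
            for c in range(arena.lattice_cols):
                rows.append({"frame": fr.frame_index, "pillar_row": r,
                             "pillar_col": c, "x_px": pos[r, c, 0],
                             "y_px": pos[r, c, 1]})
    return pd.DataFrame(rows)


def write_centroid_csv(arena: PillarArena, frames: list[DeflectionFrame],
                       path) -> None:
    centroid_table(arena, frames).to_csv(path, index=False)


def write_site_scores_csv(records: list[MDSRecord], path) -> None:
    from .scoring import SITE_COLUMNS
    rows = []
    for rec in records:
        row = {"strain": rec.strain}
        row.update(dict(zip(SITE_COLUMNS, rec.site_scores)))
        row["mds"] = rec.mds
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def save_profiles_yaml(profiles: list[StrainProfile], path) -> None:
    payload = [
        {"name": str(p.name), "health": float(p.health),
         "strength_scale": float(p.strength_scale),
         "strength_cv": float(p.strength_cv),
         "diameter_mean": float(p.diameter_mean),
         "diameter_cv": float(p.diameter_cv),
         "burrow_rate": float(p.burrow_rate),
         "burrow_success": float(p.burrow_success),
         "site_bias": [float(b) for b in p.site_bias]}
        for p in profiles
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"strains": payload}, fh, sort_keys=False)


def load_profiles_yaml(path) -> list[StrainProfile]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        StrainProfile(
            name=entry["name"], health=entry["health"],
            strength_scale=entry["strength_scale"],
            strength_cv=entry["strength_cv"],
            diameter_mean=entry["diameter_mean"],
            diameter_cv=entry["diameter_cv"],
            burrow_rate=entry["burrow_rate"],
            burrow_success=entry["burrow_success"],
            site_bias=tuple(entry["site_bias"]))
        for entry in payload["strains"]
    ]
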