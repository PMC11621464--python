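"""Synthetic data with known ground truth for every pipeline stage.

Generators
----------
- :func:`simulate_fhn_series` — noise-driven FitzHugh–Nagumo oscillator,
  the phenomenological model for ultradian activity bursts.
- :func:`simulate_image_stack` — dark blobs on a light background, a stand-in
  for nest images, with an exactly known fraction of blobs moving per frame.
- :func:`simulate_open_field_track` — piecewise moving/stationary coordinate
  tracks with known bout speed.
- :func:`simulate_bm_traits` — Brownian-motion tip values on a chronogram.
- :func:`pure_birth_chronogram` — Yule-process tree scaled to unit height.
- :func:`simulate_study_dataset` — a whole study-shaped dataset: per-species
  latent rhythm parameters at colony and individual level, recordings
  generated by the oscillator, plus a chronogram and full provenance.
- :func:`simulate_metric_tables` — the same latent structure emitted directly
  as per-recording rhythm metrics (no oscillator/wavelet stage), for fast
  calibration studies of the comparative machinery.

All randomness flows from a single seeded generator per call; identical
(arguments, seed) give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo import Chronogram
from .series import ActivityTimeSeries

__all__ = [
    "FHNParams",
    "IntegrationError",
    "PlacementError",
    "ImageStack",
    "SyntheticStudyConfig",
    "StudyDataset",
    "PHENOSPACE_PRESETS",
    "simulate_fhn_series",
    "simulate_image_stack",
    "render_blob_frames",
    "simulate_open_field_track",
    "simulate_bm_traits",
    "pure_birth_chronogram",
    "simulate_study_dataset",
    "simulate_metric_tables",
]


class IntegrationError(RuntimeError):
    """The stochastic integration produced a non-finite state."""


class PlacementError(ValueError):
    """Blob placement impossible at the requested density/geometry."""


# ---------------------------------------------------------------------------
# FitzHugh–Nagumo oscillator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FHNParams:
    """Parameters of the noise-driven FitzHugh–Nagumo oscillator.

    The model is the standard two-variable excitable system

        dv = (v - v^3/3 - w + drive) dt' + noise_sd dW,
        dw = epsilon (v + a - b w) dt',

    integrated by Euler–Maruyama in model time t'. One model time unit maps
    to ``time_unit_min`` minutes of wall-clock time, which sets the realized
    oscillation period (for the classic oscillatory parameterization
    epsilon=0.08, a=0.7, b=0.8, drive=0.5 the limit cycle takes ~36.6 model
    units, i.e. ~36.6 min at the default mapping). ``noise_sd`` is the
    standard deviation of the stochastic forcing per unit sqrt(model time)
    and enters the activation variable v only. ``obs_noise_sd`` adds white
    observation noise (on the unit-rescaled output scale) to the sampled
    series: it degrades rhythm regularity without perturbing the
    oscillator's period, unlike dynamical noise which does both. The
    observation noise is an AR(1) process with per-sample correlation
    ``obs_noise_rho`` (correlation time of several minutes at 30 s
    sampling), so it is not simply removed by the pipeline's short
    Gaussian smoothing the way white noise would be.
    """

    epsilon: float = 0.08
    a: float = 0.7
    b: float = 0.8
    drive: float = 0.5
    noise_sd: float = 0.0
    obs_noise_sd: float = 0.0
    obs_noise_rho: float = 0.85
    time_unit_min: float = 1.0
    dt_s: float = 1.0
    burn_in_s: float = 1800.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be > 0")
        if self.noise_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.obs_noise_rho < 1:
            raise ValueError("obs_noise_rho must be in [0, 1)")
        if self.burn_in_s < 0:
            raise ValueError("burn_in_s must be >= 0")
        if not self.time_unit_min > 0:
            raise ValueError("time_unit_min must be > 0")


#: Presets spanning the four corners of the (rhythmicity, period) phenospace.
#: High-rhythmicity corners use the deterministic oscillatory regime with a
#: little noise; low-rhythmicity corners are sub-threshold (excitable) and
#: driven by strong noise, which yields irregular bursts. Short vs long
#: period is set by the model-time-to-minutes mapping.
PHENOSPACE_PRESETS: dict[str, FHNParams] = {
    "high_beta_short_period": FHNParams(noise_sd=0.02, time_unit_min=0.5),
    "high_beta_long_period": FHNParams(noise_sd=0.02, time_unit_min=1.8),
    "low_beta_short_period": FHNParams(drive=0.2, noise_sd=1.0, time_unit_min=0.5),
    "low_beta_long_period": FHNParams(drive=0.2, noise_sd=1.0, time_unit_min=1.8),
}


def simulate_fhn_series(
    params: FHNParams,
    duration_s: float,
    sample_interval_s: float = 30.0,
    seed: int = 0,
    **tags,
) -> ActivityTimeSeries:
    """Integrate the oscillator and return a sampled, unit-rescaled series.

    ``duration_s`` counts from time zero and must exceed the burn-in; the
    returned series covers ``duration_s - burn_in_s`` at ``sample_interval_s``
    spacing. The activation variable is rescaled to [0, 1] per series; a
    series whose range is negligible (noise-free excitable regime at its
    fixed point) is returned unscaled, since rescaling would only amplify
    the residual transient.
    """
    if duration_s <= params.burn_in_s:
        raise ValueError("duration_s must exceed burn_in_s")
    if sample_interval_s < params.dt_s:
        raise ValueError("sample_interval_s must be >= dt_s")
    rng = np.random.default_rng(seed)
    dt_model = params.dt_s / 60.0 / params.time_unit_min
    n_steps = int(round(duration_s / params.dt_s))
    noise = params.noise_sd * math.sqrt(dt_model) * rng.standard_normal(n_steps)

    eps, a, b, drive = params.epsilon, params.a, params.b, params.drive
    v, w = 0.0, 0.0
    traj = np.empty(n_steps)
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n_steps):
            dv = (v - v * v * v / 3.0 - w + drive) * dt_model + noise[i]
            dw = eps * (v + a - b * w) * dt_model
            v += dv
            w += dw
            traj[i] = v
    bad = np.flatnonzero(~np.isfinite(traj))
    if bad.size:
        raise IntegrationError(
            f"non-finite trajectory at step {int(bad[0])}; "
            "parameters likely cause blow-up at this dt"
        )

    first = int(round(params.burn_in_s / params.dt_s))
    stride = int(round(sample_interval_s / params.dt_s))
    sampled = traj[first::stride]

    def unit_rescale(x: np.ndarray) -> np.ndarray:
        lo, hi = float(x.min()), float(x.max())
        scale = hi - lo
        if scale > 1e-9 * max(1.0, abs(hi), abs(lo)):
            return (x - lo) / scale
        # effectively constant: shift to a nonnegative constant, do not rescale
        return x - lo

    sampled = unit_rescale(sampled)
    if params.obs_noise_sd > 0:
        from scipy.signal import lfilter

        e = rng.standard_normal(sampled.size)
        rho = params.obs_noise_rho
        red = lfilter([math.sqrt(1.0 - rho * rho)], [1.0, -rho], e)
        sampled = unit_rescale(sampled + params.obs_noise_sd * red)
    tags.setdefault("source", "synthetic")
    return ActivityTimeSeries(values=sampled, sample_interval_s=sample_interval_s, **tags)


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageStack:
    """An ordered stack of equally shaped 2-D grayscale frames."""

    frames: np.ndarray  # (n_frames, h, w) float
    frame_interval_s: float = 30.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise ValueError("frames must be (n>=2, h, w)")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame intensities must be finite")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])


def _disk_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def render_blob_frames(
    positions: np.ndarray,
    radius_px: float,
    shape: tuple[int, int],
    background: float = 0.85,
    foreground: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_interval_s: float = 30.0,
) -> ImageStack:
    """Render dark disks on a light background.

    ``positions`` is (n_frames, n_blobs, 2) in (row, col) pixel coordinates.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:  # single blob: (n_frames, 2)
        positions = positions[:, None, :]
    n_frames = positions.shape[0]
    h, w = shape
    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, h, w), background)
    for t in range(n_frames):
        for cy, cx in positions[t]:
            frames[t][_disk_mask(h, w, cy, cx, radius_px)] = foreground
    if noise_sd > 0:
        frames += noise_sd * rng.standard_normal(frames.shape)
    return ImageStack(frames=frames, frame_interval_s=frame_interval_s)


def simulate_image_stack(
    n_blobs: int,
    n_frames: int,
    frac_moving_per_frame: float,
    blob_radius_px: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
) -> ImageStack:
    """Blobs on a grid; an exact count toggles position at each transition.

    Each blob owns a grid cell with two slots separated by 2.5x the blob
    radius (so a move displaces it by >= 2 radii and the old and new disks
    are disjoint). Per transition exactly
    ``round(frac_moving_per_frame * n_blobs)`` blobs, chosen at random,
    switch slot; the rest stay put.
    """
    if not 0 <= frac_moving_per_frame <= 1:
        raise ValueError("frac_moving_per_frame must be in [0, 1]")
    if n_blobs < 1 or n_frames < 2:
        raise ValueError("need n_blobs >= 1 and n_frames >= 2")
    rng = np.random.default_rng(seed)
    r = float(blob_radius_px)
    cell = int(math.ceil(6 * r))
    ncol = int(math.ceil(math.sqrt(n_blobs)))
    nrow = int(math.ceil(n_blobs / ncol))
    margin = int(math.ceil(2 * r))
    h = nrow * cell + 2 * margin
    w = ncol * cell + 2 * margin
    if frame_shape is not None:
        if frame_shape[0] < h or frame_shape[1] < w:
            raise PlacementError(
                f"{n_blobs} blobs of radius {r} need at least ({h}, {w}) pixels, "
                f"got {frame_shape}"
            )
        h, w = frame_shape

    # two slots per cell, offset horizontally by +-1.25 r around the center
    centers = np.array(
        [
            (margin + (i // ncol) * cell + cell / 2, margin + (i % ncol) * cell + cell / 2)
            for i in range(n_blobs)
        ],
        dtype=float,
    )
    offset = np.array([0.0, 1.25 * r])
    slot_state = np.zeros(n_blobs, dtype=int)  # 0 -> -offset, 1 -> +offset
    n_move = int(round(frac_moving_per_frame * n_blobs))

    positions = np.empty((n_frames, n_blobs, 2))
    for t in range(n_frames):
        if t > 0 and n_move > 0:
            movers = rng.choice(n_blobs, size=n_move, replace=False)
            slot_state[movers] ^= 1
        signs = np.where(slot_state == 1, 1.0, -1.0)[:, None]
        positions[t] = centers + signs * offset[None, :]
    return render_blob_frames(
        positions, r, (h, w), noise_sd=noise_sd, seed=int(rng.integers(2**31))
    )


# ---------------------------------------------------------------------------
# Open-field tracks
# ---------------------------------------------------------------------------

def simulate_open_field_track(
    speed_bl_s: float,
    body_length_px: float,
    fps: float,
    duration_s: float,
    moving_fraction: float = 0.6,
    seed: int = 0,
    mean_bout_frames: int = 12,
) -> np.ndarray:
    """Piecewise track alternating moving bouts and stationary bouts.

    During a moving bout the per-frame displacement is exactly
    ``speed_bl_s * body_length_px / fps`` along a per-bout random heading;
    stationary bouts contribute zero displacement. Exactly
    ``round(moving_fraction * n_transitions)`` transitions are moving.
    Returns an (n_frames, 2) array of (x, y) pixel coordinates.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if speed_bl_s < 0:
        raise ValueError("speed_bl_s must be >= 0")
    if body_length_px <= 0:
        raise ValueError("body_length_px must be > 0")
    if not 0 <= moving_fraction <= 1:
        raise ValueError("moving_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_frames = max(2, int(round(duration_s * fps)))
    n_trans = n_frames - 1
    n_moving = int(round(moving_fraction * n_trans))

    moving = np.zeros(n_trans, dtype=bool)
    # lay out alternating bouts until the moving budget is spent
    i, budget = 0, n_moving
    while i < n_trans and budget > 0:
        mov_len = min(budget, 1 + rng.poisson(mean_bout_frames - 1))
        moving[i : i + mov_len] = True
        i += mov_len
        budget -= mov_len
        i += 1 + rng.poisson(mean_bout_frames - 1)  # stationary gap
    # force any leftover moving frames (bout layout may have run off the end)
    shortfall = n_moving - int(moving.sum())
    if shortfall > 0:
        still = np.flatnonzero(~moving)
        moving[still[:shortfall]] = True

    step = speed_bl_s * body_length_px / fps
    headings = np.zeros(n_trans)
    theta = rng.uniform(0, 2 * math.pi)
    prev = False
    for t in range(n_trans):
        if moving[t] and not prev:
            theta = rng.uniform(0, 2 * math.pi)
        headings[t] = theta
        prev = moving[t]
    dx = np.where(moving, step * np.cos(headings), 0.0)
    dy = np.where(moving, step * np.sin(headings), 0.0)
    coords = np.zeros((n_frames, 2))
    coords[1:, 0] = np.cumsum(dx)
    coords[1:, 1] = np.cumsum(dy)
    return coords


# ---------------------------------------------------------------------------
# Brownian-motion traits and trees
# ---------------------------------------------------------------------------

def simulate_bm_traits(
    tree: Chronogram,
    sigma2: float,
    root_state: float = 0.0,
    seed: int = 0,
    n_draws: int = 1,
) -> dict[str, float] | pd.DataFrame:
    """Draw tip values under Brownian motion on the chronogram.

    Tips are jointly normal with mean ``root_state`` and covariance
    ``sigma2 * C``. With ``n_draws > 1`` a DataFrame (draws x species) is
    returned; the single-draw default returns a species -> value mapping.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    C, labels = tree.vcv()
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        draws = np.full((n_draws, len(labels)), float(root_state))
    else:
        try:
            L = np.linalg.cholesky(sigma2 * C)
        except np.linalg.LinAlgError as exc:
            raise ValueError("tree covariance is not positive definite") from exc
        z = rng.standard_normal((n_draws, len(labels)))
        draws = root_state + z @ L.T
    if n_draws == 1:
        return dict(zip(labels, draws[0]))
    return pd.DataFrame(draws, columns=labels)


def pure_birth_chronogram(n_species: int, seed: int = 0, height: float = 1.0,
                          min_tip_frac: float = 0.1,
                          label_fmt: str = "sp{:02d}") -> Chronogram:
    """Simulate a Yule (pure-birth) tree and rescale it to the given height.

    ``min_tip_frac`` guarantees every terminal branch is at least that
    fraction of the tree height, emulating a species-level chronogram in
    which all tips are well-separated taxa; without it the Yule process
    produces near-zero sister distances, against which any comparative
    rate estimate is pathologically sensitive to tip measurement noise.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not 0 <= min_tip_frac < 1:
        raise ValueError("min_tip_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)

    birth_time = {tree.seed_node: 0.0}
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth_time[node] if node.parent_node else 0.0
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_species)
    if min_tip_frac > 0:
        t_end = max(t_end, t / (1.0 - min_tip_frac))
    for leaf in active:
        leaf.edge.length = t_end - birth_time[leaf]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_ns.new_taxon(label=label_fmt.format(i + 1))
    # rescale the realized root-to-tip depth to the requested height
    depth = 0.0
    node = next(tree.leaf_node_iter())
    while node.parent_node is not None:
        depth += node.edge.length
        node = node.parent_node
    factor = height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return Chronogram(tree)


# ---------------------------------------------------------------------------
# Study-shaped datasets
# ---------------------------------------------------------------------------

def _as_pair(x) -> tuple[float, float]:
    if np.isscalar(x):
        return (float(x), float(x))
    pair = tuple(float(v) for v in x)
    if len(pair) != 2:
        raise ValueError("SD must be a scalar or a (rhythm, period) pair")
    return pair


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Shape and latent-parameter spread of a synthetic study.

    Defaults emulate the deposited study structure: 22 species, colonies
    recorded at 30 s for 14.5 h (1740 frames, most colonies twice) and
    isolated individuals for 8.5 h (1020 frames), with interspecific spread
    of colony-level rhythm strength exceeding the individual-level spread.
    The SD fields act on the log scale of the latent oscillator parameters
    and may be a scalar (applied to both components) or a
    ``(rhythm_strength, period)`` pair.
    """

    n_species: int = 22
    colonies_per_species: int = 3
    recordings_per_colony: int = 2
    individuals_per_species: int = 6
    colony_series_len: int = 1740
    individual_series_len: int = 1020
    interspecific_sd_colony: float | tuple[float, float] = (0.45, 0.40)
    interspecific_sd_individual: float | tuple[float, float] = (0.15, 0.40)
    intraspecific_sd: float = 0.10
    seed: int = 0
    latent_model: str = "bm"
    base_noise_sd: float = 0.25
    base_obs_noise_sd: float = 0.15
    base_time_unit_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_species", "colonies_per_species", "recordings_per_colony",
                     "individuals_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("colony_series_len", "individual_series_len"):
            if getattr(self, name) < 64:
                raise ValueError(f"{name} must be >= 64")
        object.__setattr__(self, "interspecific_sd_colony",
                           _as_pair(self.interspecific_sd_colony))
        object.__setattr__(self, "interspecific_sd_individual",
                           _as_pair(self.interspecific_sd_individual))
        for pair in (self.interspecific_sd_colony, self.interspecific_sd_individual):
            if min(pair) < 0:
                raise ValueError("interspecific SDs must be >= 0")
        if self.intraspecific_sd < 0:
            raise ValueError("intraspecific_sd must be >= 0")
        if self.latent_model not in ("bm", "iid"):
            raise ValueError("latent_model must be 'bm' or 'iid'")


@dataclass
class StudyDataset:
    """A simulated study: recordings, chronogram and latent provenance."""

    series: list[ActivityTimeSeries]
    tree: Chronogram
    provenance: dict = field(default_factory=dict)


def _species_latents(config: SyntheticStudyConfig, rng: np.random.Generator,
                     tree: Chronogram):
    """Draw per-species, per-level latent (log rhythm strength, log period).

    With the default ``latent_model="bm"`` the latents evolve by Brownian
    motion along the chronogram (unit height), so the configured
    interspecific SD is the marginal SD at the tips and the downstream
    Brownian-rate machinery sees correctly structured data; ``"iid"`` draws
    independent species effects instead. Rhythm strength maps inversely
    onto observation-noise amplitude: weaker rhythm = noisier series =
    lower coherence factor downstream, without moving the oscillator's
    period. Period maps onto the model-time unit.
    """
    C, labels = tree.vcv()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))

    def bm_draw(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(len(labels))
        z = rng.standard_normal(len(labels))
        if config.latent_model == "iid":
            return sd * z
        return sd * (L @ z)

    draws = {}
    for level, (sd_r, sd_p) in (
        ("colony", config.interspecific_sd_colony),
        ("individual", config.interspecific_sd_individual),
    ):
        draws[level] = (bm_draw(sd_r), bm_draw(sd_p))

    latents: dict[str, dict] = {}
    for j, sp in enumerate(labels):
        latents[sp] = {}
        for level in ("colony", "individual"):
            dr, dp = draws[level]
            latents[sp][level] = {
                # rhythm strength down = observation noise up; log scale
                "log_obs_noise": math.log(config.base_obs_noise_sd) + dr[j],
                "log_time_unit": math.log(config.base_time_unit_min) + dp[j],
            }
    return latents


def simulate_study_dataset(config: SyntheticStudyConfig) -> StudyDataset:
    """Generate a full study-shaped dataset from the oscillator.

    Per species and level a latent (rhythm strength, period) pair is drawn
    with the configured interspecific SDs; each colony/individual gets a
    jittered copy (``intraspecific_sd``, log scale) and its recordings are
    integrated with :func:`simulate_fhn_series`. A pure-birth chronogram
    with matching tips is returned along with all latent parameters.
    """
    rng = np.random.default_rng(config.seed)
    tree = pure_birth_chronogram(config.n_species, seed=int(rng.integers(2**31)))
    latents = _species_latents(config, rng, tree)

    series: list[ActivityTimeSeries] = []
    provenance: dict = {"config_seed": config.seed, "species": {}}
    for sp, by_level in latents.items():
        provenance["species"][sp] = {"latents": by_level, "units": {}}
        # colony recordings
        for c in range(config.colonies_per_species):
            cid = f"{sp}_c{c + 1}"
            jitter_r = config.intraspecific_sd * rng.standard_normal()
            jitter_p = config.intraspecific_sd * rng.standard_normal()
            obs_sd = math.exp(by_level["colony"]["log_obs_noise"] + jitter_r)
            tu = math.exp(by_level["colony"]["log_time_unit"] + jitter_p)
            provenance["species"][sp]["units"][cid] = {
                "obs_noise_sd": obs_sd, "time_unit_min": tu}
            for r in range(config.recordings_per_colony):
                params = FHNParams(noise_sd=config.base_noise_sd,
                                   obs_noise_sd=obs_sd, time_unit_min=tu)
                dur = params.burn_in_s + config.colony_series_len * 30.0
                ts = simulate_fhn_series(
                    params, dur, 30.0, seed=int(rng.integers(2**31)),
                    level="colony", species=sp, colony_id=cid,
                    series_id=f"{cid}_r{r + 1}",
                )
                series.append(ts.with_values(ts.values[: config.colony_series_len]))
        # isolated individuals (colony of origin assigned round-robin)
        for ind in range(config.individuals_per_species):
            cid = f"{sp}_c{ind % config.colonies_per_species + 1}"
            iid = f"{sp}_i{ind + 1}"
            jitter_r = config.intraspecific_sd * rng.standard_normal()
            jitter_p = config.intraspecific_sd * rng.standard_normal()
            obs_sd = math.exp(by_level["individual"]["log_obs_noise"] + jitter_r)
            tu = math.exp(by_level["individual"]["log_time_unit"] + jitter_p)
            provenance["species"][sp]["units"][iid] = {
                "obs_noise_sd": obs_sd, "time_unit_min": tu}
            params = FHNParams(noise_sd=config.base_noise_sd,
                               obs_noise_sd=obs_sd, time_unit_min=tu)
            dur = params.burn_in_s + config.individual_series_len * 30.0
            ts = simulate_fhn_series(
                params, dur, 30.0, seed=int(rng.integers(2**31)),
                level="individual", species=sp, colony_id=cid,
                individual_id=iid, series_id=iid,
            )
            series.append(ts.with_values(ts.values[: config.individual_series_len]))
    return StudyDataset(series=series, tree=tree, provenance=provenance)


def simulate_metric_tables(
    config: SyntheticStudyConfig,
    base_beta_excess: float = 4.0,
    base_period_min: float = 36.0,
) -> tuple[pd.DataFrame, pd.DataFrame, Chronogram, dict]:
    """Emit per-recording rhythm metrics directly from the latent structure.

    Skips the oscillator and wavelet stages: per species and level a latent
    (log rhythmicity excess, log period) pair is drawn with the configured
    interspecific SDs and every recording is a log-normal jitter of it
    (``intraspecific_sd``). Rhythmicity is ``1 + exp(latent)`` so the
    beta >= 1 invariant holds. Intended for calibration studies of the
    comparative stage, where thousands of full simulations would be
    needless; note ``intraspecific_sd`` must be > 0 for resampling to have
    anything to resample.

    Returns ``(colony_table, individual_table, tree, provenance)`` with
    tables in the per-recording metric schema (species, colony_id /
    individual_id, rhythmicity_beta, dominant_period_min).
    """
    rng = np.random.default_rng(config.seed)
    tree = pure_birth_chronogram(config.n_species, seed=int(rng.integers(2**31)))
    latents = _species_latents(config, rng, tree)

    def record(latent, n):
        jr = config.intraspecific_sd * rng.standard_normal(n)
        jp = config.intraspecific_sd * rng.standard_normal(n)
        # the obs-noise latent plays the role of -log rhythmicity excess
        beta = 1.0 + base_beta_excess * np.exp(
            -(latent["log_obs_noise"] - math.log(config.base_obs_noise_sd)) + jr
        )
        period = base_period_min * np.exp(
            latent["log_time_unit"] - math.log(config.base_time_unit_min) + jp
        )
        return beta, period

    colony_rows, indiv_rows = [], []
    for sp, by_level in latents.items():
        for c in range(config.colonies_per_species):
            beta, period = record(by_level["colony"], config.recordings_per_colony)
            for r in range(config.recordings_per_colony):
                colony_rows.append(
                    {"species": sp, "colony_id": f"{sp}_c{c + 1}",
                     "rhythmicity_beta": beta[r], "dominant_period_min": period[r]}
                )
        beta, period = record(by_level["individual"], config.individuals_per_species)
        for ind in range(config.individuals_per_species):
            indiv_rows.append(
                {"species": sp, "colony_id": f"{sp}_c{ind % config.colonies_per_species + 1}",
                 "individual_id": f"{sp}_i{ind + 1}",
                 "rhythmicity_beta": beta[ind], "dominant_period_min": period[ind]}
            )
    provenance = {"config_seed": config.seed, "latents": latents}
    return (
        pd.DataFrame(colony_rows),
        pd.DataFrame(indiv_rows),
        tree,
        provenance,
    )
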