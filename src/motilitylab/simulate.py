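"""Synthetic trajectory generator for 2D motility assays and 3D tissue scenes.

The generator provides ground truth for every downstream stage: Brownian,
persistent-random-walk (Ornstein–Uhlenbeck velocity), directed and Lévy
walkers, per-condition mixtures of those regimes, localization noise, and
3D scenes in which cells and fiducial landmarks share a rigid drift.

Default scenarios mirror the study design they emulate: 2D nuclei tracks
imaged every 10 min for 12 h (72 intervals), 3D tracks every 12 min for 8 h,
and untreated/treated motile fractions of 1/24 and 11/24.

The persistent random walk uses the exact joint (position, velocity) update
of the integrated OU process rather than an Euler step, so its ensemble MSD
matches the Fürth form

    MSD(t) = 2 d S² P (t − P (1 − e^(−t/P)))

at any frame interval, with S the per-axis stationary velocity SD (μm/min)
and P the persistence time (min).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Track, TrackSet

_MODELS = ("brownian", "prw", "directed", "levy", "mixture")


@dataclass(frozen=True)
class MixtureComponent:
    """One regime of a per-condition mixture: a model, its parameters, and
    the proportion of tracks drawn from it."""

    name: str
    model: str
    params: dict
    proportion: float


@dataclass
class SimulationConfig:
    """Parameters of a synthetic tracking experiment.

    sigma is the per-axis Brownian step SD in μm per frame; speed and
    persistence_time parameterize the PRW (per-axis stationary velocity SD in
    μm/min, relaxation time in min); velocity is the constant drift of the
    directed model in μm/min; levy_alpha/levy_min_step parameterize Pareto
    step lengths; noise_sd is the localization noise SD in μm.
    """

    model: str = "brownian"
    n_tracks: int = 100
    n_frames: int = 73
    frame_interval: float = 10.0
    dim: int = 2
    seed: int = 0
    sigma: float = 1.0
    speed: float = 0.3
    persistence_time: float = 30.0
    velocity: Sequence[float] | None = None
    levy_alpha: float = 2.0
    levy_min_step: float = 0.5
    mixture_spec: dict[str, list[MixtureComponent]] = field(default_factory=dict)
    noise_sd: float = 0.0

    def validate(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be ≥ 2")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if min(self.sigma, self.speed, self.persistence_time, self.noise_sd) < 0:
            raise ValueError("sigma, speed, persistence_time, noise_sd must be ≥ 0")
        if self.model == "levy" and self.levy_alpha <= 1:
            raise ValueError("levy_alpha must be > 1 for a finite mean step")
        if self.model == "mixture":
            for cond, comps in self.mixture_spec.items():
                total = sum(c.proportion for c in comps)
                if not np.isclose(total, 1.0):
                    raise ValueError(
                        f"mixture proportions for {cond!r} sum to {total}, not 1"
                    )


@dataclass
class DriftScene:
    """A 3D construct scene: cell tracks and fiducial landmark tracks that
    share a rigid drift, plus the latent drift path the correction must
    recover (cumulative, relative to frame 0)."""

    cells: TrackSet
    fiducials: TrackSet
    true_drift: np.ndarray
    fiducial_jitter_sd: float


def _isotropic_directions(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    v = rng.standard_normal((n, dim))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


def _steps_brownian(rng, n_steps, dim, sigma: float, **_) -> np.ndarray:
    return rng.normal(0.0, sigma, size=(n_steps, dim))


def _steps_prw(
    rng, n_steps, dim, speed: float, persistence_time: float, frame_interval: float, **_
) -> np.ndarray:
    # exact integrated-OU update (Gillespie 1996): jointly sample the velocity
    # and the position increment over each frame, starting from the stationary
    # velocity distribution, so the discrete-time MSD is exactly Fürth's.
    s2 = speed**2
    theta = 1.0 / persistence_time
    dt = frame_interval
    e1 = np.exp(-theta * dt)
    var_v = s2 * (1.0 - e1**2)
    var_x = (s2 / theta**2) * (2.0 * theta * dt - 3.0 + 4.0 * e1 - e1**2)
    cov_xv = (s2 / theta) * (1.0 - e1) ** 2
    # Cholesky of the 2x2 increment covariance [[var_x, cov], [cov, var_v]]
    a = np.sqrt(var_x)
    b = cov_xv / a if a > 0 else 0.0
    c = np.sqrt(max(var_v - b**2, 0.0))
    v = rng.normal(0.0, speed, size=dim)
    steps = np.empty((n_steps, dim))
    for i in range(n_steps):
        z1 = rng.standard_normal(dim)
        z2 = rng.standard_normal(dim)
        steps[i] = v / theta * (1.0 - e1) + a * z1
        v = v * e1 + b * z1 + c * z2
    return steps


def _steps_directed(
    rng, n_steps, dim, velocity, sigma: float, frame_interval: float, **_
) -> np.ndarray:
    if velocity is None:
        raise ValueError("directed model requires a velocity vector")
    v = np.asarray(velocity, dtype=float)
    if v.shape != (dim,):
        raise ValueError(f"velocity must have {dim} components")
    return v * frame_interval + rng.normal(0.0, sigma, size=(n_steps, dim))


def _steps_levy(
    rng, n_steps, dim, levy_alpha: float, levy_min_step: float, **_
) -> np.ndarray:
    lengths = levy_min_step * rng.uniform(size=n_steps) ** (-1.0 / levy_alpha)
    return lengths[:, None] * _isotropic_directions(rng, n_steps, dim)


_STEP_FNS = {
    "brownian": _steps_brownian,
    "prw": _steps_prw,
    "directed": _steps_directed,
    "levy": _steps_levy,
}


def _one_track(
    model: str, cfg_kwargs: dict, rng: np.random.Generator, n_frames: int, dim: int
) -> np.ndarray:
    steps = _STEP_FNS[model](rng, n_frames - 1, dim, **cfg_kwargs)
    pos = np.zeros((n_frames, dim))
    pos[1:] = np.cumsum(steps, axis=0)
    return pos


def _model_kwargs(cfg: SimulationConfig, model: str, overrides: dict | None = None) -> dict:
    kw = {
        "sigma": cfg.sigma,
        "speed": cfg.speed,
        "persistence_time": cfg.persistence_time,
        "velocity": cfg.velocity,
        "levy_alpha": cfg.levy_alpha,
        "levy_min_step": cfg.levy_min_step,
        "frame_interval": cfg.frame_interval,
    }
    if overrides:
        kw.update(overrides)
    return kw


def simulate_tracks(
    cfg: SimulationConfig, condition: str = "unspecified"
) -> tuple[TrackSet, list[str]]:
    """Simulate a TrackSet under ``cfg``; returns (tracks, component labels).

    For single-model configs every label is the model name; for mixtures the
    component of each track is drawn from the condition's proportions and its
    name returned, giving planted ground truth for clustering tests.

    Deterministic given ``cfg.seed``: a per-track substream is spawned from
    the single seed, so growing ``n_tracks`` never reshuffles earlier tracks.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_tracks)
    if cfg.model == "mixture":
        comps = cfg.mixture_spec.get(condition)
        if not comps:
            raise ValueError(f"no mixture components configured for condition {condition!r}")
        props = np.array([c.proportion for c in comps])
    tracks, labels = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if cfg.model == "mixture":
            comp = comps[rng.choice(len(comps), p=props)]
            model, kw = comp.model, _model_kwargs(cfg, comp.model, comp.params)
            labels.append(comp.name)
        else:
            model, kw = cfg.model, _model_kwargs(cfg, cfg.model)
            labels.append(cfg.model)
        pos = _one_track(model, kw, rng, cfg.n_frames, cfg.dim)
        if cfg.noise_sd > 0:
            pos = pos + rng.normal(0.0, cfg.noise_sd, size=pos.shape)
        tracks.append(
            Track(
                track_id=f"{condition}_{i:05d}",
                condition=condition,
                frame_interval=cfg.frame_interval,
                frames=np.arange(cfg.n_frames),
                positions=pos,
            )
        )
    return (
        TrackSet(tracks=tracks, frame_interval=cfg.frame_interval, meta={"seed": cfg.seed}),
        labels,
    )


def add_localization_noise(ts: TrackSet, sd: float, seed: int) -> TrackSet:
    """Add i.i.d. Normal(0, sd²) localization error to every coordinate."""
    if sd < 0:
        raise ValueError("noise sd must be ≥ 0")
    if sd == 0:
        return ts
    rng = np.random.default_rng(seed)
    noisy = [
        replace(t, positions=t.positions + rng.normal(0.0, sd, size=t.positions.shape))
        for t in ts
    ]
    return TrackSet(tracks=noisy, frame_interval=ts.frame_interval,
                    field_bounds=ts.field_bounds, meta=dict(ts.meta))


def _drift_path(
    spec: dict, n_frames: int, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative drift path (n_frames, dim), zero at frame 0."""
    model = spec.get("model", "sine")
    amplitude = float(spec.get("amplitude", 5.0))
    t = np.arange(n_frames, dtype=float)
    if model == "linear":
        if "direction" in spec:
            direction = np.asarray(spec["direction"], dtype=float)
            direction = direction / np.linalg.norm(direction)
        else:
            direction = _isotropic_directions(rng, 1, dim)[0]
        return amplitude * (t / max(n_frames - 1, 1))[:, None] * direction
    if model == "sine":
        period = float(spec.get("period", max(n_frames // 4, 4)))
        phases = rng.uniform(0, 2 * np.pi, size=dim)
        path = amplitude * np.sin(2 * np.pi * t[:, None] / period + phases)
        return path - path[0]
    if model == "random_walk":
        steps = rng.normal(0.0, amplitude, size=(n_frames - 1, dim))
        path = np.zeros((n_frames, dim))
        path[1:] = np.cumsum(steps, axis=0)
        return path
    raise ValueError(f"unknown drift model {model!r}")


def add_shared_drift(
    cells: TrackSet,
    drift_spec: dict,
    n_fiducials: int = 10,
    fiducial_jitter_sd: float = 0.2,
    seed: int = 0,
    field_extent: float = 300.0,
) -> DriftScene:
    """Impose one rigid drift on an existing TrackSet and emit fiducials.

    All cells (any mix of conditions) receive the same cumulative drift;
    fiducial landmarks, scattered uniformly in a cube of side
    ``field_extent`` μm, follow the drift path up to i.i.d. Normal jitter.
    The latent drift path (relative to frame 0) is stored for round-trip
    verification.
    """
    if n_fiducials < 2:
        raise ValueError("need at least 2 fiducials")
    if len(cells) == 0:
        raise ValueError("empty TrackSet")
    n_frames = max(int(t.frames[-1]) for t in cells) + 1
    dim = cells.ndim
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CE7E]))
    drift = _drift_path(drift_spec, n_frames, dim, rng)
    drifted_cells = [
        replace(t, positions=t.positions + drift[t.frames]) for t in cells
    ]
    fids = []
    starts = rng.uniform(0.0, field_extent, size=(n_fiducials, dim))
    for j in range(n_fiducials):
        pos = starts[j] + drift
        if fiducial_jitter_sd > 0:
            pos = pos + rng.normal(0.0, fiducial_jitter_sd, size=pos.shape)
        fids.append(
            Track(
                track_id=f"fid_{j:03d}",
                condition="fiducial",
                frame_interval=cells.frame_interval,
                frames=np.arange(n_frames),
                positions=pos,
            )
        )
    return DriftScene(
        cells=TrackSet(drifted_cells, cells.frame_interval, meta=dict(cells.meta)),
        fiducials=TrackSet(fids, cells.frame_interval, meta={"seed": seed}),
        true_drift=drift,
        fiducial_jitter_sd=fiducial_jitter_sd,
    )


def make_drift_scene(
    cfg: SimulationConfig,
    drift_spec: dict,
    n_fiducials: int = 10,
    fiducial_jitter_sd: float = 0.2,
    condition: str = "unspecified",
    field_extent: float = 300.0,
) -> DriftScene:
    """Simulate cells under ``cfg`` and wrap them in a drifting 3D scene
    (see :func:`add_shared_drift`)."""
    cfg.validate()
    cells, _ = simulate_tracks(cfg, condition)
    return add_shared_drift(
        cells, drift_spec, n_fiducials, fiducial_jitter_sd,
        seed=cfg.seed, field_extent=field_extent,
    )


# ---------------------------------------------------------------------------
# Study-condition scenario builders


def two_regime_mixture(
    motile_fraction_untreated: float = 1 / 24,
    motile_fraction_treated: float = 11 / 24,
    slow_sigma: float = 0.8,
    motile_speed: float = 0.35,
    motile_persistence: float = 40.0,
) -> dict[str, list[MixtureComponent]]:
    """Per-condition mixture of a low-motility Brownian regime and a motile
    persistent regime, with the default condition-dependent motile fractions
    1/24 (untreated) vs 11/24 (treated)."""

    def comps(frac: float) -> list[MixtureComponent]:
        return [
            MixtureComponent("slow", "brownian", {"sigma": slow_sigma}, 1 - frac),
            MixtureComponent(
                "motile",
                "prw",
                {"speed": motile_speed, "persistence_time": motile_persistence},
                frac,
            ),
        ]

    return {
        "untreated": comps(motile_fraction_untreated),
        "treated": comps(motile_fraction_treated),
    }


def default_2d_config(
    n_tracks: int = 120, seed: int = 0, noise_sd: float = 0.3
) -> SimulationConfig:
    """2D motility assay: 10-min frames over 12 h (73 frames), two-regime
    condition mixture, mild localization noise."""
    return SimulationConfig(
        model="mixture",
        n_tracks=n_tracks,
        n_frames=73,
        frame_interval=10.0,
        dim=2,
        seed=seed,
        mixture_spec=two_regime_mixture(),
        noise_sd=noise_sd,
    )


def default_3d_config(
    n_tracks: int = 24, seed: int = 0, noise_sd: float = 0.2
) -> SimulationConfig:
    """3D construct migration: 12-min frames over 8 h (41 frames).  Regime
    parameters are set so the slow and motile populations travel ≈47 μm and
    ≈75 μm of total path over the 8-h movie."""
    return SimulationConfig(
        model="mixture",
        n_tracks=n_tracks,
        n_frames=41,
        frame_interval=12.0,
        dim=3,
        seed=seed,
        mixture_spec=two_regime_mixture(
            slow_sigma=0.686, motile_speed=0.0953, motile_persistence=60.0
        ),
        noise_sd=noise_sd,
    )
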