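"""Seeded generators for every input the analysis consumes.

Emulated study conditions:

* per-hemibrain postsynaptic-partner counts across 12–31 °C following
  n/n0 = exp[-beta (T - T0)] with overdispersed (negative-binomial) noise,
  group sizes 20–38 as in the fixed-temperature experiments;
* developmental times following t/t0 = exp[-alpha (T - T0)] with lognormal
  noise;
* synapse tables with planted partner structure and spatially clustered
  glomeruli;
* arena trajectories from a stop/go correlated random walk with Gaussian
  active speeds and optional drift toward the odor source.

Every generator is a pure function of its configuration: identical config
(including seed) gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .behavior import TrajectorySet
from .inference import FoldChangeDataset

__all__ = [
    "GeneratorConfig",
    "GlomerulusSpec",
    "gen_partner_counts",
    "gen_devtimes",
    "gen_synapse_table",
    "gen_trajectories",
]

#: Temperatures (°C) -> hemibrains per group, matching the fixed-temperature design.
DEFAULT_DESIGN = {12.0: 25, 18.0: 30, 25.0: 38, 31.0: 20}


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared configuration of the fold-change generators.

    ``n0`` (mean partner count at T0) and ``t0_days`` (developmental time at
    T0) set absolute scales that the real study reports only graphically;
    the defaults (20 partners, 10 days) are placeholder magnitudes, not
    measured values.  ``nb_dispersion`` is the negative-binomial size
    parameter (variance = mu + mu^2/dispersion); ``lognormal_cv`` the
    coefficient of variation of developmental times.
    """

    seed: int = 20250115
    alpha: float = 0.128
    beta: float = 0.133
    ref_temp: float = 25.0
    n0: float = 20.0
    t0_days: float = 10.0
    nb_dispersion: float = 20.0
    lognormal_cv: float = 0.08
    design: Mapping[float, int] = field(default_factory=lambda: dict(DEFAULT_DESIGN))

    def __post_init__(self) -> None:
        if not (self.n0 > 0 and self.t0_days > 0):
            raise InvalidArgumentError("n0 and t0_days must be > 0")
        if not (self.nb_dispersion > 0):
            raise InvalidArgumentError("nb_dispersion must be > 0")
        if self.lognormal_cv < 0:
            raise InvalidArgumentError("lognormal_cv must be >= 0")
        if not self.design:
            raise InvalidArgumentError("design must list at least one temperature")
        for t, n in self.design.items():
            if n < 1:
                raise InvalidArgumentError(f"group size at {t} °C must be >= 1")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config_seed, stream)))


def gen_partner_counts(config: GeneratorConfig) -> FoldChangeDataset:
    """Negative-binomial partner counts with mean n0*exp[-beta (T - T0)]."""
    rng = _rng(config.seed, 1)
    rows = []
    for temp in sorted(config.design):
        n = config.design[temp]
        mu = config.n0 * np.exp(-config.beta * (temp - config.ref_temp))
        k = config.nb_dispersion
        counts = rng.negative_binomial(k, k / (k + mu), size=n)
        for i, c in enumerate(counts):
            rows.append({"temperature_c": temp, "individual": f"T{temp:g}_h{i:03d}",
                         "value": int(c), "condition": "fixed"})
    return FoldChangeDataset(records=pd.DataFrame(rows), ref_temp=config.ref_temp,
                             value_kind="partners")


def gen_devtimes(config: GeneratorConfig) -> FoldChangeDataset:
    """Lognormal developmental times (days) with mean t0*exp[-alpha (T - T0)]."""
    rng = _rng(config.seed, 2)
    sigma2 = np.log1p(config.lognormal_cv**2)
    sigma = np.sqrt(sigma2)
    rows = []
    for temp in sorted(config.design):
        n = config.design[temp]
        mean = config.t0_days * np.exp(-config.alpha * (temp - config.ref_temp))
        mu = np.log(mean) - sigma2 / 2.0
        times = rng.lognormal(mu, sigma, size=n) if sigma > 0 else np.full(n, mean)
        for i, t in enumerate(times):
            rows.append({"temperature_c": temp, "individual": f"T{temp:g}_f{i:03d}",
                         "value": float(t), "condition": "fixed"})
    return FoldChangeDataset(records=pd.DataFrame(rows), ref_temp=config.ref_temp,
                             value_kind="devtime")


@dataclass(frozen=True)
class GlomerulusSpec:
    """Planted structure of one glomerulus in a synthetic synapse table.

    ``connections`` lists (pre_id, post_id, n_synapses); ``post_classes``
    maps post_id to a cell-class label (default "other").
    """

    name: str
    pre_type: str
    connections: Sequence[tuple[str, str, int]]
    post_classes: Mapping[str, str] = field(default_factory=dict)
    center: tuple[float, float, float] | None = None


def gen_synapse_table(
    glomeruli: Sequence[GlomerulusSpec],
    coordinate_spread: float = 1.0,
    separation: float = 10.0,
    seed: int = 20250115,
) -> pd.DataFrame:
    """Synthetic synapse table with planted partner structure and spatial blobs.

    Each glomerulus becomes an isotropic Gaussian blob of synapses
    (sd ``coordinate_spread``); blob centers are ``separation`` spreads
    apart along the x axis unless given explicitly.  Running the emitted
    table through partner allocation with filters disabled reproduces the
    planted synapse counts exactly; the ``glomerulus_true`` column carries
    the planted cluster label.
    """
    if not glomeruli:
        raise InvalidArgumentError("need at least one glomerulus spec")
    if coordinate_spread < 0:
        raise InvalidArgumentError("coordinate_spread must be >= 0")
    rng = _rng(seed, 3)
    rows = []
    for gi, spec in enumerate(glomeruli):
        center = (spec.center if spec.center is not None
                  else (gi * separation * max(coordinate_spread, 1e-9), 0.0, 0.0))
        for pre_id, post_id, count in spec.connections:
            if count < 0:
                raise InvalidArgumentError("synapse counts must be non-negative")
            coords = rng.normal(loc=center, scale=coordinate_spread, size=(count, 3))
            for x, y, z in coords:
                rows.append({
                    "pre_id": pre_id, "pre_type": spec.pre_type, "post_id": post_id,
                    "x": x, "y": y, "z": z,
                    "post_class": spec.post_classes.get(post_id, "other"),
                    "glomerulus_true": spec.name,
                })
    return pd.DataFrame(rows, columns=["pre_id", "pre_type", "post_id", "x", "y", "z",
                                       "post_class", "glomerulus_true"])


def gen_trajectories(
    n_flies: int = 10,
    arena_radius: float = 20.1,
    source_xy: tuple[float, float] = (10.0, 0.0),
    attraction: float = 0.0,
    stop_rate: float = 0.1,
    go_rate: float = 0.2,
    active_speed_mean: float = 8.0,
    active_speed_width: float = 3.0,
    turn_rate: float = 0.7,
    frames: int = 9000,
    frame_rate: float = 20.0,
    seed: int = 20250115,
    start_at_source: bool = False,
) -> TrajectorySet:
    """Stop/go biased correlated random walk in a circular arena.

    Flies alternate between stopped and active bouts (two-state Markov chain
    with per-second switching rates ``stop_rate`` and ``go_rate``).  Each
    active bout holds one speed drawn from the Gaussian density
    exp[-((v-b)/c)^2] with mean ``active_speed_mean`` and width
    ``active_speed_width`` (mm/s, truncated at 0) — walking flies keep a
    roughly constant pace within a bout, and bout-constant speeds are what a
    finite-difference speed estimate can recover.  Heading diffuses with
    ``turn_rate`` rad per sqrt-second (frame-rate independent; the default
    decorrelates heading over a couple of seconds), and ``attraction`` in
    [0, 1] steers the heading toward the odor source.  Walls reflect.  With
    zero attraction the long-run at-source occupancy approaches the area
    fraction of the threshold disc; with strong attraction it tends to 1.
    """
    if n_flies < 1 or frames < 2:
        raise InvalidArgumentError("need at least one fly and two frames")
    if np.hypot(*source_xy) > arena_radius:
        raise InvalidArgumentError("source must lie inside the arena")
    if not (0.0 <= attraction <= 1.0):
        raise InvalidArgumentError("attraction must lie in [0, 1]")
    rng = _rng(seed, 4)
    dt = 1.0 / frame_rate
    p_stop = 1.0 - np.exp(-stop_rate * dt)
    p_go = 1.0 - np.exp(-go_rate * dt)
    sx, sy = source_xy
    all_rows = []
    for fly in range(n_flies):
        if start_at_source:
            pos = np.array([sx, sy], float)
        else:
            r = arena_radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            pos = np.array([r * np.cos(th), r * np.sin(th)])
        heading = rng.uniform(0, 2 * np.pi)
        active = rng.uniform() < go_rate / (go_rate + stop_rate)

        def draw_bout_speed() -> float:
            # Gaussian density with width parameter c has sd = c/sqrt(2)
            v = rng.normal(active_speed_mean, active_speed_width / np.sqrt(2.0))
            return max(v, 0.0) / 10.0  # mm/s -> cm/s

        bout_speed = draw_bout_speed()
        turn_step_sd = turn_rate * np.sqrt(dt)
        xs = np.empty(frames)
        ys = np.empty(frames)
        for i in range(frames):
            xs[i], ys[i] = pos
            if active and rng.uniform() < p_stop:
                active = False
            elif not active and rng.uniform() < p_go:
                active = True
                bout_speed = draw_bout_speed()
            if not active:
                continue
            v = bout_speed
            heading += rng.normal(0.0, turn_step_sd)
            if attraction > 0.0:
                bearing = np.arctan2(sy - pos[1], sx - pos[0])
                diff = np.angle(np.exp(1j * (bearing - heading)))
                heading += attraction * diff
            step = v * dt * np.array([np.cos(heading), np.sin(heading)])
            pos = pos + step
            rad = np.hypot(*pos)
            if rad > arena_radius:  # reflect across the wall and turn around
                pos = pos * (2 * arena_radius - rad) / rad
                heading += np.pi
        t = np.arange(frames) * dt
        all_rows.append(pd.DataFrame({"fly": fly, "t_s": t, "x_cm": xs, "y_cm": ys}))
    df = pd.concat(all_rows, ignore_index=True)
    return TrajectorySet(positions=df, source_xy=source_xy,
                         arena_radius=arena_radius, frame_rate=frame_rate)
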