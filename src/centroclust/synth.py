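"""Seeded synthetic-fixture generators with ground-truth labels.

Every generator is a pure function of its spec (the seed lives inside the
spec), returns fixtures in the same shapes the analysis modules consume and
emits a truth table alongside.  Default noise levels (localization sigma
0.05 µm, FRAP sigma 0.02, Poisson + Gaussian camera noise) are documented
choices, not fitted values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .frap import FRAPTrace
from .motility import DIFFUSIVE, PROCESSIVE, STATIC, Track


def _spec_json(spec) -> str:
    return json.dumps(dataclasses.asdict(spec), indent=2, default=list)


# ---------------------------------------------------------------------- #
# FRAP traces


@dataclass
class FRAPSpec:
    """Single-exponential recovery with an immobile fraction.

    Ground truth: post-bleach floor ``F0``, rate ``k`` (from ``t_half``),
    plateau derived from the immobile fraction via
    plateau = F0 + (1 - immobile) * (1 - F0).
    """

    t_half_s: float = 9.92
    immobile_fraction: float = 0.70
    F0: float = 0.2
    n_traces: int = 100
    dt_s: float = 1.0
    t_max_s: float = 120.0
    n_prebleach: int = 5
    sigma: float = 0.02
    ref_bleach_rate: float = 0.001   # 1/s acquisition photobleaching of the reference
    background_level: float = 20.0
    reference_level: float = 200.0
    seed: int = 0

    @property
    def k(self) -> float:
        return float(np.log(2.0) / self.t_half_s)

    @property
    def plateau(self) -> float:
        return self.F0 + (1.0 - self.immobile_fraction) * (1.0 - self.F0)


def gen_frap_traces(spec: FRAPSpec) -> tuple[list[FRAPTrace], pd.DataFrame]:
    """Generate raw three-channel traces whose normalization recovers the
    noiseless model exactly at sigma = 0."""
    if spec.t_half_s <= 0 or spec.sigma < 0:
        raise ConfigurationError("t_half_s must be > 0 and sigma >= 0")
    if not (0.0 <= spec.immobile_fraction <= 1.0 and 0.0 <= spec.F0 < 1.0):
        raise ConfigurationError("fractions must lie in [0, 1] and F0 in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    t_pre = -spec.dt_s * np.arange(spec.n_prebleach, 0, -1)
    t_post = np.arange(0.0, spec.t_max_s + 0.5 * spec.dt_s, spec.dt_s)
    times = np.concatenate([t_pre, t_post])
    t_acq = times - times[0]  # acquisition clock for reference bleaching

    model = np.where(
        times < 0,
        1.0,
        spec.F0 + (spec.plateau - spec.F0) * (1.0 - np.exp(-spec.k * np.maximum(times, 0.0))),
    )
    traces = []
    rows = []
    for i in range(spec.n_traces):
        noisy = model + spec.sigma * rng.standard_normal(len(times))
        ref = spec.reference_level * np.exp(-spec.ref_bleach_rate * t_acq)
        bg = np.full(len(times), spec.background_level)
        roi = bg + (ref - bg) * noisy
        traces.append(
            FRAPTrace(
                times=times,
                roi_intensity=roi,
                background_intensity=bg,
                reference_intensity=ref,
                n_prebleach=spec.n_prebleach,
                trace_id=i,
            )
        )
        rows.append(
            {
                "trace_id": i,
                "F0": spec.F0,
                "plateau": spec.plateau,
                "k_per_s": spec.k,
                "t_half_s": spec.t_half_s,
                "mobile_fraction": 1.0 - spec.immobile_fraction,
                "immobile_fraction": spec.immobile_fraction,
            }
        )
    return traces, pd.DataFrame(rows)


def frap_traces_to_csv(traces: list[FRAPTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for j in range(len(tr.times)):
            rows.append(
                {
                    "trace_id": tr.trace_id,
                    "t_s": tr.times[j],
                    "roi": tr.roi_intensity[j],
                    "background": tr.background_intensity[j],
                    "reference": tr.reference_intensity[j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------- #
# particle tracks


@dataclass
class TrackSpec:
    """Mixture of processive / diffusive / static particle tracks.

    Processive tracks drift toward the minus end (decreasing x) at a
    per-track speed from Normal(speed_mean, speed_sd); when run-length
    parameters are given, the drift lasts run/speed seconds and the particle
    then parks.  Diffusive tracks are reflected random walks; static tracks
    show localization noise only.

    With ``stratified`` (default) the per-track speeds and run lengths form
    a quantile-stratified sample of their normal distributions, shuffled by
    the seed: every fixture is exactly representative (its sample mean is
    the population mean), so parameter-recovery results measure estimator
    error rather than draw luck.  Set ``stratified=False`` for iid draws.
    """

    n_tracks: int = 66
    frame_interval_s: float = 5.0
    n_frames: int = 24
    speed_mean: float = 0.055        # µm/s
    speed_sd: float = 0.016
    run_mean_um: float | None = None
    run_sd_um: float | None = None
    filament_length_um: float = 10.0
    sigma_loc: float = 0.05          # µm localization noise
    fractions: tuple = (1.0, 0.0, 0.0)   # processive, diffusive, static
    diffusion_um2_s: float = 0.002
    min_speed: float = 0.005         # µm/s floor when drawing speeds
    stratified: bool = True
    seed: int = 0


def gen_tracks(spec: TrackSpec) -> tuple[list[Track], pd.DataFrame]:
    """Generate tracks plus a truth table with per-frame labels.

    The truth table has one row per track: kind, true speed, realized
    (noise-free) run distance and the frame labels as a string.
    """
    if spec.speed_mean < 0 or spec.speed_sd < 0 or spec.sigma_loc < 0:
        raise ConfigurationError("speeds and noise levels must be >= 0")
    if abs(sum(spec.fractions) - 1.0) > 1e-9 or any(f < 0 for f in spec.fractions):
        raise ConfigurationError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval_s
    n = spec.n_frames
    t = dt * np.arange(n)
    kinds = rng.choice(
        [PROCESSIVE, DIFFUSIVE, STATIC], size=spec.n_tracks, p=list(spec.fractions)
    )

    def draw_pool(mean, sd):
        if spec.stratified:
            from scipy.stats import norm

            vals = mean + sd * norm.ppf((np.arange(spec.n_tracks) + 0.5) / spec.n_tracks)
            rng.shuffle(vals)
            return vals
        return rng.normal(mean, sd, size=spec.n_tracks)

    speed_pool = draw_pool(spec.speed_mean, spec.speed_sd)
    run_pool = (
        draw_pool(spec.run_mean_um, spec.run_sd_um or 0.0)
        if spec.run_mean_um is not None
        else None
    )

    tracks, rows = [], []
    for i in range(spec.n_tracks):
        kind = kinds[i]
        labels = np.full(n, STATIC, dtype=object)
        speed = 0.0
        run_true = 0.0
        L = spec.filament_length_um
        if kind == PROCESSIVE:
            speed = max(spec.min_speed, speed_pool[i])
            if run_pool is not None:
                run = max(0.5, run_pool[i])
                # long runs happen on long filaments; extend rather than clip,
                # which would truncate the upper tail and bias the mean down
                L = max(L, run + 1.0)
                n_drift = int(np.clip(round(run / (speed * dt)), 3, n - 1))
            else:
                n_drift = min(n - 1, max(3, int((L - 0.5) / (speed * dt))))
            run_true = n_drift * speed * dt
            x0 = run_true + rng.uniform(0.1, max(0.2, L - run_true - 0.1))
            x0 = min(x0, L)
            x = np.empty(n)
            x[: n_drift + 1] = x0 - speed * dt * np.arange(n_drift + 1)
            x[n_drift + 1 :] = x[n_drift]
            labels[: n_drift + 1] = PROCESSIVE
        elif kind == DIFFUSIVE:
            steps = rng.normal(0.0, np.sqrt(2.0 * spec.diffusion_um2_s * dt), size=n - 1)
            x = np.empty(n)
            x[0] = rng.uniform(0.2 * L, 0.8 * L)
            for j in range(1, n):
                nxt = x[j - 1] + steps[j - 1]
                if nxt < 0:
                    nxt = -nxt
                if nxt > L:
                    nxt = 2 * L - nxt
                x[j] = nxt
            labels[:] = DIFFUSIVE
        else:
            x = np.full(n, rng.uniform(0.1 * L, 0.9 * L))

        x_noisy = x + spec.sigma_loc * rng.standard_normal(n)
        tracks.append(Track(t=t, x=x_noisy, track_id=i, filament_length=L))
        rows.append(
            {
                "track_id": i,
                "kind": kind,
                "speed_um_s": speed,
                "run_um": run_true,
                "labels": ",".join(labels),
            }
        )
    return tracks, pd.DataFrame(rows)


def tracks_to_csv(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for j in range(tr.n_frames):
            rows.append({"track_id": tr.track_id, "t_s": tr.t[j], "x_um": tr.x[j]})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------- #
# droplet images


@dataclass
class DropletImageSpec:
    """Non-overlapping bright disks on a dilute background with camera noise."""

    shape: tuple = (256, 256)
    pixel_size_um: float = 0.1
    n_disks: int = 25
    radius_mean_px: float = 5.0
    radius_sd_px: float = 0.0
    partition: float = 50.0          # condensate/dilute intensity ratio
    dilute_level: float = 100.0      # photons per pixel in the dilute phase
    poisson_noise: bool = True
    readout_sigma: float = 2.0
    margin_px: int = 3
    max_retries: int = 2000
    seed: int = 0


def gen_droplet_image(spec: DropletImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the image (uint16) and return it with the disk truth table."""
    if spec.partition < 1.0:
        raise ConfigurationError("partition must be >= 1")
    if spec.n_disks < 0 or spec.radius_mean_px <= 0:
        raise ConfigurationError("invalid disk parameters")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]

    centers, radii = [], []
    tries = 0
    while len(centers) < spec.n_disks:
        if tries > spec.max_retries:
            raise ConfigurationError(
                f"could not place {spec.n_disks} non-overlapping disks in {spec.shape} "
                f"after {spec.max_retries} retries"
            )
        tries += 1
        r = max(1.5, rng.normal(spec.radius_mean_px, spec.radius_sd_px))
        cy = rng.uniform(r + spec.margin_px, h - r - spec.margin_px)
        cx = rng.uniform(r + spec.margin_px, w - r - spec.margin_px)
        if all(
            np.hypot(cy - py, cx - px) > r + pr + spec.margin_px
            for (py, px), pr in zip(centers, radii)
        ):
            centers.append((cy, cx))
            radii.append(r)

    clean = np.full(spec.shape, spec.dilute_level, dtype=float)
    for (cy, cx), r in zip(centers, radii):
        clean[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = spec.dilute_level * spec.partition

    img = rng.poisson(clean).astype(float) if spec.poisson_noise else clean.copy()
    if spec.readout_sigma > 0:
        img += spec.readout_sigma * rng.standard_normal(spec.shape)
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(
        {
            "disk_id": np.arange(len(centers)),
            "center_y_px": [c[0] for c in centers],
            "center_x_px": [c[1] for c in centers],
            "radius_px": radii,
            "partition": spec.partition,
        }
    )
    return img, truth


# ---------------------------------------------------------------------- #
# point sets


@dataclass
class PointSetSpec:
    """Gaussian blobs plus uniform background points in a circular arena."""

    n_clusters: int = 3
    points_per_cluster: int = 10
    cluster_sd_um: float = 0.5
    n_background: int = 10
    arena_radius_um: float = 20.0
    seed: int = 0


def gen_point_set(spec: PointSetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions (n, 2), labels) with label -1 for background points."""
    if spec.n_clusters < 0 or spec.points_per_cluster < 0 or spec.cluster_sd_um < 0:
        raise ConfigurationError("invalid point-set parameters")
    rng = np.random.default_rng(spec.seed)

    def uniform_disk(k):
        r = spec.arena_radius_um * np.sqrt(rng.uniform(size=k))
        th = rng.uniform(0, 2 * np.pi, size=k)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    pts, labels = [], []
    centers = uniform_disk(spec.n_clusters)
    for c in range(spec.n_clusters):
        blob = centers[c] + spec.cluster_sd_um * rng.standard_normal(
            (spec.points_per_cluster, 2)
        )
        pts.append(blob)
        labels.extend([c] * spec.points_per_cluster)
    if spec.n_background:
        pts.append(uniform_disk(spec.n_background))
        labels.extend([-1] * spec.n_background)
    positions = np.concatenate(pts) if pts else np.empty((0, 2))
    return positions, np.asarray(labels, dtype=np.int64)


# ---------------------------------------------------------------------- #
# fixture writing (CLI entry)

SPEC_KINDS = {
    "frap": FRAPSpec,
    "tracks": TrackSpec,
    "droplet_image": DropletImageSpec,
    "point_set": PointSetSpec,
}


def make_fixtures(kind: str, spec_overrides: dict, out_dir: str | Path) -> Path:
    """Generate one fixture set of the given kind into ``out_dir``.

    The spec JSON is written beside every fixture.
    """
    if kind not in SPEC_KINDS:
        raise ConfigurationError(f"unknown fixture kind {kind!r}; choose from {sorted(SPEC_KINDS)}")
    cls = SPEC_KINDS[kind]
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(spec_overrides) - known
    if unknown:
        raise ConfigurationError(f"unknown {kind} spec keys: {sorted(unknown)}")
    if "shape" in spec_overrides:
        spec_overrides["shape"] = tuple(spec_overrides["shape"])
    if "fractions" in spec_overrides:
        spec_overrides["fractions"] = tuple(spec_overrides["fractions"])
    spec = cls(**spec_overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spec.json").write_text(_spec_json(spec))

    if kind == "frap":
        traces, truth = gen_frap_traces(spec)
        frap_traces_to_csv(traces, out / "frap_traces.csv")
        truth.to_csv(out / "truth.csv", index=False)
    elif kind == "tracks":
        tracks, truth = gen_tracks(spec)
        tracks_to_csv(tracks, out / "tracks.csv")
        truth.to_csv(out / "truth.csv", index=False)
        pd.DataFrame(
            {
                "track_id": [tr.track_id for tr in tracks],
                "filament_length_um": [tr.filament_length for tr in tracks],
            }
        ).to_csv(out / "filament_lengths.csv", index=False)
    elif kind == "droplet_image":
        import tifffile

        img, truth = gen_droplet_image(spec)
        tifffile.imwrite(out / "droplets.tif", img)
        truth.to_csv(out / "truth.csv", index=False)
    else:
        positions, labels = gen_point_set(spec)
        pd.DataFrame(
            {
                "id": np.arange(len(positions)),
                "x_um": positions[:, 0],
                "y_um": positions[:, 1],
                "label": labels,
            }
        ).to_csv(out / "points.csv", index=False)
    return out
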