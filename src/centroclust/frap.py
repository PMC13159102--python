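"""FRAP trace normalization and single-exponential recovery fitting.

The raw trace carries three channels sampled at the same time points: the
bleached region of interest, a background region and an unbleached reference
region (to correct acquisition photobleaching).  Normalization is the double
normalization

    N(t) = [(ROI - bg) / (ref - bg)]  /  mean over pre-bleach frames,

so the pre-bleach mean of N is exactly 1.  The recovery model for t > 0 is

    N(t) = F0 + (plateau - F0) * (1 - exp(-k t)),

with t_half = ln2 / k, mobile fraction (plateau - F0) / (1 - F0) and
immobile fraction its complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError

#: frames whose reference drops below this fraction of its pre-bleach mean
#: are trimmed (catastrophic reference bleaching)
REFERENCE_FLOOR_FRACTION = 0.5
#: plateau rises this little above the floor -> rate unidentifiable
FLAT_AMPLITUDE_TOL = 1e-3


@dataclass
class FRAPTrace:
    """Raw three-channel FRAP recording; bleach occurs at t = 0."""

    times: np.ndarray
    roi_intensity: np.ndarray
    background_intensity: np.ndarray
    reference_intensity: np.ndarray
    n_prebleach: int
    trace_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("roi_intensity", "background_intensity", "reference_intensity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} length must match times")
            setattr(self, name, arr)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach < 3:
            raise ValueError("need >= 3 pre-bleach frames")
        if len(self.times) - self.n_prebleach < 10:
            raise ValueError("need >= 10 post-bleach frames")


@dataclass
class FRAPFit:
    F0: float
    plateau: float
    k: float                    # 1/s
    t_half: float               # s, ln2/k
    mobile_fraction: float
    immobile_fraction: float
    residual_rms: float
    flat: bool = False          # True when the rate was unidentifiable

    def to_dict(self) -> dict:
        return {
            "F0": self.F0,
            "plateau": self.plateau,
            "k_per_s": self.k,
            "t_half_s": self.t_half,
            "mobile_fraction": self.mobile_fraction,
            "immobile_fraction": self.immobile_fraction,
            "residual_rms": self.residual_rms,
            "flat": self.flat,
        }


def normalize_trace(trace: FRAPTrace) -> tuple[np.ndarray, np.ndarray]:
    """Double-normalize a raw trace.  Returns (times, N).

    Frames where the reference has collapsed below
    ``REFERENCE_FLOOR_FRACTION`` of its pre-bleach mean are trimmed with a
    warning; a non-positive (reference - background) anywhere else is an
    error naming the frame.
    """
    denom = trace.reference_intensity - trace.background_intensity
    ref_pre = float(np.mean(trace.reference_intensity[: trace.n_prebleach]))
    collapsed = trace.reference_intensity < REFERENCE_FLOOR_FRACTION * ref_pre
    if np.any(collapsed):
        warnings.warn(
            f"trimming {int(np.sum(collapsed))} frames with reference below "
            f"{REFERENCE_FLOOR_FRACTION:.0%} of its pre-bleach mean"
        )
    keep = ~collapsed
    bad = np.nonzero((denom <= 0) & keep)[0]
    if len(bad):
        raise ValueError(
            f"reference - background is non-positive at frame {int(bad[0])}"
        )
    ratio = (trace.roi_intensity - trace.background_intensity) / denom
    pre = ratio[: trace.n_prebleach]
    pre = pre[keep[: trace.n_prebleach]]
    if len(pre) == 0:
        raise ValueError("all pre-bleach frames were trimmed")
    scale = float(np.mean(pre))
    if scale <= 0:
        raise ValueError("pre-bleach mean of the corrected ratio is non-positive")
    return trace.times[keep], ratio[keep] / scale


def _recovery(t, F0, plateau, k):
    return F0 + (plateau - F0) * (1.0 - np.exp(-k * t))


def fit_recovery(times: np.ndarray, normalized: np.ndarray) -> FRAPFit:
    """Fit the post-bleach portion (t >= 0) of a normalized recovery curve.

    Bounds: F0 in [0, 1], plateau in [F0, 1.2], k > 0.  Initialization is
    deterministic: F0 from the first post-bleach point, plateau from the
    final 10% of points, k from a log-linear regression of (plateau - N).
    A flat trace (plateau indistinguishable from the floor) is returned with
    ``flat=True``, zero mobile fraction and an undefined rate rather than
    raising.
    """
    times = np.asarray(times, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    post = times >= 0
    t = times[post]
    y = normalized[post]
    if len(t) < 4:
        raise FitError("too few post-bleach points to fit")

    F0_init = float(np.clip(y[0], 0.0, 1.0))
    n_tail = max(3, len(y) // 10)
    plateau_init = float(np.clip(np.mean(y[-n_tail:]), F0_init, 1.2))

    if plateau_init - F0_init < FLAT_AMPLITUDE_TOL:
        resid = y - np.mean(y)
        return FRAPFit(
            F0=F0_init,
            plateau=plateau_init,
            k=float("nan"),
            t_half=float("nan"),
            mobile_fraction=(plateau_init - F0_init) / (1.0 - F0_init)
            if F0_init < 1
            else 0.0,
            immobile_fraction=1.0
            - ((plateau_init - F0_init) / (1.0 - F0_init) if F0_init < 1 else 0.0),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            flat=True,
        )

    # log-linear rate guess on the decaying gap to the plateau
    gap = plateau_init - y
    ok = (gap > 1e-6) & (t > 0)
    if np.sum(ok) >= 2:
        slope = np.polyfit(t[ok], np.log(gap[ok]), 1)[0]
        k_init = max(1e-4, -float(slope))
    else:
        k_init = 1.0 / max(t[-1], 1.0)

    p0 = (F0_init, plateau_init, k_init)
    try:
        popt, _ = curve_fit(
            _recovery,
            t,
            y,
            p0=p0,
            bounds=([0.0, 0.0, 1e-6], [1.0, 1.2, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"recovery fit did not converge: {exc}", p0=p0) from exc
    F0, plateau, k = (float(v) for v in popt)
    plateau = max(plateau, F0)
    resid = y - _recovery(t, F0, plateau, k)
    mobile = (plateau - F0) / (1.0 - F0) if F0 < 1.0 else 0.0
    mobile = float(np.clip(mobile, 0.0, 1.0))
    return FRAPFit(
        F0=F0,
        plateau=plateau,
        k=k,
        t_half=float(np.log(2.0) / k),
        mobile_fraction=mobile,
        immobile_fraction=1.0 - mobile,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_trace(trace: FRAPTrace) -> FRAPFit:
    """Normalize then fit one raw trace."""
    t, n = normalize_trace(trace)
    return fit_recovery(t, n)


# ---------------------------------------------------------------------- #
# table I/O


def read_traces(path: str | Path, n_prebleach: int = 5) -> list[FRAPTrace]:
    """Read traces from CSV (t_s, roi, background, reference[, trace_id]).

    The bleach is at t = 0; pre-bleach frames have negative times.  If no
    negative times are present, the first ``n_prebleach`` frames are taken
    as pre-bleach and times are shifted so the bleach lands at t = 0.
    """
    df = pd.read_csv(path)
    if "trace_id" not in df.columns:
        df = df.assign(trace_id=0)
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("t_s")
        times = grp["t_s"].to_numpy(dtype=float)
        npre = int(np.sum(times < 0))
        if npre == 0:
            npre = n_prebleach
            times = times - times[npre]
        traces.append(
            FRAPTrace(
                times=times,
                roi_intensity=grp["roi"].to_numpy(),
                background_intensity=grp["background"].to_numpy(),
                reference_intensity=grp["reference"].to_numpy(),
                n_prebleach=npre,
                trace_id=int(tid),
            )
        )
    return traces


def fits_to_frame(traces: list[FRAPTrace]) -> pd.DataFrame:
    rows = []
    for trace in traces:
        d = fit_trace(trace).to_dict()
        d["trace_id"] = trace.trace_id
        rows.append(d)
    return pd.DataFrame(rows)


def plot_fit(trace: FRAPTrace, fit: FRAPFit, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, n = normalize_trace(trace)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t, n, ".", ms=3, label="normalized")
    if not fit.flat:
        tt = np.linspace(0, t.max(), 200)
        ax.plot(tt, _recovery(tt, fit.F0, fit.plateau, fit.k), "-", label="fit")
        ax.set_title(f"t½ = {fit.t_half:.2f} s, immobile = {fit.immobile_fraction:.1%}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
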