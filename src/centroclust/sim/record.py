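"""Run records: timestamped snapshots plus provenance, with disk round-trip.

On disk a record is one directory:

* ``config.json``    — echo of the full configuration
* ``snapshots.csv``  — columns ``time_s, complex_id, x_um, y_um``
* ``filaments.csv``  — columns ``time_s, filament_id, minus_x_um, minus_y_um``
* ``hands.csv``      — motor-hand bookkeeping (bound filament id, abscissa)
* ``meta.json``      — seed, package version, runtime, provenance, failure flag
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import MissingSnapshotError
from .config import SimConfig


@dataclass
class SimRecord:
    config: SimConfig
    seed: int
    times: list[float] = field(default_factory=list)
    complex_positions: list[np.ndarray] = field(default_factory=list)
    minus_ends: list[np.ndarray] = field(default_factory=list)
    motor_fil: list[np.ndarray] = field(default_factory=list)
    motor_abs: list[np.ndarray] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    failed: bool = False
    runtime_s: float = 0.0

    def add_snapshot(self, time, cx_pos, minus_ends, motor_fil=None, motor_abs=None):
        if self.times and time <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(float(time))
        self.complex_positions.append(np.asarray(cx_pos, dtype=float).copy())
        self.minus_ends.append(np.asarray(minus_ends, dtype=float).copy())
        n = len(self.complex_positions[-1])
        self.motor_fil.append(
            np.asarray(motor_fil).copy() if motor_fil is not None else np.full(n, -1, dtype=np.int64)
        )
        self.motor_abs.append(
            np.asarray(motor_abs, dtype=float).copy() if motor_abs is not None else np.zeros(n)
        )

    def snapshot_at(self, time_s: float, atol: float = 1e-6) -> np.ndarray:
        """Complex positions at the snapshot closest to ``time_s`` within ``atol``."""
        for t, pos in zip(self.times, self.complex_positions):
            if abs(t - time_s) <= atol:
                return pos
        raise MissingSnapshotError(time_s)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.config.to_dict(), sort_keys=True).encode())
        h.update(np.asarray(self.times).tobytes())
        for pos, me in zip(self.complex_positions, self.minus_ends):
            h.update(np.ascontiguousarray(pos).tobytes())
            h.update(np.ascontiguousarray(me).tobytes())
        return h.hexdigest()

    # -- disk round trip ------------------------------------------------ #

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.save(out / "config.json")

        rows = []
        for t, pos in zip(self.times, self.complex_positions):
            for cid, (x, y) in enumerate(pos):
                rows.append((t, cid, x, y))
        pd.DataFrame(rows, columns=["time_s", "complex_id", "x_um", "y_um"]).to_csv(
            out / "snapshots.csv", index=False
        )

        rows = []
        for t, me in zip(self.times, self.minus_ends):
            for fid, (x, y) in enumerate(me):
                rows.append((t, fid, x, y))
        pd.DataFrame(
            rows, columns=["time_s", "filament_id", "minus_x_um", "minus_y_um"]
        ).to_csv(out / "filaments.csv", index=False)

        rows = []
        for t, mf, ma in zip(self.times, self.motor_fil, self.motor_abs):
            for cid in range(len(mf)):
                rows.append((t, cid, int(mf[cid]), ma[cid]))
        pd.DataFrame(
            rows, columns=["time_s", "complex_id", "motor_filament", "motor_abscissa_um"]
        ).to_csv(out / "hands.csv", index=False)

        from .. import __version__

        meta = {
            "seed": self.seed,
            "version": __version__,
            "runtime_s": self.runtime_s,
            "failed": self.failed,
            "provenance": self.provenance,
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
        return out

    @classmethod
    def load(cls, run_dir: str | Path) -> "SimRecord":
        run_dir = Path(run_dir)
        config = SimConfig.load(run_dir / "config.json")
        meta = json.loads((run_dir / "meta.json").read_text())
        rec = cls(
            config=config,
            seed=meta["seed"],
            provenance=meta.get("provenance", {}),
            failed=meta.get("failed", False),
            runtime_s=meta.get("runtime_s", 0.0),
        )
        snaps = pd.read_csv(run_dir / "snapshots.csv")
        fils = pd.read_csv(run_dir / "filaments.csv")
        hands_path = run_dir / "hands.csv"
        hands = pd.read_csv(hands_path) if hands_path.exists() else None
        all_times = sorted(set(snaps["time_s"]).union(fils["time_s"]))
        for t in all_times:
            grp = snaps[np.isclose(snaps["time_s"], t)].sort_values("complex_id")
            f = fils[np.isclose(fils["time_s"], t)].sort_values("filament_id")
            mf = ma = None
            if hands is not None:
                h = hands[np.isclose(hands["time_s"], t)].sort_values("complex_id")
                if len(h):
                    mf = h["motor_filament"].to_numpy()
                    ma = h["motor_abscissa_um"].to_numpy()
            rec.add_snapshot(
                t,
                grp[["x_um", "y_um"]].to_numpy().reshape(-1, 2),
                f[["minus_x_um", "minus_y_um"]].to_numpy().reshape(-1, 2),
                mf,
                ma,
            )
        return rec
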