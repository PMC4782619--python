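"""Neighbouring (adjacent) current-injection protocol and measurement frames.

A scan drives current through each adjacent electrode pair in turn — one
"projection" per pair, N projections for N electrodes — and records boundary
voltages in one of two modes:

* ``differential`` (Brown–Segar): the voltage difference across every
  adjacent electrode pair that touches neither current electrode; for 16
  electrodes that is 13 channels per projection, 16 x 13 = 208 values.
* ``grounded`` (Cheng): the potential of every electrode against the common
  ground, 16 channels per projection, 16 x 16 = 256 values.

Electrode labels are 1-based (E1..E16) in all user-facing I/O; internal node
arrays are 0-based.  Frames are projection-major: all channels of P1, then
P2, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import ElectrodeSet, TriMesh

__all__ = [
    "Projection",
    "MeasurementFrame",
    "neighbouring_projections",
    "brown_segar_channels",
    "run_scan",
    "differential_from_grounded",
]

MODES = ("grounded", "differential")


@dataclass(frozen=True)
class Projection:
    """One current projection: drive the (source, sink) adjacent pair.

    Electrode numbers are 1-based; projection ``p`` drives (E_p, E_{p+1})
    with wraparound, so P16 drives (E16, E1).
    """

    index: int
    source: int
    sink: int
    n_electrodes: int = 16

    @property
    def channels(self) -> tuple[tuple[int, int], ...]:
        """Differential measurement pairs for this projection."""
        return brown_segar_channels(self, self.n_electrodes)


def neighbouring_projections(n_electrodes: int = 16) -> list[Projection]:
    """All adjacent-drive projections of an ``n_electrodes`` system."""
    n = int(n_electrodes)
    if n < 4:
        raise ValueError(f"neighbouring protocol needs >= 4 electrodes, got {n}")
    return [
        Projection(index=p, source=p, sink=p % n + 1, n_electrodes=n)
        for p in range(1, n + 1)
    ]


def brown_segar_channels(
    projection: Projection, n_electrodes: int = 16
) -> tuple[tuple[int, int], ...]:
    """Ordered differential channels of one projection.

    For drive (E_s, E_{s+1}) the channels are the ``n - 3`` adjacent pairs
    (E_{s+2}, E_{s+3}), ..., (E_{s+n-2}, E_{s+n-1}) with wraparound —
    every adjacent pair that contains no current electrode, starting just
    past the sink.  Sign convention: V = phi(first) - phi(second).
    """
    n = int(n_electrodes)
    if n < 4:
        raise ValueError(f"need >= 4 electrodes, got {n}")
    s = projection.source  # 1-based
    pairs = []
    for k in range(2, n - 1):
        a = (s - 1 + k) % n + 1
        b = (s + k) % n + 1
        pairs.append((a, b))
    return tuple(pairs)


@dataclass(frozen=True)
class MeasurementFrame:
    """Ordered boundary-data vector of one complete scan.

    ``values`` is projection-major; ``projection`` holds the 1-based
    projection index of each entry and ``channel`` its label — ``"E5"`` for a
    grounded potential, ``"E3-E4"`` for a differential pair.
    """

    values: np.ndarray
    mode: str
    n_electrodes: int
    projection: np.ndarray = field(repr=False)
    channel: tuple[str, ...] = field(repr=False)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        values = np.asarray(self.values, dtype=float)
        m = self.channels_per_projection
        expected = self.n_electrodes * m
        if values.shape != (expected,):
            raise ValueError(
                f"{self.mode} frame for {self.n_electrodes} electrodes must have "
                f"{expected} values, got shape {values.shape}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "projection", np.asarray(self.projection, dtype=np.int64)
        )

    @property
    def channels_per_projection(self) -> int:
        return self.n_electrodes if self.mode == "grounded" else self.n_electrodes - 3

    def __len__(self) -> int:
        return len(self.values)

    def block(self, projection_index: int) -> np.ndarray:
        """Channel values of one projection (1-based index)."""
        m = self.channels_per_projection
        i = projection_index - 1
        return self.values[i * m : (i + 1) * m]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "projection": self.projection,
                "channel": list(self.channel),
                "value_volts": self.values,
            }
        )

    def to_csv(self, path) -> None:
        """Write the frame as CSV; values round-trip bit-exactly."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "MeasurementFrame":
        df = pd.read_csv(path, float_precision="round_trip")
        channels = tuple(str(c) for c in df["channel"])
        mode = "differential" if "-" in channels[0] else "grounded"
        n_proj = int(df["projection"].max())
        return cls(
            values=df["value_volts"].to_numpy(dtype=float),
            mode=mode,
            n_electrodes=n_proj,
            projection=df["projection"].to_numpy(dtype=np.int64),
            channel=channels,
        )


def frame_labels(
    projections: list[Projection], mode: str, n_electrodes: int
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Projection-index array and channel labels of a full scan, in order."""
    proj_idx, labels = [], []
    for proj in projections:
        if mode == "grounded":
            chans = [f"E{e}" for e in range(1, n_electrodes + 1)]
        else:
            chans = [f"E{a}-E{b}" for a, b in brown_segar_channels(proj, n_electrodes)]
        proj_idx.extend([proj.index] * len(chans))
        labels.extend(chans)
    return np.asarray(proj_idx, dtype=np.int64), tuple(labels)


def run_scan(
    mesh: TriMesh,
    conductivity,
    electrodes: ElectrodeSet,
    mode: str = "grounded",
    amplitude: float = 1e-3,
    noise_sd: float = 0.0,
    rng=None,
) -> MeasurementFrame:
    """Simulate one complete neighbouring-protocol scan.

    Assembles the FEM system once, solves all projections against a single
    factorization and extracts the boundary data in the requested mode.
    Optionally adds i.i.d. Gaussian noise of standard deviation ``noise_sd``
    volts (off by default; ``rng`` may be a seed or a Generator).

    Parameters
    ----------
    conductivity : ConductivityMap or per-element array, S/m.
    amplitude : drive current in amperes (default 1 mA).
    """
    from .forward import (
        assemble_stiffness,
        current_matrix,
        extract_electrode_potentials,
        solve_forward,
    )

    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    projections = neighbouring_projections(electrodes.n_electrodes)
    system = assemble_stiffness(mesh, conductivity)
    c = current_matrix(mesh.n_nodes, electrodes, projections, amplitude)
    m_np = solve_forward(system, c)
    frame = extract_electrode_potentials(m_np, electrodes, mode, projections)
    if noise_sd:
        gen = np.random.default_rng(rng)
        noisy = frame.values + gen.normal(0.0, noise_sd, size=len(frame))
        frame = MeasurementFrame(
            values=noisy,
            mode=frame.mode,
            n_electrodes=frame.n_electrodes,
            projection=frame.projection,
            channel=frame.channel,
        )
    return frame


def differential_from_grounded(frame: MeasurementFrame) -> MeasurementFrame:
    """Exact linear conversion of a grounded frame to Brown–Segar form.

    Each differential channel (Ea, Eb) is the difference of the two grounded
    potentials of the same projection; the result is identical to extracting
    the differential frame directly.
    """
    if frame.mode != "grounded":
        raise ValueError("input frame must be in grounded mode")
    n = frame.n_electrodes
    projections = neighbouring_projections(n)
    values = []
    for proj in projections:
        block = frame.block(proj.index)
        for a, b in brown_segar_channels(proj, n):
            values.append(block[a - 1] - block[b - 1])
    proj_idx, labels = frame_labels(projections, "differential", n)
    return MeasurementFrame(
        values=np.asarray(values),
        mode="differential",
        n_electrodes=n,
        projection=proj_idx,
        channel=labels,
    )
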