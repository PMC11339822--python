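"""Trajectory stability metrics: RMSD series, rolling smoothing, RMSF.

RMSD is computed after optimal rigid superposition of a fit selection onto a
reference structure (matched atom-by-atom on chain/resid/name), either for the
whole assembly at once or independently per tile. Equilibration is handled by
an explicit time cut supplied by the user — the convention being that the
equilibration window is judged from the RMSD curve, not auto-detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import superpose
from .structure_io import Selection, Structure, Trajectory, select

__all__ = [
    "MetricSeries",
    "rmsd_series",
    "rmsd_series_per_tile",
    "rolling_mean",
    "rmsf",
    "equilibration_mask",
]


@dataclass
class MetricSeries:
    """A labelled time series of a scalar metric (times ns, values Angstrom)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, self.label or "value": self.values})


def _match_reference(
    topology: Structure, ref: Structure, indices: np.ndarray
) -> np.ndarray:
    """Map topology atom indices onto reference indices via (chain, resid, name)."""
    ref_lookup = {
        (str(ref.chains[i]), int(ref.resids[i]), str(ref.names[i])): i
        for i in range(ref.n_atoms)
    }
    out = np.empty(len(indices), dtype=int)
    for j, i in enumerate(indices):
        key = (str(topology.chains[i]), int(topology.resids[i]), str(topology.names[i]))
        if key not in ref_lookup:
            raise ValueError(
                f"atom {key} from the trajectory has no match in the reference"
            )
        out[j] = ref_lookup[key]
    return out


def rmsd_series(
    traj: Trajectory,
    sel: Selection | str,
    ref: Structure,
    fit_sel: Selection | str | None = None,
    label: str = "rmsd",
) -> MetricSeries:
    """Per-frame RMSD (Angstrom) over ``sel`` after superposing ``fit_sel``.

    ``fit_sel`` defaults to ``sel``. Atoms are matched to the reference by
    (chain, resid, name); a missing match is an error naming the first
    offending atom.
    """
    sel_idx = select(traj.topology, sel)
    fit_idx = select(traj.topology, fit_sel) if fit_sel is not None else sel_idx
    if sel_idx.size == 0 or fit_idx.size == 0:
        raise ValueError("empty selection for RMSD")
    ref_sel = _match_reference(traj.topology, ref, sel_idx)
    ref_fit = _match_reference(traj.topology, ref, fit_idx)

    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        tr, _ = superpose(traj.coords[f][fit_idx], ref.coords[ref_fit])
        moved = tr.apply(traj.coords[f][sel_idx])
        diff = moved - ref.coords[ref_sel]
        values[f] = np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff)))
    return MetricSeries(times=traj.times.copy(), values=values, label=label)


def rmsd_series_per_tile(
    traj: Trajectory,
    tiles: dict[str, Selection | str],
    ref: Structure,
) -> dict[str, MetricSeries]:
    """RMSD series with each tile fitted independently to its own reference."""
    return {
        name: rmsd_series(traj, sel, ref, fit_sel=sel, label=name)
        for name, sel in tiles.items()
    }


def rolling_mean(series: MetricSeries, window: int = 5) -> MetricSeries:
    """Trailing rolling-window mean; the first window-1 points average the
    available prefix, so length is preserved and no future frames leak in."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > series.values.size:
        raise ValueError(
            f"window {window} exceeds series length {series.values.size}"
        )
    smoothed = (
        pd.Series(series.values).rolling(window, min_periods=1).mean().to_numpy()
    )
    return MetricSeries(
        times=series.times.copy(),
        values=smoothed,
        label=f"{series.label}_smoothed" if series.label else "smoothed",
        smoothing_window=window,
    )


def equilibration_mask(traj: Trajectory, cut: float) -> np.ndarray:
    """Frame indices at or after the equilibration cut (ns)."""
    if cut < 0:
        raise ValueError("equilibration cut must be non-negative")
    if cut > traj.times[-1]:
        raise ValueError(
            f"equilibration cut {cut} ns beyond final frame time {traj.times[-1]} ns"
        )
    return np.flatnonzero(traj.times >= cut)


def rmsf(
    traj: Trajectory,
    sel: Selection | str,
    equil_cut: float = 0.0,
    fit_sel: Selection | str | None = None,
) -> pd.DataFrame:
    """Per-atom root-mean-square fluctuation (Angstrom) about the time mean.

    Frames before ``equil_cut`` are excluded. Every retained frame is first
    superposed (over ``fit_sel``, default ``sel``) onto the initial trajectory
    frame, which makes the result invariant to global rigid motion.

    Returns a DataFrame with columns chain, resid, resname, name, rmsf.
    """
    mask = equilibration_mask(traj, equil_cut)
    if mask.size < 2:
        raise ValueError("need at least 2 frames after the equilibration cut")
    sel_idx = select(traj.topology, sel)
    if sel_idx.size == 0:
        raise ValueError("empty selection for RMSF")
    fit_idx = select(traj.topology, fit_sel) if fit_sel is not None else sel_idx

    ref_fit = traj.coords[0][fit_idx]
    aligned = np.empty((mask.size, sel_idx.size, 3))
    for j, f in enumerate(mask):
        tr, _ = superpose(traj.coords[f][fit_idx], ref_fit)
        aligned[j] = tr.apply(traj.coords[f][sel_idx])
    mean_pos = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))

    top = traj.topology
    return pd.DataFrame(
        {
            "chain": [str(top.chains[i]) for i in sel_idx],
            "resid": [int(top.resids[i]) for i in sel_idx],
            "resname": [str(top.resnames[i]) for i in sel_idx],
            "name": [str(top.names[i]) for i in sel_idx],
            "rmsf": fluct,
        }
    )
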