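"""HOLE-style pore-radius profiling along a channel axis.

In each plane perpendicular to the channel axis, the pore radius is the
radius of the largest sphere centred in that plane that overlaps no
vdW-inflated atom: the maximum over in-plane centres p of
f(p) = min_i (||p - x_i|| - R_i), with 3D distances to atoms. The maximum is
located by an improvement-only Monte-Carlo search with a geometrically
shrinking step (simulated-annealing style), marching plane by plane and
seeding each plane's search from the previous plane's centre so that bent
channels are followed.

No periodic imaging is applied: the pore interior of a shell-protein tile
never crosses the simulation box in the systems this targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure_io import Selection, Structure, Trajectory, select

__all__ = ["PoreParams", "PoreProfile", "PoreStats", "pore_radius_at", "pore_profile", "profile_stats"]


@dataclass(frozen=True)
class PoreParams:
    """Parameters of the pore search.

    ``axis`` is the channel direction; ``seed_point`` the starting centre
    (default: geometric centre of the selection); ``z_range`` the march limits
    in Angstrom relative to the seed; ``max_radius`` the escape cap marking
    the pore mouth; ``mc_*`` control the Monte-Carlo maximisation.
    """

    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    seed_point: np.ndarray | None = None
    z_range: tuple[float, float] = (-15.0, 15.0)
    z_step: float = 0.25
    max_radius: float = 15.0
    mc_steps: int = 1000
    mc_initial_step: float = 0.5
    mc_decay: float = 0.9
    mc_levels: int = 40
    mc_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.max_radius <= 0:
            raise ValueError("max_radius must be positive")
        if self.z_range[1] < self.z_range[0]:
            raise ValueError("z_range must be (low, high)")
        axis = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", axis / np.linalg.norm(axis))
        if self.seed_point is not None:
            object.__setattr__(
                self, "seed_point", np.asarray(self.seed_point, dtype=float)
            )


@dataclass
class PoreProfile:
    """Radius-vs-z profile for one frame; centres track the channel path."""

    z: np.ndarray
    radius: np.ndarray
    centers: np.ndarray  # (n, 2) in-plane coordinates
    escaped: np.ndarray  # True where the search exceeded max_radius
    frame: int = 0

    def bottleneck(self) -> tuple[float, float]:
        """(min radius, z of the minimum) over non-escaped planes."""
        valid = ~self.escaped
        if not valid.any():
            return float("nan"), float("nan")
        i = int(np.argmin(np.where(valid, self.radius, np.inf)))
        return float(self.radius[i]), float(self.z[i])


@dataclass
class PoreStats:
    """Per-z envelopes across frames plus per-frame bottleneck records."""

    z: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    min: np.ndarray
    max: np.ndarray
    bottlenecks: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z,
                "mean": self.mean,
                "median": self.median,
                "min": self.min,
                "max": self.max,
            }
        )


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(ref, axis))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _clearance(p: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> float:
    """f(p) = min_i ||p - x_i|| - R_i (3D distances; sphere fits iff f > 0)."""
    d = np.sqrt(np.sum((coords - p) ** 2, axis=1))
    return float(np.min(d - radii))


def pore_radius_at(
    frame: Structure,
    sel: Selection | str,
    point: np.ndarray,
    params: PoreParams = PoreParams(),
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray, bool]:
    """Largest-sphere radius centred in the plane through ``point``.

    Maximises the clearance f(p) over in-plane displacements from the seed by
    an improvement-only Monte-Carlo search with geometric step decay (several
    deterministic restarts, best result kept). Returns
    (radius, in-plane centre as a 3-vector, escaped) where ``escaped`` flags
    radius > max_radius (pore mouth). A non-positive radius means the plane
    is closed at the seed (the search never found open space).
    """
    idx = select(frame, sel)
    if idx.size == 0:
        raise ValueError("empty selection for pore search")
    coords = frame.coords[idx]
    radii = frame.radii[idx]
    if np.any(radii <= 0):
        raise ValueError("pore search requires positive vdW radii")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    point = np.asarray(point, dtype=float)
    u, v = _plane_basis(params.axis)

    per_level = max(params.mc_steps // params.mc_levels, 1)
    best_p = point
    best_f = _clearance(point, coords, radii)
    for _ in range(max(params.mc_restarts, 1)):
        p = point
        fp = _clearance(point, coords, radii)
        step = params.mc_initial_step
        for _level in range(params.mc_levels):
            for _ in range(per_level):
                ang = rng.uniform(0.0, 2.0 * np.pi)
                rad = step * np.sqrt(rng.uniform())
                cand = p + rad * (np.cos(ang) * u + np.sin(ang) * v)
                fc = _clearance(cand, coords, radii)
                if fc > fp:
                    p, fp = cand, fc
            step *= params.mc_decay
            if fp > params.max_radius:
                break
        if fp > best_f:
            best_p, best_f = p, fp
        if best_f > params.max_radius:
            break
    return best_f, best_p, best_f > params.max_radius


def pore_profile(
    frame: Structure,
    sel: Selection | str,
    params: PoreParams = PoreParams(),
    frame_index: int = 0,
    rng: np.random.Generator | None = None,
) -> PoreProfile:
    """March the pore search along the axis, following the channel centre.

    Planes are spaced ``z_step`` apart within ``z_range`` around the seed
    point; each plane's search starts from the previous plane's optimal
    centre. Marching in a direction stops early once the radius exceeds
    ``max_radius`` (the pore mouth); that plane is recorded with the escape
    flag set.
    """
    idx = select(frame, sel)
    if idx.size == 0:
        raise ValueError("empty selection for pore profile")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seed_point = (
        params.seed_point
        if params.seed_point is not None
        else frame.coords[idx].mean(axis=0)
    )
    axis = params.axis
    u, v = _plane_basis(axis)
    lo, hi = params.z_range
    offsets_up = np.arange(0.0, hi + 1e-9, params.z_step)
    offsets_down = -np.arange(params.z_step, -lo + 1e-9, params.z_step)

    results: dict[float, tuple[float, np.ndarray, bool]] = {}
    for offsets in (offsets_up, offsets_down):
        start = seed_point
        for dz in offsets:
            plane_point = start + axis * (
                dz - float(np.dot(start - seed_point, axis))
            )
            r, center, escaped = pore_radius_at(frame, sel, plane_point, params, rng=rng)
            results[float(dz)] = (r, center, escaped)
            if escaped:
                break
            start = center

    zs = np.array(sorted(results))
    radius = np.array([results[z][0] for z in zs])
    centers3d = np.array([results[z][1] for z in zs])
    escaped = np.array([results[z][2] for z in zs])
    rel = centers3d - seed_point
    centers2d = np.column_stack([rel @ u, rel @ v])
    return PoreProfile(
        z=zs, radius=radius, centers=centers2d, escaped=escaped, frame=frame_index
    )


def profile_stats(
    traj: Trajectory,
    sel: Selection | str,
    params: PoreParams = PoreParams(),
    mask: np.ndarray | None = None,
) -> PoreStats:
    """Per-z mean/median/min/max pore radius across frames, plus bottlenecks.

    The seed point is fixed (default: selection centre of the first masked
    frame) so all frames share one z grid; planes beyond a frame's escape
    point are treated as missing for that frame.
    """
    mask = np.arange(traj.n_frames) if mask is None else np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("no frames in mask")
    if params.seed_point is None:
        idx = select(traj.topology, sel)
        seed_point = traj.coords[mask[0]][idx].mean(axis=0)
        params = replace(params, seed_point=seed_point)

    lo, hi = params.z_range
    grid = np.concatenate(
        [
            -np.arange(params.z_step, -lo + 1e-9, params.z_step)[::-1],
            np.arange(0.0, hi + 1e-9, params.z_step),
        ]
    )
    per_frame = []
    bottle_rows = []
    for f in mask:
        prof = pore_profile(
            traj.frame(f),
            sel,
            params,
            frame_index=int(f),
            rng=np.random.default_rng((int(params.seed) * 100003 + int(f)) % 2**31),
        )
        per_frame.append(prof)
        r, z_at = prof.bottleneck()
        bottle_rows.append(dict(frame=int(f), time_ns=float(traj.times[f]), radius=r, z=z_at))

    values = np.full((len(per_frame), grid.size), np.nan)
    for fi, prof in enumerate(per_frame):
        pos = np.searchsorted(grid, prof.z - 1e-9)
        ok = ~prof.escaped
        values[fi, pos[ok]] = prof.radius[ok]

    keep = ~np.all(np.isnan(values), axis=0)
    values = values[:, keep]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        stats = PoreStats(
            z=grid[keep],
            mean=np.nanmean(values, axis=0),
            median=np.nanmedian(values, axis=0),
            min=np.nanmin(values, axis=0),
            max=np.nanmax(values, axis=0),
            bottlenecks=pd.DataFrame(bottle_rows),
        )
    return stats
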