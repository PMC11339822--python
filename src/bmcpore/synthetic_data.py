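"""Synthetic inputs with analytically known answers for every pipeline stage.

Each generator returns both the data and its ground truth, and the ground
truth is computed directly from the generating script (ring algebra, the
scripted distances, the closed-form exponential) — never by calling the
analysis modules under test.

Generators are pure functions of their spec; all randomness sits behind
explicit integer seeds.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import Atom, Structure, Trajectory

__all__ = [
    "PoreGeometrySpec",
    "WaterTrackSpec",
    "DoseResponseSpec",
    "make_pore_assembly",
    "make_water_trajectory",
    "make_dose_response",
    "make_curved_assembly",
    "random_walk_tracks",
    "random_cage",
    "make_demo_system",
]

_WATER_OH = 0.9572  # TIP3-style O-H bond length, Angstrom
_WATER_HOH = np.deg2rad(104.52)


# --------------------------------------------------------------------------
# Pore geometries
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PoreGeometrySpec:
    """Stacked atom rings defining a channel with known radius profile.

    Each ring is (z, ring_radius, n_atoms, vdw); the open-pore radius at a
    ring plane is exactly ring_radius - vdw.
    """

    rings: Sequence[tuple[float, float, int, float]]
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if not self.rings:
            raise ValueError("at least one ring required")
        for z, rr, n, vdw in self.rings:
            if n < 3:
                raise ValueError("each ring needs at least 3 atoms")
            if rr <= vdw:
                raise ValueError(
                    f"closed ring at z={z}: ring_radius {rr} <= vdw {vdw}"
                )
        axis = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", axis / np.linalg.norm(axis))


def _axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``axis``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def make_pore_assembly(spec: PoreGeometrySpec) -> tuple[Structure, np.ndarray]:
    """Build a ring-stack structure and its analytic radius profile.

    Returns (structure, profile) where profile is an (n_rings, 2) array of
    (z, ring_radius - vdw) rows — the exact largest-inscribed-sphere radius in
    each ring plane for a sphere centred on the axis.
    """
    u, v = _axis_frame(spec.axis)
    atoms: list[Atom] = []
    profile = []
    serial = 1
    for ri, (z, ring_radius, n_atoms, vdw) in enumerate(spec.rings):
        phase = 0.39996 * ri  # stagger rings so atoms do not stack in columns
        center = spec.axis * z
        for k in range(n_atoms):
            theta = phase + 2 * np.pi * k / n_atoms
            pos = center + ring_radius * (np.cos(theta) * u + np.sin(theta) * v)
            atoms.append(
                Atom(
                    serial=serial,
                    name=f"C{k + 1}",
                    element="C",
                    resname="RNG",
                    resid=ri + 1,
                    chain="P",
                    position=pos,
                    vdw_radius=vdw,
                )
            )
            serial += 1
        profile.append((z, ring_radius - vdw))
    return Structure(atoms), np.asarray(profile)


def random_cage(
    seed: int,
    n_atoms: int = 50,
    mean_radius: float = 6.0,
    radius_sd: float = 0.6,
    z_extent: float = 4.0,
    vdw_choices: Sequence[float] = (1.5, 1.7, 2.0),
) -> Structure:
    """A randomised roughly-cylindrical atom cage with an open central pore.

    Used to exercise the pore search against exhaustive grid oracles; no
    analytic answer, but the pore is open near the axis by construction.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_atoms):
        theta = rng.uniform(0, 2 * np.pi)
        rr = mean_radius + rng.normal(0, radius_sd)
        rr = max(rr, mean_radius - 2 * radius_sd)
        z = rng.uniform(-z_extent, z_extent)
        vdw = float(rng.choice(np.asarray(vdw_choices)))
        atoms.append(
            Atom(
                serial=i + 1,
                name=f"C{i + 1}",
                element="C",
                resname="CGE",
                resid=1,
                chain="X",
                position=np.array([rr * np.cos(theta), rr * np.sin(theta), z]),
                vdw_radius=vdw,
            )
        )
    return Structure(atoms)


# --------------------------------------------------------------------------
# Scripted water trajectories
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterTrackSpec:
    """Per-water scripted distances to a target residue, one value per frame.

    ``tracks[w][f]`` is the distance (Angstrom) of water w's oxygen from the
    target residue at frame f. ``dt`` is the frame spacing in ns.
    """

    tracks: Sequence[np.ndarray]
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        tracks = tuple(np.asarray(t, dtype=float) for t in self.tracks)
        if not tracks:
            raise ValueError("at least one water track required")
        n = len(tracks[0])
        for t in tracks:
            if len(t) != n:
                raise ValueError("all tracks must cover every frame")
            if np.any(t < 0):
                raise ValueError("distances must be non-negative")
        object.__setattr__(self, "tracks", tracks)


def expected_residence_events(
    tracks: Sequence[np.ndarray],
    dt: float,
    contact_cutoff: float = 5.0,
    release_cutoff: float = 8.0,
) -> list[dict]:
    """Ground-truth residence events from scripted distances.

    Implements the two-threshold rule directly on the script: an event starts
    at the first frame with distance <= contact_cutoff, persists while
    distance <= release_cutoff, and ends the frame before distance exceeds
    release_cutoff; an event still open at the final frame is censored.
    Duration is (end - start + 1) * dt.
    """
    events = []
    for wi, track in enumerate(tracks):
        start = None
        for f, d in enumerate(track):
            if start is None:
                if d <= contact_cutoff:
                    start = f
            elif d > release_cutoff:
                events.append(
                    dict(
                        water=wi + 1,
                        start=start,
                        end=f - 1,
                        duration_ns=(f - start) * dt,
                        censored=False,
                    )
                )
                start = f if d <= contact_cutoff else None
        if start is not None:
            end = len(track) - 1
            events.append(
                dict(
                    water=wi + 1,
                    start=start,
                    end=end,
                    duration_ns=(end - start + 1) * dt,
                    censored=True,
                )
            )
    return events


def make_water_trajectory(
    spec: WaterTrackSpec,
    target: Structure | None = None,
    box_size: float = 200.0,
) -> tuple[Trajectory, list[dict]]:
    """Place 3-site waters on rays from a target residue at scripted distances.

    The target defaults to a single-atom probe residue at the origin. Water
    oxygens sit exactly at the scripted distance; both hydrogens are offset
    perpendicular to the ray so the oxygen is always the nearest water atom
    and the scripted distance equals the min atom-atom distance.

    Returns the trajectory and the ground-truth residence events from the
    default 5/8 Angstrom rule.
    """
    if target is None:
        target = Structure(
            [
                Atom(
                    serial=1,
                    name="CA",
                    element="C",
                    resname="GLY",
                    resid=1,
                    chain="T",
                    position=np.zeros(3),
                    vdw_radius=1.7,
                )
            ]
        )
    centroid = target.coords.mean(axis=0)
    rng = np.random.default_rng(spec.seed)
    n_frames = len(spec.tracks[0])
    rays, perps1, perps2 = [], [], []
    for _ in spec.tracks:
        ray = rng.normal(size=3)
        ray /= np.linalg.norm(ray)
        u, v = _axis_frame(ray)
        rays.append(ray)
        perps1.append(u)
        perps2.append(v)

    atoms = list(target)
    serial = target.n_atoms + 1
    for wi in range(len(spec.tracks)):
        for name in ("OH2", "H1", "H2"):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element="O" if name == "OH2" else "H",
                    resname="TIP3",
                    resid=wi + 1,
                    chain="W",
                    position=np.zeros(3),
                    vdw_radius=1.52 if name == "OH2" else 1.2,
                )
            )
            serial += 1
    topology = Structure(atoms)

    shift = np.full(3, box_size / 2.0) - centroid
    coords = np.empty((n_frames, topology.n_atoms, 3))
    h1_off = _WATER_OH
    h2_u = _WATER_OH * np.cos(_WATER_HOH)
    h2_v = _WATER_OH * np.sin(_WATER_HOH)
    for f in range(n_frames):
        coords[f, : target.n_atoms] = target.coords + shift
        for wi, track in enumerate(spec.tracks):
            o = centroid + track[f] * rays[wi]
            base = target.n_atoms + 3 * wi
            coords[f, base] = o + shift
            coords[f, base + 1] = o + h1_off * perps1[wi] + shift
            coords[f, base + 2] = o + h2_u * perps1[wi] + h2_v * perps2[wi] + shift
    boxes = np.full((n_frames, 3), box_size)
    times = spec.dt * np.arange(n_frames)
    traj = Trajectory(topology=topology, coords=coords, boxes=boxes, times=times)
    return traj, expected_residence_events(spec.tracks, spec.dt)


def random_walk_tracks(
    n_waters: int,
    n_frames: int,
    dt: float = 0.1,
    seed: int = 0,
    start_range: tuple[float, float] = (2.0, 12.0),
    step_sd: float = 0.8,
    bounds: tuple[float, float] = (0.5, 20.0),
) -> WaterTrackSpec:
    """Reflected Gaussian random-walk distance scripts for many waters."""
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    tracks = []
    for _ in range(n_waters):
        d = np.empty(n_frames)
        d[0] = rng.uniform(*start_range)
        for f in range(1, n_frames):
            nxt = d[f - 1] + rng.normal(0, step_sd)
            while nxt < lo or nxt > hi:  # reflect at the walls
                nxt = lo + abs(nxt - lo) if nxt < lo else hi - abs(nxt - hi)
            d[f] = nxt
        tracks.append(d)
    return WaterTrackSpec(tracks=tracks, dt=dt, seed=seed)


# --------------------------------------------------------------------------
# Dose-response curves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseSpec:
    """Exponential decay fraction-unmodified curves with Gaussian noise."""

    k_true: float
    exposures: Sequence[float] = (0.0, 100.0, 250.0, 500.0, 750.0, 1000.0, 2000.0)
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        exposures = np.asarray(self.exposures, dtype=float)
        if 0.0 not in exposures:
            raise ValueError("exposures must include 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.k_true < 0:
            raise ValueError("k_true must be non-negative")
        object.__setattr__(self, "exposures", exposures)


def make_dose_response(spec: DoseResponseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noisy fraction-unmodified replicates: exp(-k t) + N(0, sd), clipped.

    Returns (exposures, fractions) with fractions of shape
    (n_replicates, n_exposures), clipped to [0, 1.05]. Reproducible for a
    fixed seed.
    """
    t = np.asarray(spec.exposures, dtype=float)
    clean = np.exp(-spec.k_true * t)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_replicates, t.size))
    if spec.noise_sd == 0:
        noise = np.zeros((spec.n_replicates, t.size))
    fractions = np.clip(clean[None, :] + noise, 0.0, 1.05)
    return t, fractions


# --------------------------------------------------------------------------
# Curved tile assemblies
# --------------------------------------------------------------------------


def _cap_directions(n: int, max_polar: float) -> np.ndarray:
    """n roughly even unit vectors within a spherical cap about +z."""
    ga = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    k = np.arange(n)
    # even-area spacing in cos(theta) over [cos(max_polar), 1]
    cos_t = 1.0 - (k + 0.5) / n * (1.0 - np.cos(max_polar))
    sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, None))
    phi = ga * k
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def make_curved_assembly(
    n_tiles: int,
    cap_radius: float,
    tile_template: Structure,
    min_gap: float = 1.0,
) -> tuple[Structure, np.ndarray, list[str]]:
    """Rigid copies of a planar tile placed tangent to a spherical cap.

    The template is assumed centred near the origin with its normal along +z.
    Tile i is rotated so +z maps onto the cap direction n_i and translated to
    cap_radius * n_i; n_i is the true outward normal. ``cap_radius = inf``
    gives the planar limit (tiles on a flat grid, all normals +z).

    Returns (assembly, normals, chains) where ``chains[i]`` is the chain id of
    tile i and ``normals[i]`` its recorded unit outward normal. Raises if any
    two tiles come within ``min_gap`` of touching (overlapping placement).
    """
    from .geometry import _rotation_aligning  # shared pure helper

    if n_tiles < 2:
        raise ValueError("need at least 2 tiles")
    template = tile_template.coords - tile_template.coords.mean(axis=0)
    tile_extent = float(np.linalg.norm(template, axis=1).max())
    chain_ids = list(string.ascii_uppercase + string.ascii_lowercase)
    if n_tiles > len(chain_ids):
        raise ValueError("too many tiles for single-character chain ids")

    if np.isinf(cap_radius):
        pitch = 2 * tile_extent + 2 * min_gap
        side = int(np.ceil(np.sqrt(n_tiles)))
        centers = np.array(
            [
                [pitch * (i % side), pitch * (i // side), 0.0]
                for i in range(n_tiles)
            ]
        )
        normals = np.tile([0.0, 0.0, 1.0], (n_tiles, 1))
        rotations = [np.eye(3)] * n_tiles
    else:
        # Cap wide enough to hold n_tiles non-overlapping tile footprints
        # (factor 4 of slack in solid angle).
        need = 4.0 * n_tiles * (tile_extent + min_gap) ** 2 / cap_radius**2
        cos_max = max(1.0 - need / 2.0, -0.5)
        max_polar = float(np.arccos(cos_max))
        normals = _cap_directions(n_tiles, max_polar)
        centers = cap_radius * normals
        rotations = [_rotation_aligning(np.array([0.0, 0.0, 1.0]), n) for n in normals]

    atoms = []
    serial = 1
    placed = []
    for ti in range(n_tiles):
        coords_i = template @ rotations[ti].T + centers[ti]
        placed.append(coords_i)
        for ai, a in enumerate(tile_template):
            atoms.append(
                Atom(
                    serial=serial,
                    name=a.name,
                    element=a.element,
                    resname=a.resname,
                    resid=a.resid,
                    chain=chain_ids[ti],
                    position=coords_i[ai],
                    vdw_radius=a.vdw_radius,
                )
            )
            serial += 1
    for i in range(n_tiles):
        for j in range(i + 1, n_tiles):
            d = np.linalg.norm(placed[i][:, None, :] - placed[j][None, :, :], axis=2)
            if d.min() < min_gap:
                raise ValueError(f"tiles {i} and {j} overlap (min gap {d.min():.2f})")
    return Structure(atoms), normals, chain_ids[:n_tiles]


# --------------------------------------------------------------------------
# Demo systems for the end-to-end pipeline
# --------------------------------------------------------------------------


def _ring_tile(
    chain: str,
    center: np.ndarray,
    ring_radius: float,
    n_per_ring: int = 12,
    half_height: float = 1.5,
    vdw: float = 1.7,
    serial0: int = 1,
) -> list[Atom]:
    """A two-ring slab tile with a central pore; one residue per ring atom
    pair so per-residue metrics have something to chew on."""
    atoms = []
    serial = serial0
    for k in range(n_per_ring):
        theta = 2 * np.pi * k / n_per_ring
        xy = ring_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        for j, dz in enumerate((-half_height, half_height)):
            atoms.append(
                Atom(
                    serial=serial,
                    name=f"C{j + 1}",
                    element="C",
                    resname="ALA",
                    resid=k + 1,
                    chain=chain,
                    position=center + xy + np.array([0.0, 0.0, dz]),
                    vdw_radius=vdw,
                )
            )
            serial += 1
    return atoms


def make_demo_system(
    seed: int,
    condition: str = "shell",
    n_frames: int = 12,
    n_waters: int = 40,
    dt: float = 1.0,
    box_size: float = 64.0,
) -> Trajectory:
    """A miniature shell-fragment-like system: one central "trimer" tile
    (chain T), two interface "hexamer" tiles (A, B) close enough to contact
    it, one solvent-exposed tile (C), and mobile waters.

    The "shell" condition bows the outer tiles slightly out of plane (curved
    facet); "sheet" keeps all tiles coplanar. Frames add small Gaussian
    thermal jitter to protein atoms and random-walk motion to waters.
    """
    if condition not in ("shell", "sheet"):
        raise ValueError("condition must be 'shell' or 'sheet'")
    rng = np.random.default_rng(seed)
    center = np.full(3, box_size / 2.0)
    curve = 2.5 if condition == "shell" else 0.0

    atoms: list[Atom] = []
    atoms += _ring_tile("T", center, ring_radius=4.5, serial0=1)
    tile_offsets = {
        "A": np.array([11.5, 0.0, curve]),
        "B": np.array([-11.5, 0.0, curve]),
        "C": np.array([0.0, 24.0, curve]),
    }
    for chain, off in tile_offsets.items():
        atoms += _ring_tile(chain, center + off, ring_radius=5.0, serial0=len(atoms) + 1)

    n_protein = len(atoms)
    serial = n_protein + 1
    for wi in range(n_waters):
        o = rng.uniform(4.0, box_size - 4.0, size=3)
        for name, off in (
            ("OH2", np.zeros(3)),
            ("H1", np.array([_WATER_OH, 0.0, 0.0])),
            ("H2", _WATER_OH * np.array([np.cos(_WATER_HOH), np.sin(_WATER_HOH), 0.0])),
        ):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element="O" if name == "OH2" else "H",
                    resname="TIP3",
                    resid=wi + 1,
                    chain="W",
                    position=o + off,
                    vdw_radius=1.52 if name == "OH2" else 1.2,
                )
            )
            serial += 1
    topology = Structure(atoms)

    coords = np.empty((n_frames, topology.n_atoms, 3))
    coords[0] = topology.coords
    for f in range(1, n_frames):
        jitter = rng.normal(0, 0.08, size=(n_protein, 3))
        coords[f, :n_protein] = topology.coords[:n_protein] + jitter
        steps = rng.normal(0, 0.8, size=(n_waters, 3))
        water = coords[f - 1, n_protein:].reshape(n_waters, 3, 3) + steps[:, None, :]
        coords[f, n_protein:] = water.reshape(-1, 3)
    boxes = np.full((n_frames, 3), float(box_size))
    times = dt * np.arange(n_frames)
    return Trajectory(topology=topology, coords=coords, boxes=boxes, times=times)
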