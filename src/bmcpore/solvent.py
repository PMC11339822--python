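"""Per-residue solvation analysis: SASA, water contacts, residence times.

Water association with a residue follows a two-threshold hysteresis rule:
a residence event starts when any water atom comes within the contact cutoff
(default 5 Angstrom) of any residue atom and ends only once the water moves
beyond the release cutoff (default 8 Angstrom). Excursions between the two
cutoffs do not end an event, which suppresses spurious event splitting from
thermal rattling at the boundary.

All water-protein distances are atom-atom minima under the minimum-image
convention in an orthorhombic box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Selection, Structure, Trajectory, select

__all__ = [
    "SASAParams",
    "ContactParams",
    "ResidenceEvent",
    "sasa_per_residue",
    "water_contacts",
    "residence_times",
    "segment_monomers",
    "monomer_average",
    "split_by_monomer",
]


@dataclass(frozen=True)
class SASAParams:
    """Shrake-Rupley parameters: probe radius (Angstrom) and sphere points."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 32:
            raise ValueError("need at least 32 sphere points")


@dataclass(frozen=True)
class ContactParams:
    """Two-threshold water association cutoffs (Angstrom)."""

    contact_cutoff: float = 5.0
    release_cutoff: float = 8.0

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.release_cutoff <= self.contact_cutoff:
            raise ValueError("release_cutoff must exceed contact_cutoff")


@dataclass(frozen=True)
class ResidenceEvent:
    """One continuous association of a water with a residue."""

    residue: tuple[str, int, str]
    water: tuple[str, int, str]
    start: int
    end: int
    duration_ns: float
    censored: bool

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end precedes start")


def _sphere_points(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (Fibonacci spiral)."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_per_residue(
    frame: Structure,
    sel: Selection | str = "protein",
    params: SASAParams = SASAParams(),
) -> pd.DataFrame:
    """Residue-wise solvent-accessible surface area (Shrake-Rupley), Angstrom^2.

    Per atom, the accessible area is the fraction of test points on the
    probe-inflated sphere not buried inside any other inflated atom, times
    4 pi (r_vdw + probe)^2; a residue's value sums its atoms. Water is
    excluded both as surface and as occluder, so the result reflects the
    protein's own surface.
    """
    sel_idx = select(frame, sel)
    not_water = ~frame.is_water
    surface = np.array([i for i in sel_idx if not_water[i]], dtype=int)
    occluders = np.flatnonzero(not_water)
    if surface.size == 0:
        raise ValueError("selection contains no non-water atoms")
    if np.any(frame.radii[occluders] <= 0):
        raise ValueError("zero or negative vdW radius encountered")

    pts = _sphere_points(params.n_sphere_points)
    coords = frame.coords
    inflated = frame.radii + params.probe_radius
    occ_coords = coords[occluders]
    occ_inflated = inflated[occluders]
    tree = cKDTree(occ_coords)
    max_r = float(occ_inflated.max())

    atom_area = np.zeros(frame.n_atoms)
    occ_pos = {int(a): j for j, a in enumerate(occluders)}
    for i in surface:
        ri = inflated[i]
        test = coords[i] + ri * pts
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        accessible = np.ones(len(test), dtype=bool)
        for j in neigh:
            aj = int(occluders[j])
            if aj == int(i):
                continue
            d2 = np.sum((test - occ_coords[j]) ** 2, axis=1)
            accessible &= d2 > occ_inflated[j] ** 2
            if not accessible.any():
                break
        atom_area[i] = accessible.mean() * 4.0 * np.pi * ri * ri
    del occ_pos

    rows = []
    residues = frame.residues
    sel_set = set(int(i) for i in surface)
    for (chain, resid, resname), idx in residues.items():
        members = [int(i) for i in idx if int(i) in sel_set]
        if not members:
            continue
        rows.append(
            dict(
                chain=chain,
                resid=resid,
                resname=resname,
                value=float(atom_area[members].sum()),
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Water distances under periodic boundaries
# --------------------------------------------------------------------------


def _min_image_distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances between point sets in an orthorhombic box."""
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta * delta, axis=2))


def _residue_water_min_dists(
    frame_coords: np.ndarray,
    box: np.ndarray,
    residue_groups: list[np.ndarray],
    water_groups: list[np.ndarray],
) -> np.ndarray:
    """(n_residues, n_waters) matrix of min atom-atom distances."""
    res_atoms = np.concatenate(residue_groups)
    wat_atoms = np.concatenate(water_groups)
    d = _min_image_distance_matrix(frame_coords[res_atoms], frame_coords[wat_atoms], box)
    res_starts = np.cumsum([0] + [len(g) for g in residue_groups[:-1]])
    wat_starts = np.cumsum([0] + [len(g) for g in water_groups[:-1]])
    d = np.minimum.reduceat(d, res_starts, axis=0)
    d = np.minimum.reduceat(d, wat_starts, axis=1)
    return d


def _group_targets_and_waters(
    top: Structure, residues_sel: Selection | str, heavy_only: bool = False
):
    sel_idx = set(int(i) for i in select(top, residues_sel))
    is_water = top.is_water
    res_keys, res_groups = [], []
    wat_keys, wat_groups = [], []
    for key, idx in top.residues.items():
        idx = np.asarray(idx, dtype=int)
        if is_water[idx[0]]:
            wat_keys.append(key)
            wat_groups.append(idx)
        else:
            members = np.array([i for i in idx if i in sel_idx], dtype=int)
            if heavy_only and members.size:
                members = np.array(
                    [i for i in members if str(top.elements[i]).upper() != "H"],
                    dtype=int,
                )
            if members.size:
                res_keys.append(key)
                res_groups.append(members)
    return res_keys, res_groups, wat_keys, wat_groups


def water_contacts(
    traj: Trajectory,
    residues: Selection | str,
    params: ContactParams = ContactParams(),
    mask: np.ndarray | None = None,
    heavy_only: bool = False,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Unique water molecules within the contact cutoff of each residue.

    Default semantics: per frame, count water molecules with at least one atom
    within ``contact_cutoff`` of at least one residue atom, then average over
    the masked frames (matching per-frame pairwise-contact averaging). With
    ``cumulative=True`` the count is instead of distinct waters ever seen in
    contact across the masked frames.
    """
    mask = np.arange(traj.n_frames) if mask is None else np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("no frames in mask")
    res_keys, res_groups, wat_keys, wat_groups = _group_targets_and_waters(
        traj.topology, residues, heavy_only
    )
    if not wat_groups:
        raise ValueError("no water residues in the topology")
    if not res_groups:
        raise ValueError("residue selection matches no non-water atoms")

    counts = np.zeros(len(res_keys))
    seen = [set() for _ in res_keys]
    for f in mask:
        d = _residue_water_min_dists(traj.coords[f], traj.boxes[f], res_groups, wat_groups)
        contact = d <= params.contact_cutoff
        if cumulative:
            for ri, row in enumerate(contact):
                seen[ri].update(np.flatnonzero(row).tolist())
        else:
            counts += contact.sum(axis=1)
    values = (
        np.array([len(s) for s in seen], dtype=float)
        if cumulative
        else counts / mask.size
    )
    return pd.DataFrame(
        [
            dict(chain=k[0], resid=k[1], resname=k[2], value=v)
            for k, v in zip(res_keys, values)
        ]
    )


def residence_times(
    traj: Trajectory,
    residues: Selection | str,
    params: ContactParams = ContactParams(),
    mask: np.ndarray | None = None,
    heavy_only: bool = False,
    include_censored: bool = True,
) -> tuple[list[ResidenceEvent], pd.DataFrame]:
    """Water residence events per residue under the two-threshold rule.

    For each (residue, water) pair an event starts at the first masked frame
    with min distance <= contact_cutoff, persists while the distance stays
    <= release_cutoff, and ends the frame before it exceeds release_cutoff;
    re-entry starts a new event. Events still open at the last masked frame
    are closed there and flagged censored. Durations are
    (end - start + 1) * dt with dt the trajectory frame spacing.

    Returns the event list and a per-residue table of mean event duration (ns)
    over all events (censored included unless ``include_censored=False``).
    """
    mask = np.arange(traj.n_frames) if mask is None else np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("no frames in mask")
    res_keys, res_groups, wat_keys, wat_groups = _group_targets_and_waters(
        traj.topology, residues, heavy_only
    )
    if not wat_groups:
        raise ValueError("no water residues in the topology")
    if not res_groups:
        raise ValueError("residue selection matches no non-water atoms")
    dt = traj.dt if traj.n_frames > 1 else 1.0

    active: dict[tuple[int, int], int] = {}  # (residue, water) -> start frame
    events: list[ResidenceEvent] = []

    def _close(ri: int, wi: int, start: int, end: int, censored: bool) -> None:
        events.append(
            ResidenceEvent(
                residue=res_keys[ri],
                water=wat_keys[wi],
                start=start,
                end=end,
                duration_ns=(end - start + 1) * dt,
                censored=censored,
            )
        )

    prev_frame: int | None = None
    for f in mask:
        d = _residue_water_min_dists(traj.coords[f], traj.boxes[f], res_groups, wat_groups)
        within_release = d <= params.release_cutoff
        within_contact = d <= params.contact_cutoff
        for (ri, wi), start in list(active.items()):
            if not within_release[ri, wi]:
                _close(ri, wi, start, prev_frame, censored=False)
                del active[(ri, wi)]
        for ri, wi in zip(*np.nonzero(within_contact)):
            key = (int(ri), int(wi))
            if key not in active:
                active[key] = int(f)
        prev_frame = int(f)
    for (ri, wi), start in active.items():
        _close(ri, wi, start, prev_frame, censored=True)

    rows = []
    for ri, key in enumerate(res_keys):
        durations = [
            e.duration_ns
            for e in events
            if e.residue == key and (include_censored or not e.censored)
        ]
        rows.append(
            dict(
                chain=key[0],
                resid=key[1],
                resname=key[2],
                value=float(np.mean(durations)) if durations else 0.0,
            )
        )
    return events, pd.DataFrame(rows)


def events_to_frame(events: list[ResidenceEvent]) -> pd.DataFrame:
    """Flatten residence events into a CSV-ready table."""
    return pd.DataFrame(
        [
            dict(
                chain=e.residue[0],
                resid=e.residue[1],
                resname=e.residue[2],
                water_chain=e.water[0],
                water_resid=e.water[1],
                start=e.start,
                end=e.end,
                duration_ns=e.duration_ns,
                censored=e.censored,
            )
            for e in events
        ]
    )


# --------------------------------------------------------------------------
# Monomer segmentation and class averaging
# --------------------------------------------------------------------------


def segment_monomers(
    assembly: Structure,
    trimer_sel: Selection | str,
    contact_distance: float = 5.0,
) -> dict[str, str]:
    """Classify non-trimer protein chains as buried-interface or exposed.

    A monomer (chain) is "buried-interface" when any of its heavy atoms lies
    within ``contact_distance`` of a trimer heavy atom, otherwise "exposed".
    Water chains are ignored.
    """
    trimer_idx = select(assembly, trimer_sel)
    if trimer_idx.size == 0:
        raise ValueError("trimer selection matches no atoms")
    heavy = np.array([str(e).upper() != "H" for e in assembly.elements])
    is_water = assembly.is_water
    trimer_heavy = np.array([i for i in trimer_idx if heavy[i]], dtype=int)
    if trimer_heavy.size == 0:
        raise ValueError("trimer selection has no heavy atoms")
    tree = cKDTree(assembly.coords[trimer_heavy])
    trimer_chains = set(str(assembly.chains[i]) for i in trimer_idx)

    out: dict[str, str] = {}
    for chain in dict.fromkeys(str(c) for c in assembly.chains):
        idx = np.flatnonzero(assembly.chains == chain)
        if chain in trimer_chains or is_water[idx[0]]:
            continue
        chain_heavy = np.array([i for i in idx if heavy[i]], dtype=int)
        if chain_heavy.size == 0:
            raise ValueError(f"monomer chain {chain!r} has no heavy atoms")
        dmin, _ = tree.query(assembly.coords[chain_heavy], k=1)
        out[chain] = (
            "buried-interface" if float(dmin.min()) <= contact_distance else "exposed"
        )
    return out


def split_by_monomer(table: pd.DataFrame) -> dict[str, pd.Series]:
    """Split a per-residue table into per-monomer series keyed by chain,
    indexed by monomer-internal residue label (resname + resid)."""
    out: dict[str, pd.Series] = {}
    for chain, sub in table.groupby("chain", sort=False):
        labels = sub["resname"].astype(str) + sub["resid"].astype(str)
        out[str(chain)] = pd.Series(sub["value"].to_numpy(), index=labels.to_numpy())
    return out


def monomer_average(
    per_monomer: dict[str, pd.Series],
    class_map: dict[str, str] | None = None,
    class_filter: str | None = None,
) -> pd.DataFrame:
    """Mean and SEM of a per-residue metric across monomer copies.

    All monomer tables must share the same residue label set. With a class
    map and filter, only monomers of that class contribute. SEM is the sample
    standard deviation over monomers divided by sqrt(n); zero for n = 1.
    """
    chains = list(per_monomer)
    if class_map is not None and class_filter is not None:
        chains = [c for c in chains if class_map.get(c) == class_filter]
    if not chains:
        raise ValueError(f"no monomers in class {class_filter!r}")
    index = per_monomer[chains[0]].index
    for c in chains[1:]:
        if not per_monomer[c].index.equals(index):
            raise ValueError(
                f"monomer {c!r} has a different residue set than {chains[0]!r}"
            )
    stacked = np.vstack([per_monomer[c].to_numpy(dtype=float) for c in chains])
    mean = stacked.mean(axis=0)
    n = len(chains)
    sem = stacked.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return pd.DataFrame(
        {"residue": index.to_numpy(), "mean": mean, "sem": sem, "n_monomers": n}
    )
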