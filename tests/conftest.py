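import numpy as np
import pytest

from bmcpore.structure_io import Atom, Structure


def make_atom(serial=1, name="CA", element="C", resname="ALA", resid=1, chain="A",
              position=(0.0, 0.0, 0.0), vdw=1.7):
    return Atom(
        serial=serial, name=name, element=element, resname=resname, resid=resid,
        chain=chain, position=np.asarray(position, dtype=float), vdw_radius=vdw,
    )


@pytest.fixture
def two_atom_structure():
    return Structure(
        [
            make_atom(serial=1, name="CA", element="C", position=(0, 0, 0)),
            make_atom(serial=2, name="O", element="O", position=(1, 0, 0), vdw=1.52),
        ]
    )


@pytest.fixture
def random_structure():
    """A mixed structure with several chains/residues/waters for selection tests."""
    rng = np.random.default_rng(7)
    atoms = []
    serial = 1
    for chain in "AB":
        for resid in range(1, 13):
            for name in ("N", "CA", "C"):
                atoms.append(
                    make_atom(
                        serial=serial, name=name, element=name[0], resname="GLY",
                        resid=resid, chain=chain, position=rng.normal(size=3) * 10,
                    )
                )
                serial += 1
    for w in range(1, 4):
        for name, elem in (("OH2", "O"), ("H1", "H"), ("H2", "H")):
            atoms.append(
                make_atom(
                    serial=serial, name=name, element=elem, resname="TIP3",
                    resid=w, chain="W", position=rng.normal(size=3) * 10,
                    vdw=1.52 if elem == "O" else 1.2,
                )
            )
            serial += 1
    return Structure(atoms)


def brute_force_filter(structure, predicate):
    """Independent reference: indices of atoms satisfying a python predicate."""
    return np.array(
        [i for i, a in enumerate(structure) if predicate(a)], dtype=int
    )


def horn_superpose_rmsd(mobile, reference):
    """Independent quaternion-based (Horn) optimal-superposition RMSD oracle."""
    A = np.asarray(mobile, float)
    B = np.asarray(reference, float)
    Am = A - A.mean(axis=0)
    Bm = B - B.mean(axis=0)
    S = Am.T @ Bm
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(N)[-1]
    n = A.shape[0]
    msd = (np.sum(Am**2) + np.sum(Bm**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def grid_search_pore_radius(structure, plane_point, axis, window=3.0, step=0.02):
    """Independent dense-grid oracle for the largest inscribed sphere centred
    in the plane through ``plane_point`` perpendicular to ``axis``.

    Returns (radius, boundary_attained) where the flag reports whether the
    optimum sits on the search-window edge (window too small)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    offs = np.arange(-window, window + step / 2, step)
    gx, gy = np.meshgrid(offs, offs, indexing="ij")
    pts = (
        np.asarray(plane_point, float)[None, :]
        + gx.ravel()[:, None] * u[None, :]
        + gy.ravel()[:, None] * v[None, :]
    )
    fmin = np.full(pts.shape[0], np.inf)
    for pos, rad in zip(structure.coords, structure.radii):
        d = np.sqrt(np.sum((pts - pos) ** 2, axis=1)) - rad
        np.minimum(fmin, d, out=fmin)
    best = int(np.argmax(fmin))
    bi, bj = np.unravel_index(best, gx.shape)
    on_edge = bi in (0, gx.shape[0] - 1) or bj in (0, gx.shape[1] - 1)
    return float(fmin[best]), on_edge


def min_image_dist_27(a, b, box):
    """Brute-force minimum-image distance via all 27 periodic translations."""
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * np.asarray(box, float)
                best = min(best, float(np.linalg.norm(np.asarray(a) - np.asarray(b) + shift)))
    return best


def residence_state_machine(distances, contact=5.0, release=8.0, dt=0.1):
    """Independent two-threshold state machine on a 1D distance series."""
    events = []
    start = None
    for f, d in enumerate(distances):
        if start is None:
            if d <= contact:
                start = f
        else:
            if d > release:
                events.append((start, f - 1, (f - start) * dt, False))
                start = f if d <= contact else None
    if start is not None:
        end = len(distances) - 1
        events.append((start, end, (end - start + 1) * dt, True))
    return events
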