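"""Structures, trajectories, vdW radius sets, and an atom-selection language.

The in-memory model is array-backed: a :class:`Structure` stores parallel
numpy arrays (coordinates, radii, names, ...) so that downstream geometric
analyses are vectorised, while :class:`Atom` provides a per-atom record view.

Coordinates are in Angstrom, times in nanoseconds, and residue ids follow the
1-based author numbering of the input PDB file (so residue labels like M7 or
Y41 match published structures).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "RadiusTable",
    "Selection",
    "PDBParseError",
    "SelectionError",
    "DEFAULT_WATER_RESNAMES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]

#: Residue names recognised as water by default (configurable per Structure).
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB records."""


class SelectionError(ValueError):
    """Raised for syntactically or semantically invalid selection strings."""


@dataclass(frozen=True)
class Atom:
    """A single atom record (author numbering, Angstrom coordinates)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


# --------------------------------------------------------------------------
# Radius tables
# --------------------------------------------------------------------------

# Bondi-style element vdW radii (Angstrom). HOLE's native set differs; absolute
# pore radii shift with the chosen set, so the table is explicit and swappable.
_BONDI = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 2.05,
    "SE": 1.90,
}


@dataclass(frozen=True)
class RadiusTable:
    """Maps atom names and elements to van der Waals radii.

    Lookup order: exact atom-name entry, then element entry. All radii must
    lie in (0.5, 3.0) Angstrom.
    """

    name: str
    by_element: Mapping[str, float] = field(default_factory=dict)
    by_atom_name: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, r in list(self.by_element.items()) + list(self.by_atom_name.items()):
            if not (0.5 < float(r) < 3.0):
                raise ValueError(f"radius for {key!r} out of range (0.5, 3.0): {r}")

    @classmethod
    def bondi(cls) -> "RadiusTable":
        """The default Bondi-style element radius set."""
        return cls(name="bondi", by_element=dict(_BONDI))

    @classmethod
    def from_text(cls, source: str | Path, name: str = "custom") -> "RadiusTable":
        """Load a two-column (key, radius) plain-text radius set.

        Keys of one or two characters matching a known element symbol are
        treated as elements; anything else as an atom name. Lines starting
        with '#' are comments.
        """
        text = Path(source).read_text() if isinstance(source, Path) else source
        by_element: dict[str, float] = {}
        by_name: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"radius file line {lineno}: expected 'key radius'")
            key = parts[0].upper()
            radius = float(parts[1])
            if key in _BONDI or (len(key) <= 2 and key.isalpha()):
                by_element[key] = radius
            else:
                by_name[key] = radius
        return cls(name=name, by_element=by_element, by_atom_name=by_name)

    def lookup(self, atom_name: str, element: str) -> float:
        key = atom_name.upper()
        if key in self.by_atom_name:
            return self.by_atom_name[key]
        ekey = element.upper()
        if ekey in self.by_element:
            return self.by_element[ekey]
        raise KeyError(
            f"no vdW radius for atom {atom_name!r} (element {element!r}) "
            f"in radius set {self.name!r}"
        )


def _guess_element(atom_name: str, resname: str) -> str:
    """Infer an element symbol from a PDB atom name (fallback path only)."""
    stripped = atom_name.strip()
    alpha = "".join(c for c in stripped if c.isalpha())
    if not alpha:
        return ""
    two = alpha[:2].upper()
    # Two-letter elements only when unambiguous (ions etc.); biological atom
    # names like "CA" (alpha carbon) must map to C, not calcium.
    if two in {"CL", "BR", "NA", "MG", "ZN", "FE", "SE"} and resname.upper() == two:
        return two
    return alpha[0].upper()


# --------------------------------------------------------------------------
# Structure / Trajectory
# --------------------------------------------------------------------------


class Structure:
    """An ordered collection of atoms grouped into residues.

    Parameters
    ----------
    atoms:
        Atom records in file order.
    water_resnames:
        Residue names identifying water molecules.
    metadata:
        Free-form provenance strings.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
        metadata: Mapping[str, str] | None = None,
    ) -> None:
        atoms = list(atoms)
        self.water_resnames = frozenset(r.upper() for r in water_resnames)
        self.metadata = dict(metadata or {})
        n = len(atoms)
        self.serials = np.array([a.serial for a in atoms], dtype=int)
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.resnames = np.array([a.resname for a in atoms], dtype=object)
        self.resids = np.array([a.resid for a in atoms], dtype=int)
        self.chains = np.array([a.chain for a in atoms], dtype=object)
        self.coords = (
            np.array([a.position for a in atoms], dtype=float)
            if n
            else np.zeros((0, 3))
        )
        self.radii = np.array([a.vdw_radius for a in atoms], dtype=float)
        seen: dict[tuple[str, int, str], None] = {}
        dup = {}
        for i in range(n):
            key = (str(self.chains[i]), int(self.resids[i]), str(self.names[i]))
            if key in dup:
                raise ValueError(f"duplicate atom {key} within model")
            dup[key] = None
            rkey = (str(self.chains[i]), int(self.resids[i]), str(self.resnames[i]))
            seen.setdefault(rkey, None)
        self._residue_keys = list(seen)

    # -- basic container protocol ------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def __len__(self) -> int:
        return self.n_atoms

    def __getitem__(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            resname=str(self.resnames[i]),
            resid=int(self.resids[i]),
            chain=str(self.chains[i]),
            position=self.coords[i].copy(),
            vdw_radius=float(self.radii[i]),
        )

    def __iter__(self) -> Iterator[Atom]:
        return (self[i] for i in range(self.n_atoms))

    @property
    def atoms(self) -> list[Atom]:
        return list(self)

    # -- residues ----------------------------------------------------------
    @property
    def residues(self) -> dict[tuple[str, int, str], np.ndarray]:
        """Mapping (chain, resid, resname) -> atom index array, file order."""
        out: dict[tuple[str, int, str], list[int]] = {k: [] for k in self._residue_keys}
        for i in range(self.n_atoms):
            out[(str(self.chains[i]), int(self.resids[i]), str(self.resnames[i]))].append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    @property
    def is_water(self) -> np.ndarray:
        """Boolean per-atom water mask based on residue name."""
        return np.array(
            [str(r).upper() in self.water_resnames for r in self.resnames], dtype=bool
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A shallow copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError(
                f"coordinate shape {coords.shape} != {self.coords.shape}"
            )
        new = Structure.__new__(Structure)
        new.__dict__.update(self.__dict__)
        new.coords = coords.copy()
        return new

    def subset(self, indices: np.ndarray) -> "Structure":
        """A new Structure containing only the given atom indices (in order)."""
        return Structure(
            [self[int(i)] for i in np.asarray(indices, dtype=int)],
            water_resnames=self.water_resnames,
            metadata=self.metadata,
        )


@dataclass
class Trajectory:
    """A topology plus per-frame coordinates in an orthorhombic box.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom, ``boxes``
    (n_frames, 3) in Angstrom, ``times`` (n_frames,) in nanoseconds and must
    be strictly increasing.
    """

    topology: Structure
    coords: np.ndarray
    boxes: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} != topology "
                f"{self.topology.n_atoms}"
            )
        n = self.coords.shape[0]
        if self.boxes.shape != (n, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if np.any(self.boxes <= 0):
            raise ValueError("box components must be positive")
        if self.times.shape != (n,):
            raise ValueError("times must have shape (n_frames,)")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    @property
    def dt(self) -> float:
        """Frame spacing in ns (uniform spacing assumed for durations)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


# --------------------------------------------------------------------------
# PDB reading / writing (fixed-column dialect)
# --------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad serial field {line[6:11]!r}") from exc
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:21].strip()
    chain = line[21].strip() or " "
    try:
        resid = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad resid field {line[22:26]!r}") from exc
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad coordinate field") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name, resname)
    return dict(
        serial=serial,
        name=name,
        altloc=altloc,
        resname=resname,
        chain=chain,
        resid=resid,
        xyz=(x, y, z),
        element=element,
    )


def _parse_models(text: str):
    """Split PDB text into models of parsed atom dicts, plus CRYST1 box."""
    box = None
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                box = np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: bad CRYST1 record") from exc
        elif rec == "MODEL":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            parsed = _parse_atom_line(line, lineno)
            if parsed["altloc"] in ("", "A"):
                current.append(parsed)
        elif rec == "END":
            break
    if current or not models:
        models.append(current)
    del in_model
    return [m for m in models if m] or [[]], box


def _looks_like_path(source: str) -> bool:
    if "\n" in source or len(source) > 4096:
        return False
    try:
        return Path(source).exists()
    except OSError:
        return False


def read_structure(
    source: str | Path,
    radii: RadiusTable | None = None,
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
) -> Structure:
    """Parse fixed-column PDB text (or a file path) into a Structure.

    Only the first model is used; additional models trigger a warning.
    HETATM records (e.g. crystallographic waters) are accepted; alternate
    locations other than blank or 'A' are dropped. Radii are assigned from
    ``radii`` (default: Bondi element set); an unresolvable atom is an error.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif _looks_like_path(source):
        text = Path(source).read_text()
    else:
        text = source
    radii = radii or RadiusTable.bondi()
    models, _ = _parse_models(text)
    if len(models) > 1:
        warnings.warn(
            f"input contains {len(models)} models; using the first",
            stacklevel=2,
        )
    atoms = []
    for rec in models[0]:
        try:
            r = radii.lookup(rec["name"], rec["element"])
        except KeyError as exc:
            raise PDBParseError(str(exc)) from exc
        atoms.append(
            Atom(
                serial=rec["serial"],
                name=rec["name"],
                element=rec["element"],
                resname=rec["resname"],
                resid=rec["resid"],
                chain=rec["chain"],
                position=np.array(rec["xyz"]),
                vdw_radius=r,
            )
        )
    return Structure(atoms, water_resnames=water_resnames)


def _format_atom_line(a: Atom, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    record = "HETATM" if a.resname.upper() in DEFAULT_WATER_RESNAMES else "ATOM  "
    return (
        f"{record}{serial:5d} {name:<4.4s} {a.resname:<4.4s}"
        f"{a.chain:1.1s}{a.resid:4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
    )


def write_structure(structure: Structure, path: str | Path | None = None) -> str:
    """Serialise a Structure to fixed-column PDB text (optionally to a file)."""
    lines = [
        _format_atom_line(a, serial=i + 1) for i, a in enumerate(structure)
    ]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_trajectory(traj: Trajectory, path: str | Path | None = None) -> str:
    """Serialise a Trajectory as a multi-model PDB with a CRYST1 box record."""
    box = traj.boxes[0]
    out = io.StringIO()
    out.write(
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
    )
    for fi in range(traj.n_frames):
        out.write(f"MODEL {fi + 1:8d}\n")
        frame = traj.frame(fi)
        for i, a in enumerate(frame):
            out.write(_format_atom_line(a, serial=i + 1) + "\n")
        out.write("ENDMDL\n")
    out.write("END\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_trajectory(
    topology: Structure,
    source: str | Path,
    box: Sequence[float] | None = None,
    dt: float = 1.0,
    t0: float = 0.0,
) -> Trajectory:
    """Read frames from a multi-model PDB (text or path) or a binary DCD file.

    ``box`` supplies a global orthorhombic box when the source carries none;
    a source without box information and no ``box`` argument is an error.
    ``dt``/``t0`` (ns) assign frame times when the format stores none.
    """
    is_path = isinstance(source, Path) or _looks_like_path(str(source))
    if is_path and str(source).lower().endswith(".dcd"):
        return _read_dcd(topology, Path(source), box=box, dt=dt, t0=t0)
    text = Path(source).read_text() if is_path else str(source)
    models, file_box = _parse_models(text)
    if box is not None:
        file_box = np.asarray(box, dtype=float)
    if file_box is None:
        raise ValueError("trajectory source has no CRYST1 box and no global box given")
    n = topology.n_atoms
    frames = np.empty((len(models), n, 3))
    for fi, model in enumerate(models):
        if len(model) != n:
            raise ValueError(
                f"frame {fi}: atom count {len(model)} != topology {n}"
            )
        frames[fi] = [rec["xyz"] for rec in model]
    boxes = np.tile(np.asarray(file_box, dtype=float), (len(models), 1))
    times = t0 + dt * np.arange(len(models))
    return Trajectory(topology=topology, coords=frames, boxes=boxes, times=times)


def _read_dcd(topology, path: Path, box=None, dt: float = 1.0, t0: float = 0.0) -> Trajectory:
    # Thin adapter over MDAnalysis so the core stays format-agnostic.
    import MDAnalysis as mda

    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    u.load_new(str(path))
    frames, boxes = [], []
    for fi, ts in enumerate(u.trajectory):
        if ts.positions.shape[0] != topology.n_atoms:
            raise ValueError(
                f"frame {fi}: atom count {ts.positions.shape[0]} != "
                f"topology {topology.n_atoms}"
            )
        frames.append(ts.positions.astype(float).copy())
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            boxes.append(ts.dimensions[:3].astype(float).copy())
        elif box is not None:
            boxes.append(np.asarray(box, dtype=float))
        else:
            raise ValueError(f"frame {fi}: no box in DCD and no global box given")
    coords = np.asarray(frames)
    times = t0 + dt * np.arange(len(frames))
    return Trajectory(topology=topology, coords=coords, boxes=np.asarray(boxes), times=times)


def write_dcd(traj: Trajectory, path: str | Path) -> None:
    """Write frames to a binary DCD file (MDAnalysis adapter)."""
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
        for fi in range(traj.n_frames):
            u.load_new(traj.coords[fi].astype(np.float32))
            u.dimensions = [*traj.boxes[fi], 90.0, 90.0, 90.0]
            w.write(u.atoms)


# --------------------------------------------------------------------------
# Selection mini-language
# --------------------------------------------------------------------------
#
# Grammar:
#   expr    := or_expr
#   or_expr := and_expr ("or" and_expr)*
#   and_expr:= not_expr ("and" not_expr)*
#   not_expr:= "not" not_expr | primary
#   primary := "(" expr ")" | "all" | "water" | "protein"
#            | "chain" VALUE+ | "resname" VALUE+ | "name" VALUE+
#            | "element" VALUE+ | "resid" (INT | INT "to" INT)+

_KEYWORDS = {"and", "or", "not", "to", "(", ")"}
_FIELDS = {"chain", "resname", "name", "element", "resid", "water", "all", "protein"}


@dataclass(frozen=True)
class Selection:
    """A parsed atom-selection expression (e.g. ``"chain A and resid 5 to 10"``)."""

    expression: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_ast", _parse_selection(self.expression))

    def evaluate(self, structure: Structure) -> np.ndarray:
        """Sorted, deduplicated atom indices matching this selection."""
        mask = _eval_node(self._ast, structure)
        return np.flatnonzero(mask)


def _tokenize(expr: str) -> list[str]:
    out: list[str] = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], expr: str) -> None:
        self.tokens = tokens
        self.pos = 0
        self.expr = expr

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selection: {self.expr!r}")
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise SelectionError(
                f"trailing token {self.peek()!r} in selection {self.expr!r}"
            )
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "or":
            self.next()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() == "and":
            self.next()
            node = ("and", node, self.parse_not())
        return node

    def parse_not(self):
        if self.peek() == "not":
            self.next()
            return ("not", self.parse_not())
        return self.parse_primary()

    def parse_primary(self):
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise SelectionError(f"unbalanced parentheses in {self.expr!r}")
            return node
        low = tok.lower()
        if low in ("all", "water", "protein"):
            return (low,)
        if low in ("chain", "resname", "name", "element"):
            values = self._collect_values()
            if not values:
                raise SelectionError(f"{low!r} needs at least one value")
            return (low, values)
        if low == "resid":
            return ("resid", self._collect_resid_terms())
        raise SelectionError(f"unknown selection keyword {tok!r} in {self.expr!r}")

    def _collect_values(self) -> list[str]:
        values = []
        while self.peek() is not None and self.peek().lower() not in _KEYWORDS | _FIELDS:
            values.append(self.next())
        return values

    def _collect_resid_terms(self):
        terms: list[tuple[int, int]] = []
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in (_KEYWORDS | _FIELDS) - {"to"}:
                break
            try:
                lo = int(self.next())
            except ValueError as exc:
                raise SelectionError(f"resid expects integers, got {tok!r}") from exc
            if self.peek() == "to":
                self.next()
                hi_tok = self.next()
                try:
                    hi = int(hi_tok)
                except ValueError as exc:
                    raise SelectionError(
                        f"resid range expects an integer after 'to', got {hi_tok!r}"
                    ) from exc
                terms.append((lo, hi))
            else:
                terms.append((lo, lo))
        if not terms:
            raise SelectionError("'resid' needs at least one value or range")
        return terms


def _parse_selection(expr: str):
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    return _Parser(tokens, expr).parse()


def _eval_node(node, s: Structure) -> np.ndarray:
    op = node[0]
    if op == "or":
        return _eval_node(node[1], s) | _eval_node(node[2], s)
    if op == "and":
        return _eval_node(node[1], s) & _eval_node(node[2], s)
    if op == "not":
        return ~_eval_node(node[1], s)
    if op == "all":
        return np.ones(s.n_atoms, dtype=bool)
    if op == "water":
        return s.is_water
    if op == "protein":
        return ~s.is_water
    if op == "chain":
        vals = set(node[1])
        return np.array([str(c) in vals for c in s.chains], dtype=bool)
    if op == "resname":
        vals = {v.upper() for v in node[1]}
        return np.array([str(r).upper() in vals for r in s.resnames], dtype=bool)
    if op == "name":
        vals = {v.upper() for v in node[1]}
        return np.array([str(n).upper() in vals for n in s.names], dtype=bool)
    if op == "element":
        vals = {v.upper() for v in node[1]}
        return np.array([str(e).upper() in vals for e in s.elements], dtype=bool)
    if op == "resid":
        mask = np.zeros(s.n_atoms, dtype=bool)
        for lo, hi in node[1]:
            mask |= (s.resids >= lo) & (s.resids <= hi)
        return mask
    raise SelectionError(f"unhandled node {op!r}")  # pragma: no cover


def select(structure: Structure, sel: Selection | str) -> np.ndarray:
    """Evaluate a selection on a structure, returning sorted atom indices."""
    if isinstance(sel, str):
        sel = Selection(sel)
    return sel.evaluate(structure)
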