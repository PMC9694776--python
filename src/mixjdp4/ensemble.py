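"""Conformer ensembles: loading, energy windows, superposition, deduplication,
Boltzmann weighting and dihedral measurement.

Conventions
-----------
* Coordinates are in angstroms, energies in kJ/mol (hartree accepted on input
  when explicitly declared; never auto-detected).
* Atom indices in every public API and file format are 1-based, matching the
  conventions of the geometry formats this module reads.
* Within an :class:`Ensemble`, relative energies are re-referenced so the
  global minimum sits at exactly 0 kJ/mol.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GAS_CONSTANT_J",
    "HARTREE_TO_KJMOL",
    "Conformer",
    "Ensemble",
    "DedupConfig",
    "BoltzmannWeights",
    "Superposition",
    "load_ensemble",
    "read_energy_table",
    "apply_energy_window",
    "superpose",
    "deduplicate",
    "boltzmann_weights",
    "measure_dihedral",
]

#: Molar gas constant, J/(K mol).
GAS_CONSTANT_J = 8.3145

#: Conversion factor from hartree to kJ/mol.
HARTREE_TO_KJMOL = 2625.499

_ENERGY_UNITS = {"kj/mol", "kjmol", "kj_mol", "hartree", "au"}


class EnsembleError(ValueError):
    """Structural or consistency problem in an ensemble or its inputs."""


class GeometryError(ValueError):
    """Degenerate geometry (collinear atoms, too few atoms to align)."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class Conformer:
    """A single molecular geometry with its relative energy.

    Parameters
    ----------
    id : str
        Unique identifier within the parent ensemble.
    elements : list of str
        Element symbols, one per atom.
    coords : (N, 3) ndarray
        Cartesian coordinates in angstroms.
    rel_energy : float
        Energy relative to the ensemble minimum, kJ/mol.
    shieldings : dict, optional
        1-based atom index -> isotropic shielding sigma (ppm).
    couplings : dict, optional
        Sorted (i, j) 1-based atom-index pair -> 3JHH coupling (Hz).
    ff_tag : str
        Name of the force field that produced the geometry.
    """

    id: str
    elements: list[str]
    coords: np.ndarray
    rel_energy: float
    shieldings: dict[int, float] | None = None
    couplings: dict[tuple[int, int], float] | None = None
    ff_tag: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise EnsembleError(
                f"conformer {self.id!r}: coords must be (N, 3), got {self.coords.shape}"
            )
        if len(self.elements) != self.coords.shape[0]:
            raise EnsembleError(
                f"conformer {self.id!r}: {len(self.elements)} elements but "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if not math.isfinite(self.rel_energy):
            raise EnsembleError(f"conformer {self.id!r}: non-finite energy")
        n = len(self.elements)
        for idx in (self.shieldings or {}):
            if not 1 <= idx <= n:
                raise EnsembleError(
                    f"conformer {self.id!r}: shielding index {idx} outside 1..{n}"
                )
        for pair in (self.couplings or {}):
            for idx in pair:
                if not 1 <= idx <= n:
                    raise EnsembleError(
                        f"conformer {self.id!r}: coupling atom {idx} outside 1..{n}"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> np.ndarray:
        """0-based indices of non-hydrogen atoms."""
        return np.asarray(
            [i for i, el in enumerate(self.elements) if el.upper() not in ("H", "D")],
            dtype=int,
        )


@dataclass
class Ensemble:
    """Ordered conformer collection for one (molecule, candidate, force field)."""

    molecule_id: str
    candidate_id: str
    ff_tag: str
    conformers: list[Conformer] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.conformers:
            raise EnsembleError(f"ensemble {self.candidate_id!r}: no conformers")
        ids = [c.id for c in self.conformers]
        if len(set(ids)) != len(ids):
            raise EnsembleError(f"ensemble {self.candidate_id!r}: duplicate conformer ids")
        ref = self.conformers[0].elements
        for c in self.conformers[1:]:
            if c.elements != ref:
                raise EnsembleError(
                    f"ensemble {self.candidate_id!r}: conformer {c.id!r} has a "
                    "different element list / atom ordering"
                )
        emin = min(c.rel_energy for c in self.conformers)
        if abs(emin) > 1e-9:
            raise EnsembleError(
                f"ensemble {self.candidate_id!r}: minimum relative energy is "
                f"{emin:g}, expected 0 (re-reference energies first)"
            )
        if any(c.rel_energy < -1e-9 for c in self.conformers):
            raise EnsembleError(f"ensemble {self.candidate_id!r}: negative relative energy")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def conformer_ids(self) -> list[str]:
        return [c.id for c in self.conformers]

    def with_conformers(self, conformers: Sequence[Conformer]) -> "Ensemble":
        return Ensemble(self.molecule_id, self.candidate_id, self.ff_tag, list(conformers))


@dataclass(frozen=True)
class DedupConfig:
    """Redundancy-elimination settings.

    method is "MAD" (maximum atom deviation) or "RMSD"; geom_threshold is the
    angstrom distance below which two aligned conformers count as duplicates;
    energy_cutoff is the kJ/mol window applied before deduplication by the
    curation pipeline; atom_subset is "heavy" or "all".
    """

    method: str = "MAD"
    geom_threshold: float = 0.5
    energy_cutoff: float = 12.0
    atom_subset: str = "heavy"

    def __post_init__(self) -> None:
        if self.method.upper() not in ("MAD", "RMSD"):
            raise ValueError(f"unknown dedup method {self.method!r}")
        if self.geom_threshold <= 0:
            raise ValueError("geom_threshold must be > 0")
        if self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be > 0")
        if self.atom_subset not in ("heavy", "all"):
            raise ValueError(f"atom_subset must be 'heavy' or 'all', got {self.atom_subset!r}")


@dataclass
class BoltzmannWeights:
    """Normalized conformer populations at a given temperature."""

    weights: dict[str, float]
    temperature: float

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total!r}, expected 1 within 1e-9")
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("weights must lie in [0, 1]")

    def as_array(self, conformer_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([self.weights[cid] for cid in conformer_ids], dtype=float)


@dataclass(frozen=True)
class Superposition:
    """Result of a least-squares rigid-body fit of one conformer onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mad: float


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _convert_energy(value: float, unit: str) -> float:
    unit_n = unit.strip().lower()
    if unit_n not in _ENERGY_UNITS:
        raise EnsembleError(
            f"energy unit {unit!r} not recognized; declare 'kJ/mol' or 'hartree' "
            "explicitly (units are never guessed from magnitude)"
        )
    if unit_n in ("hartree", "au"):
        return value * HARTREE_TO_KJMOL
    return value


def read_energy_table(path: str | Path) -> dict[str, float]:
    """Read a sidecar CSV with columns conformer_id, energy, unit -> kJ/mol map."""
    energies: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"conformer_id", "energy", "unit"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise EnsembleError(
                f"{path}: energy table needs columns conformer_id, energy, unit"
            )
        for row in reader:
            energies[row["conformer_id"]] = _convert_energy(
                float(row["energy"]), row["unit"]
            )
    return energies


def _rereference(raw: dict[str, float]) -> dict[str, float]:
    emin = min(raw.values())
    return {k: v - emin for k, v in raw.items()}


def _parse_xyz_comment_energy(comment: str, lineno: int) -> tuple[float, str]:
    # expected form:  ... E= <value> <unit> ...
    tokens = comment.split()
    for i, tok in enumerate(tokens):
        if tok in ("E=", "e="):
            if i + 2 >= len(tokens) + 1 and i + 1 >= len(tokens):
                break
            try:
                value = float(tokens[i + 1])
            except (IndexError, ValueError) as exc:
                raise EnsembleError(
                    f"line {lineno}: cannot parse energy from comment {comment!r}"
                ) from exc
            if i + 2 >= len(tokens):
                raise EnsembleError(
                    f"line {lineno}: energy on comment line lacks a unit "
                    "(write 'E= <value> <unit>')"
                )
            return value, tokens[i + 2]
        if tok.startswith("E=") and len(tok) > 2:
            try:
                value = float(tok[2:])
            except ValueError as exc:
                raise EnsembleError(
                    f"line {lineno}: cannot parse energy from comment {comment!r}"
                ) from exc
            if i + 1 >= len(tokens):
                raise EnsembleError(f"line {lineno}: energy lacks a unit in {comment!r}")
            return value, tokens[i + 1]
    raise EnsembleError(
        f"line {lineno}: no 'E= <value> <unit>' energy found on comment line "
        f"{comment!r} and no sidecar energy table was given (energies are never "
        "defaulted to 0)"
    )


def _load_xyz_multi(path: Path, sidecar: dict[str, float] | None, ff_tag: str):
    lines = path.read_text().splitlines()
    conformers: list[tuple[str, list[str], np.ndarray, float | None]] = []
    i = 0
    block = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise EnsembleError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n >= len(lines) + 1:
            raise EnsembleError(f"{path}: truncated geometry block starting line {i + 1}")
        comment = lines[i + 1]
        block += 1
        conf_id = f"c{block}"
        # conformer id may be given as "id=<name>" on the comment line
        for tok in comment.split():
            if tok.startswith("id="):
                conf_id = tok[3:]
        energy: float | None = None
        if sidecar is None:
            value, unit = _parse_xyz_comment_energy(comment, i + 2)
            energy = _convert_energy(value, unit)
        elements: list[str] = []
        coords: list[list[float]] = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise EnsembleError(
                    f"{path}: line {i + 3 + j}: malformed atom line {lines[i + 2 + j]!r}"
                )
            elements.append(parts[0])
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise EnsembleError(
                    f"{path}: line {i + 3 + j}: non-numeric coordinate in "
                    f"{lines[i + 2 + j]!r}"
                ) from exc
        conformers.append((conf_id, elements, np.asarray(coords), energy))
        i += 2 + n
    if not conformers:
        raise EnsembleError(f"{path}: no geometry blocks found")
    return conformers


def _load_sdf(path: Path, energy_field: str, energy_unit: str, sidecar):
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit present in supported envs
        raise EnsembleError("reading SDF requires RDKit") from exc

    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for k, mol in enumerate(supplier):
        if mol is None:
            raise EnsembleError(f"{path}: unparseable molecule block #{k + 1}")
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.asarray(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        conf_id = name.strip() or f"c{k + 1}"
        energy: float | None = None
        if sidecar is None:
            if not mol.HasProp(energy_field):
                raise EnsembleError(
                    f"{path}: molecule #{k + 1} lacks energy property "
                    f"{energy_field!r} and no sidecar table was given"
                )
            energy = _convert_energy(float(mol.GetProp(energy_field)), energy_unit)
        out.append((conf_id, elements, coords, energy))
    if not out:
        raise EnsembleError(f"{path}: no molecules found")
    return out


def _load_csv_coords(path: Path, sidecar):
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"conformer_id", "atom_index", "element", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise EnsembleError(
                f"{path}: csv-coords needs columns conformer_id, atom_index, "
                "element, x, y, z"
            )
        for row in reader:
            rows.append(row)
    if not rows:
        raise EnsembleError(f"{path}: empty coordinate table")
    by_conf: dict[str, list] = {}
    order: list[str] = []
    for row in rows:
        cid = row["conformer_id"]
        if cid not in by_conf:
            by_conf[cid] = []
            order.append(cid)
        by_conf[cid].append(row)
    out = []
    for cid in order:
        group = sorted(by_conf[cid], key=lambda r: int(r["atom_index"]))
        elements = [r["element"] for r in group]
        coords = np.asarray([[float(r["x"]), float(r["y"]), float(r["z"])] for r in group])
        out.append((cid, elements, coords, None))
    if sidecar is None:
        raise EnsembleError(
            f"{path}: csv-coords carries no energies; provide a sidecar energy table"
        )
    return out


def load_ensemble(
    path: str | Path,
    fmt: str = "xyz-multi",
    *,
    molecule_id: str = "",
    candidate_id: str = "",
    ff_tag: str = "",
    energy_table: str | Path | None = None,
    sdf_energy_field: str = "rel_energy_kjmol",
    sdf_energy_unit: str = "kJ/mol",
) -> Ensemble:
    """Load a multi-conformer geometry file into an :class:`Ensemble`.

    Energies must be present in-file (XYZ comment line ``E= <value> <unit>``,
    SDF property block) or in a sidecar CSV (columns conformer_id, energy,
    unit); they are re-referenced so the minimum is 0 kJ/mol. Missing energies
    are an error, never silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = read_energy_table(energy_table) if energy_table is not None else None

    if fmt == "xyz-multi":
        raw = _load_xyz_multi(path, sidecar, ff_tag)
    elif fmt == "sdf":
        raw = _load_sdf(path, sdf_energy_field, sdf_energy_unit, sidecar)
    elif fmt == "csv-coords":
        raw = _load_csv_coords(path, sidecar)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    n_ref = len(raw[0][1])
    for cid, elements, coords, _ in raw:
        if len(elements) != n_ref:
            raise EnsembleError(
                f"{path}: conformer {cid!r} has {len(elements)} atoms, "
                f"expected {n_ref} (inconsistent atom counts)"
            )

    energies: dict[str, float] = {}
    for cid, _, _, energy in raw:
        if sidecar is not None:
            if cid not in sidecar:
                raise EnsembleError(f"{path}: conformer {cid!r} missing from energy table")
            energies[cid] = sidecar[cid]
        else:
            assert energy is not None
            energies[cid] = energy
    energies = _rereference(energies)

    conformers = [
        Conformer(cid, elements, coords, energies[cid], ff_tag=ff_tag)
        for cid, elements, coords, _ in raw
    ]
    return Ensemble(
        molecule_id=molecule_id or path.stem,
        candidate_id=candidate_id or path.stem,
        ff_tag=ff_tag,
        conformers=conformers,
    )


def write_xyz_multi(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as multi-XYZ with energies on the comment lines."""
    with open(path, "w") as fh:
        for c in ensemble:
            fh.write(f"{c.n_atoms}\n")
            fh.write(f"id={c.id} E= {c.rel_energy:.6f} kJ/mol\n")
            for el, (x, y, z) in zip(c.elements, c.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------


def apply_energy_window(e: Ensemble, cutoff: float) -> Ensemble:
    """Keep conformers with rel_energy <= cutoff (inclusive), order preserved.

    The boundary is inclusive so at-the-line conformers are never silently
    trimmed; the global minimum always survives.
    """
    if cutoff <= 0:
        raise ValueError("energy cutoff must be > 0")
    kept = [c for c in e if c.rel_energy <= cutoff]
    return e.with_conformers(kept)


def _subset_indices(a: Conformer, atom_subset: str) -> np.ndarray:
    if atom_subset == "all":
        return np.arange(a.n_atoms)
    idx = a.heavy_indices()
    if idx.size == 0:  # all-hydrogen corner case: fall back to every atom
        return np.arange(a.n_atoms)
    return idx


def superpose(a: Conformer, b: Conformer, atom_subset: str = "heavy") -> Superposition:
    """Kabsch least-squares fit of ``b`` onto ``a`` over the chosen atom subset.

    Returns the rotation/translation together with the post-alignment RMSD and
    MAD (maximum atom deviation) over the same subset. rmsd <= mad always.
    """
    if a.elements != b.elements:
        raise EnsembleError("superpose: conformers have different atom orderings")
    idx = _subset_indices(a, atom_subset)
    if idx.size < 3:
        raise GeometryError("superpose needs at least 3 subset atoms")
    P = a.coords[idx]
    Q = b.coords[idx]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: centered coordinates must span a plane
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise GeometryError("superpose: subset atoms are (near-)collinear")
    rot, _ = Rotation.align_vectors(Pc, Qc)
    R = rot.as_matrix()
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    diff = Pc - Qc @ R.T
    dists = np.linalg.norm(diff, axis=1)
    rmsd = float(np.sqrt(np.mean(dists**2)))
    mad = float(np.max(dists))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, mad=mad)


def pair_distance(a: Conformer, b: Conformer, method: str, atom_subset: str = "heavy") -> float:
    """MAD or RMSD between two conformers after best-fit superposition."""
    sup = superpose(a, b, atom_subset)
    return sup.mad if method.upper() == "MAD" else sup.rmsd


def deduplicate(e: Ensemble, cfg: DedupConfig) -> Ensemble:
    """Greedy redundancy elimination in ascending energy order.

    Conformers are visited from lowest to highest energy (ties broken by input
    order); one is discarded iff its MAD/RMSD distance to an already-retained
    conformer is strictly below ``cfg.geom_threshold``. The global minimum is
    always retained and the output is sorted by ascending energy.
    """
    order = sorted(range(len(e.conformers)), key=lambda i: (e.conformers[i].rel_energy, i))
    retained: list[Conformer] = []
    for i in order:
        cand = e.conformers[i]
        duplicate = False
        for kept in retained:
            if pair_distance(kept, cand, cfg.method, cfg.atom_subset) < cfg.geom_threshold:
                duplicate = True
                break
        if not duplicate:
            retained.append(cand)
    return e.with_conformers(retained)


def curate(e: Ensemble, cfg: DedupConfig) -> Ensemble:
    """Energy window then redundancy elimination, the standard curation order."""
    return deduplicate(apply_energy_window(e, cfg.energy_cutoff), cfg)


# ---------------------------------------------------------------------------
# Boltzmann weighting
# ---------------------------------------------------------------------------


def boltzmann_weights(
    e: Ensemble,
    energies: Mapping[str, float] | None = None,
    T: float = 298.0,
) -> BoltzmannWeights:
    """Boltzmann populations w_i = exp(-E_i/RT) / sum_j exp(-E_j/RT).

    ``energies`` (kJ/mol, relative) overrides the ensemble's own energies,
    e.g. to use single-point energies computed at a different level on the
    same geometries. Computed with the max-shift trick so large energy gaps
    cannot overflow.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if energies is None:
        energies = {c.id: c.rel_energy for c in e}
    else:
        missing = [c.id for c in e if c.id not in energies]
        if missing:
            raise EnsembleError(f"energies missing for conformers {missing}")
    ids = e.conformer_ids()
    ev = np.asarray([energies[cid] for cid in ids], dtype=float)
    if not np.all(np.isfinite(ev)):
        raise ValueError("non-finite energy")
    beta = 1000.0 / (GAS_CONSTANT_J * T)  # kJ/mol -> dimensionless
    x = -ev * beta
    x -= x.max()
    w = np.exp(x)
    w /= w.sum()
    return BoltzmannWeights(weights=dict(zip(ids, w.tolist())), temperature=T)


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def measure_dihedral(c: Conformer, atoms: Sequence[int]) -> float:
    """Signed dihedral (degrees, IUPAC convention) over four 1-based atoms.

    Range is (-180, 180]. Raises :class:`GeometryError` if three consecutive
    atoms are collinear, where the dihedral is undefined.
    """
    if len(atoms) != 4 or len(set(atoms)) != 4:
        raise ValueError("measure_dihedral needs 4 distinct atom indices")
    for idx in atoms:
        if not 1 <= idx <= c.n_atoms:
            raise EnsembleError(f"atom index {idx} outside 1..{c.n_atoms}")
    p = c.coords[[i - 1 for i in atoms]]
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise GeometryError("three consecutive atoms are collinear; dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle
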