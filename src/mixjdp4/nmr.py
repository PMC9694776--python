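"""NMR observable assembly: Boltzmann-averaged shieldings, TMS referencing,
linear scaling against experiment, coupling rescale, and error diagnostics.

Chemical shifts are assembled in three steps. Per-conformer isotropic
shieldings sigma_i^x are population-averaged into sigma_x; unscaled shifts
follow from a reference standard as delta_u = sigma_0 - sigma_x; scaled
shifts come from an ordinary least-squares fit of delta_u against the
experimental shifts, delta_s = (delta_u - b)/m. The regression absorbs any
systematic affine distortion of the raw predictions, which is what makes the
resulting errors comparable across force fields.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ensemble import BoltzmannWeights

__all__ = [
    "ShieldingTable",
    "CouplingTable",
    "ReferenceStandard",
    "Signal",
    "CouplingObservation",
    "ExperimentalData",
    "PredictionDiagnostics",
    "ScalingResult",
    "J_SCALING_PROFILES",
    "average_shieldings",
    "unscaled_shifts",
    "group_average",
    "scale_shifts",
    "scale_couplings",
    "prediction_diagnostics",
    "max_delta_sigma",
    "read_shielding_table",
    "read_coupling_table",
    "read_experimental_data",
    "read_qc_log",
]


class NMRConsistencyError(ValueError):
    """Mismatch between shielding tables, weights, and experimental data."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class ShieldingTable:
    """Per-(conformer, nucleus) isotropic shieldings in ppm.

    sigmas maps conformer id -> {1-based atom index -> sigma}; elements maps
    atom index -> element symbol. All conformers must report the same nuclei.
    """

    sigmas: dict[str, dict[int, float]]
    elements: dict[int, str]

    def __post_init__(self) -> None:
        if not self.sigmas:
            raise NMRConsistencyError("empty shielding table")
        ref = None
        for cid, row in self.sigmas.items():
            keys = set(row)
            if ref is None:
                ref = keys
            elif keys != ref:
                raise NMRConsistencyError(
                    f"conformer {cid!r} reports different nuclei than the others"
                )
            for idx, sigma in row.items():
                if not np.isfinite(sigma):
                    raise NMRConsistencyError(
                        f"non-finite shielding for conformer {cid!r}, atom {idx}"
                    )
        for idx in ref or ():
            if idx not in self.elements:
                raise NMRConsistencyError(f"no element recorded for atom {idx}")

    def conformer_ids(self) -> list[str]:
        return list(self.sigmas)

    def nuclei(self) -> list[int]:
        return sorted(next(iter(self.sigmas.values())))


@dataclass
class CouplingTable:
    """Per-(conformer, proton pair) computed 3JHH couplings in Hz."""

    couplings: dict[str, dict[tuple[int, int], float]]

    def conformer_ids(self) -> list[str]:
        return list(self.couplings)

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(next(iter(self.couplings.values())))


@dataclass(frozen=True)
class ReferenceStandard:
    """TMS shieldings computed at the same level of theory as the ensemble.

    Never defaulted: sigma_0 depends on the level of theory, so the values
    must be supplied explicitly alongside the shielding data.
    """

    sigma0_H: float
    sigma0_C: float
    provenance: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma0_H) and np.isfinite(self.sigma0_C)):
            raise ValueError("reference shieldings must be finite")
        if not self.provenance:
            raise ValueError("reference standard needs a provenance string")

    def sigma0(self, element: str) -> float:
        el = element.upper()
        if el == "H":
            return self.sigma0_H
        if el == "C":
            return self.sigma0_C
        raise NMRConsistencyError(f"no reference shielding for element {element!r}")


@dataclass(frozen=True)
class Signal:
    """One experimental shift signal: equivalent nuclei sharing a resonance."""

    signal_id: str
    element: str
    atom_indices: tuple[int, ...]
    delta_exp: float

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError(f"signal {self.signal_id!r}: empty atom group")


@dataclass(frozen=True)
class CouplingObservation:
    """One experimental 3JHH value with the dihedral it reports on."""

    pair_id: str
    h1: int
    h2: int
    dihedral_atoms: tuple[int, int, int, int]
    j_exp: float
    use_for_filter: bool = True

    def __post_init__(self) -> None:
        if self.j_exp < 0:
            raise ValueError(f"coupling {self.pair_id!r}: J_exp must be >= 0")

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.h1, self.h2)))  # type: ignore[return-value]


@dataclass
class ExperimentalData:
    """Assigned experimental shifts (with equivalence groups) and couplings."""

    shifts: list[Signal] = field(default_factory=list)
    couplings: list[CouplingObservation] = field(default_factory=list)
    #: pairs of signal_ids whose experimental assignment may be interchanged
    #: (diastereotopic protons); the error-minimizing pairing is used per
    #: candidate when resolving errors.
    swappable: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for element in ("H", "C"):
            seen: set[int] = set()
            for s in self.signals(element):
                overlap = seen.intersection(s.atom_indices)
                if overlap:
                    raise NMRConsistencyError(
                        f"atom(s) {sorted(overlap)} appear in more than one "
                        f"{element} signal group"
                    )
                seen.update(s.atom_indices)

    def signals(self, element: str) -> list[Signal]:
        return [s for s in self.shifts if s.element.upper() == element.upper()]

    def filtering_couplings(self) -> list[CouplingObservation]:
        return [c for c in self.couplings if c.use_for_filter]


@dataclass
class PredictionDiagnostics:
    """Per-channel error summary of a scaled prediction."""

    cmae: float
    max_err: float
    errors: np.ndarray

    def __post_init__(self) -> None:
        if self.cmae > self.max_err + 1e-12:
            raise ValueError("CMAE cannot exceed MaxErr")


@dataclass
class ScalingResult:
    """Outcome of the linear rescale of predicted against experimental shifts."""

    slope: float
    intercept: float
    delta_scaled: np.ndarray
    scaled: bool  # False when too few points to regress; delta_u passed through


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def average_shieldings(tbl: ShieldingTable, w: BoltzmannWeights) -> dict[int, float]:
    """Population-weighted shielding per nucleus: sigma_x = sum_i w_i sigma_i^x."""
    tbl_ids = set(tbl.sigmas)
    w_ids = set(w.weights)
    if tbl_ids != w_ids:
        raise NMRConsistencyError(
            f"weights and shielding table cover different conformers: "
            f"only-in-table={sorted(tbl_ids - w_ids)}, only-in-weights={sorted(w_ids - tbl_ids)}"
        )
    nuclei = tbl.nuclei()
    out = {n: 0.0 for n in nuclei}
    for cid, row in tbl.sigmas.items():
        wi = w.weights[cid]
        for n in nuclei:
            out[n] += wi * row[n]
    return out


def unscaled_shifts(
    sigma_x: Mapping[int, float],
    elements: Mapping[int, str],
    ref: ReferenceStandard,
) -> dict[int, float]:
    """delta_u = sigma_0(element) - sigma_x, per nucleus."""
    return {n: ref.sigma0(elements[n]) - s for n, s in sigma_x.items()}


def group_average(
    delta: Mapping[int, float], signals: Sequence[Signal]
) -> np.ndarray:
    """Average computed shifts within each experimental equivalence group.

    Returns one value per signal, in the order of ``signals`` (the
    experimental file order); experimental signals, not individual nuclei,
    are the unit of comparison downstream.
    """
    out = np.empty(len(signals))
    for k, s in enumerate(signals):
        missing = [i for i in s.atom_indices if i not in delta]
        if missing:
            raise NMRConsistencyError(
                f"signal {s.signal_id!r} references nuclei {missing} absent "
                "from the computed shifts"
            )
        out[k] = float(np.mean([delta[i] for i in s.atom_indices]))
    return out


def scale_shifts(delta_u: np.ndarray, delta_exp: np.ndarray) -> ScalingResult:
    """OLS of delta_u against delta_exp; returns slope m, intercept b and
    delta_s = (delta_u - b)/m.

    The regression runs with the experimental shifts on the abscissa. With
    fewer than 3 signals the rescale is refused and delta_u is passed through
    with ``scaled=False``.
    """
    delta_u = np.asarray(delta_u, dtype=float)
    delta_exp = np.asarray(delta_exp, dtype=float)
    if delta_u.shape != delta_exp.shape:
        raise NMRConsistencyError("delta_u and delta_exp length mismatch")
    n = delta_u.size
    if n < 3:
        return ScalingResult(1.0, 0.0, delta_u.copy(), scaled=False)
    if np.ptp(delta_exp) == 0:
        raise NMRConsistencyError("experimental shifts have zero variance; cannot scale")
    m, b = np.polyfit(delta_exp, delta_u, 1)
    if m == 0:
        raise NMRConsistencyError("degenerate regression: zero slope")
    return ScalingResult(float(m), float(b), (delta_u - b) / m, scaled=True)


#: Named linear rescales J_scaled = a * J_fc + c for Fermi-contact-only
#: couplings. The "jdp4-2019" constants follow the multiplicative rescale
#: recommended by the J-DP4 authors for B3LYP/6-31G** FC couplings
#: (approximate; override via a custom profile if your level differs).
J_SCALING_PROFILES: dict[str, tuple[float, float]] = {
    "identity": (1.0, 0.0),
    "jdp4-2019": (1.0709, 0.0),
}


def scale_couplings(
    j_fc: np.ndarray | Mapping, profile: str = "jdp4-2019"
):
    """Linear rescale of Fermi-contact couplings, J = a*J_fc + c."""
    if profile not in J_SCALING_PROFILES:
        raise KeyError(
            f"unknown J scaling profile {profile!r}; "
            f"available: {sorted(J_SCALING_PROFILES)}"
        )
    a, c = J_SCALING_PROFILES[profile]
    if isinstance(j_fc, Mapping):
        return {k: a * v + c for k, v in j_fc.items()}
    return a * np.asarray(j_fc, dtype=float) + c


def prediction_diagnostics(
    delta_s: np.ndarray, delta_exp: np.ndarray
) -> PredictionDiagnostics:
    """Signed errors e_j = delta_s - delta_exp with CMAE and MaxErr."""
    delta_s = np.asarray(delta_s, dtype=float)
    delta_exp = np.asarray(delta_exp, dtype=float)
    if delta_s.shape != delta_exp.shape:
        raise NMRConsistencyError("prediction/experiment length mismatch")
    if delta_s.size == 0:
        raise NMRConsistencyError("no signals to diagnose")
    errors = delta_s - delta_exp
    return PredictionDiagnostics(
        cmae=float(np.mean(np.abs(errors))),
        max_err=float(np.max(np.abs(errors))),
        errors=errors,
    )


def max_delta_sigma(
    tables: Sequence[Mapping[int, float]], nuclei: Sequence[int] | None = None
) -> tuple[dict[int, float], dict[str, float]]:
    """Across-force-field spread max(sigma) - min(sigma) per nucleus.

    ``tables`` holds one per-nucleus map per force field (shieldings, or
    scaled shifts for the MaxDeltaDelta variant). Returns the per-nucleus
    spread and a (min, max, mean) summary.
    """
    if len(tables) < 2:
        raise NMRConsistencyError("need at least two force-field tables")
    if nuclei is None:
        nuclei = sorted(tables[0])
    spread: dict[int, float] = {}
    for n in nuclei:
        vals = []
        for k, t in enumerate(tables):
            if n not in t:
                raise NMRConsistencyError(f"nucleus {n} missing from table #{k + 1}")
            vals.append(t[n])
        spread[n] = float(max(vals) - min(vals))
    arr = np.asarray(list(spread.values()))
    summary = {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
    }
    return spread, summary


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------


def read_shielding_table(path: str | Path) -> ShieldingTable:
    """CSV with columns conformer_id, atom_index (1-based), element, sigma_ppm."""
    sigmas: dict[str, dict[int, float]] = {}
    elements: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"conformer_id", "atom_index", "element", "sigma_ppm"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise NMRConsistencyError(
                f"{path}: shielding table needs columns conformer_id, "
                "atom_index, element, sigma_ppm"
            )
        for row in reader:
            cid = row["conformer_id"]
            idx = int(row["atom_index"])
            sigmas.setdefault(cid, {})[idx] = float(row["sigma_ppm"])
            elements[idx] = row["element"]
    return ShieldingTable(sigmas=sigmas, elements=elements)


def read_coupling_table(path: str | Path) -> CouplingTable:
    """CSV with columns conformer_id, h1, h2, j_fc_hz."""
    couplings: dict[str, dict[tuple[int, int], float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"conformer_id", "h1", "h2", "j_fc_hz"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise NMRConsistencyError(
                f"{path}: coupling table needs columns conformer_id, h1, h2, j_fc_hz"
            )
        for row in reader:
            pair = tuple(sorted((int(row["h1"]), int(row["h2"]))))
            couplings.setdefault(row["conformer_id"], {})[pair] = float(row["j_fc_hz"])
    return CouplingTable(couplings=couplings)


def read_experimental_data(
    shifts_path: str | Path, couplings_path: str | Path | None = None
) -> ExperimentalData:
    """Read experimental shift and (optionally) coupling tables.

    Shifts CSV: signal_id, element, atom_indices (semicolon-separated,
    1-based), delta_exp_ppm. Couplings CSV: pair_id, h1, h2, dihedral_atoms
    (4 semicolon-separated indices), J_exp_hz, and an optional use_for_filter
    column (1/0/true/false).
    """
    shifts: list[Signal] = []
    with open(shifts_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"signal_id", "element", "atom_indices", "delta_exp_ppm"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise NMRConsistencyError(
                f"{shifts_path}: shifts table needs columns signal_id, element, "
                "atom_indices, delta_exp_ppm"
            )
        for row in reader:
            indices = tuple(int(t) for t in row["atom_indices"].split(";") if t)
            shifts.append(
                Signal(
                    signal_id=row["signal_id"],
                    element=row["element"],
                    atom_indices=indices,
                    delta_exp=float(row["delta_exp_ppm"]),
                )
            )
    couplings: list[CouplingObservation] = []
    if couplings_path is not None:
        with open(couplings_path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"pair_id", "h1", "h2", "dihedral_atoms", "J_exp_hz"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise NMRConsistencyError(
                    f"{couplings_path}: couplings table needs columns pair_id, "
                    "h1, h2, dihedral_atoms, J_exp_hz"
                )
            for row in reader:
                dihedral = tuple(int(t) for t in row["dihedral_atoms"].split(";") if t)
                if len(dihedral) != 4:
                    raise NMRConsistencyError(
                        f"{couplings_path}: pair {row['pair_id']!r} needs 4 "
                        "dihedral atoms"
                    )
                flag = row.get("use_for_filter", "1").strip().lower()
                couplings.append(
                    CouplingObservation(
                        pair_id=row["pair_id"],
                        h1=int(row["h1"]),
                        h2=int(row["h2"]),
                        dihedral_atoms=dihedral,  # type: ignore[arg-type]
                        j_exp=float(row["J_exp_hz"]),
                        use_for_filter=flag in ("1", "true", "yes"),
                    )
                )
    return ExperimentalData(shifts=shifts, couplings=couplings)


_GIAO_RE = re.compile(
    r"^\s*(\d+)\s+([A-Za-z]{1,2})\s+Isotropic\s*=\s*(-?\d+\.\d+)", re.M
)
_FC_RE = re.compile(r"Fermi Contact \(FC\) contribution to J", re.I)


def read_qc_log(path: str | Path) -> tuple[dict[int, float], dict[int, str]]:
    """Tolerant scan of a quantum-chemistry output for GIAO isotropic values.

    Returns (atom index -> sigma, atom index -> element). Raises a clear
    error pointing at the CSV interchange format when nothing is found.
    """
    text = Path(path).read_text(errors="replace")
    sigmas: dict[int, float] = {}
    elements: dict[int, str] = {}
    for m in _GIAO_RE.finditer(text):
        idx = int(m.group(1))
        sigmas[idx] = float(m.group(3))
        elements[idx] = m.group(2)
    if not sigmas:
        raise NMRConsistencyError(
            f"{path}: no GIAO isotropic shieldings recognized; export the values "
            "to the CSV interchange format (conformer_id, atom_index, element, "
            "sigma_ppm) instead"
        )
    return sigmas, elements
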