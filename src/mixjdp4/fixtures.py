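"""Synthetic ground-truthed fixtures for the whole assignment pipeline.

Real inputs to this package come from force-field conformational searches
and DFT NMR calculations. This module fabricates statistically equivalent
stand-ins with every intermediate recorded, so each pipeline stage can be
tested against a known truth without any quantum-chemistry run:

* geometries: a self-avoiding 3-D chain whose rotatable "reporter" dihedral
  is set to rotamer states (-60/60/180 degrees plus jitter), with Cartesian
  noise emulating force-field geometry differences;
* shieldings: affine-encoded true shifts (sigma = sigma0 - (m*delta + b))
  plus optional per-conformer offsets, so Boltzmann averaging matters;
* couplings: per-conformer Karplus values of the measured dihedrals;
* experimental data: the true candidate's observables plus Student-t noise
  from the configured error model; wrong candidates carry location-shifted
  and/or scale-inflated predictions.

Energetics and Karplus chemistry here are statistical stand-ins, not
physical force-field output. All randomness flows through
``numpy.random.default_rng`` (PCG64) from a mandatory integer seed; no
wall-clock seeding.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ensemble import (
    Conformer,
    Ensemble,
    GAS_CONSTANT_J,
    measure_dihedral,
    write_xyz_multi,
)
from .nmr import (
    CouplingObservation,
    CouplingTable,
    ExperimentalData,
    J_SCALING_PROFILES,
    ReferenceStandard,
    ShieldingTable,
    Signal,
)
from .probability import ERROR_MODEL_PROFILES, ErrorModel, karplus_j, resolve_error_model

__all__ = [
    "FixtureSpec",
    "FixtureData",
    "make_scaffold",
    "make_ensemble",
    "make_nmr_data",
    "make_fixture",
    "make_mix_fixture",
    "write_demo_bundle",
]

#: Typical B3LYP-quality TMS shieldings; stand-in reference for fixtures.
FIXTURE_REFERENCE = ReferenceStandard(
    sigma0_H=31.8, sigma0_C=189.7, provenance="synthetic fixture reference"
)

_ROTAMER_STATES = (-60.0, 60.0, 180.0)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic system.

    Defaults emulate the recommended working regime: two candidate
    diastereomers, conformer counts and an energy spread matching a
    12 kJ/mol window, Cartesian perturbations at the 0.02 angstrom scale of
    typical inter-force-field geometry differences, and t-distributed
    experimental noise from the jdp4-2019 error model with wrong candidates
    shifted by 2 channel-sigmas per signal.
    """

    seed: int
    n_candidates: int = 2
    n_conformers: int = 6
    n_decoys: int = 2  # extra conformers at rotamers inconsistent with J_exp
    n_H_signals: int = 6
    n_C_signals: int = 10
    n_couplings: int = 1
    perturbation: float = 0.02  # angstrom Cartesian noise
    energy_spread: float = 12.0  # kJ/mol
    error_model: str | ErrorModel = "jdp4-2019"
    inflation_shift: float = 2.0  # wrong-candidate location shift, channel sigmas
    inflation_scale: float = 1.0  # wrong-candidate extra spread multiplier
    karplus_profile: str = "classic"
    j_scaling: str = "jdp4-2019"
    true_state: float = 180.0  # reporter dihedral of the J-consistent rotamer
    decoy_states: tuple[float, ...] = (-60.0, 60.0)
    rotamer_jitter: float = 5.0  # degrees
    sigma_spread: float = 0.0  # per-conformer shift offsets, channel sigmas
    decoy_offset_scale: float = 1.0  # extra decoy shift offset, channel sigmas
    noise_target: str = "experimental"  # or "shieldings"
    include_duplicates: bool = False
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.n_candidates < 1 or self.n_conformers < 1:
            raise ValueError("counts must be >= 1")
        if self.n_H_signals < 1 or self.n_C_signals < 1:
            raise ValueError("need at least one signal per channel")
        if self.perturbation < 0 or self.energy_spread < 0:
            raise ValueError("perturbation and energy spread must be >= 0")
        if self.noise_target not in ("experimental", "shieldings"):
            raise ValueError("noise_target must be 'experimental' or 'shieldings'")

    @property
    def n_atoms(self) -> int:
        return max(4, self.n_H_signals + self.n_C_signals, self.n_couplings + 3)


@dataclass
class FixtureData:
    """A complete synthetic input set with its ground truth."""

    spec: FixtureSpec
    ensembles: dict[str, Ensemble]
    shieldings: dict[str, ShieldingTable]
    couplings: dict[str, CouplingTable]
    exp: ExperimentalData
    reference: ReferenceStandard
    truth: dict


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Internal-coordinate (NeRF) placement of the next chain atom."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(phi),
         bond * np.sin(theta) * np.sin(phi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_scaffold(n_atoms: int, seed: int) -> Conformer:
    """Deterministic self-avoiding 3-D chain with 1.5-angstrom bonds,
    tetrahedral angles, and random backbone dihedrals."""
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms for a rotatable dihedral")
    rng = np.random.default_rng(seed)
    bond, angle = 1.5, 109.47
    coords = np.zeros((n_atoms, 3))
    coords[1] = (bond, 0.0, 0.0)
    th = np.radians(180.0 - angle)
    coords[2] = coords[1] + bond * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(3, n_atoms):
        for _ in range(200):
            phi = float(rng.choice(_ROTAMER_STATES) + rng.normal(0, 10.0))
            pos = _place_atom(coords[i - 3], coords[i - 2], coords[i - 1], bond, angle, phi)
            clash = np.linalg.norm(coords[: i - 1] - pos, axis=1).min() < 1.2
            if not clash:
                break
        coords[i] = pos
    return Conformer(
        id="scaffold", elements=["C"] * n_atoms, coords=coords, rel_energy=0.0
    )


def _rotate_about_axis(coords, origin, axis, angle_deg):
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    return (coords - origin) @ R.T + origin


def set_reporter_dihedral(coords: np.ndarray, target_deg: float) -> np.ndarray:
    """Rotate the chain tail (atoms 4..N) about bond 2-3 so the 1-2-3-4
    dihedral equals ``target_deg``."""
    probe = Conformer("probe", ["C"] * len(coords), coords, 0.0)
    current = measure_dihedral(probe, (1, 2, 3, 4))
    delta = target_deg - current
    out = coords.copy()
    axis = coords[2] - coords[1]
    out[3:] = _rotate_about_axis(coords[3:], coords[2], axis, delta)
    probe2 = Conformer("probe", ["C"] * len(coords), out, 0.0)
    if abs(_angdiff(measure_dihedral(probe2, (1, 2, 3, 4)), target_deg)) > 1e-6:
        out = coords.copy()
        out[3:] = _rotate_about_axis(coords[3:], coords[2], axis, -delta)
    return out


def _angdiff(a: float, b: float) -> float:
    d = (a - b) % 360.0
    return d - 360.0 if d > 180.0 else d


def make_ensemble(
    scaffold: Conformer,
    spec: FixtureSpec,
    *,
    candidate_id: str = "cand",
    ff_tag: str = "FFX",
    seed: int | None = None,
) -> tuple[Ensemble, dict[str, float]]:
    """Conformers from the scaffold: reporter-dihedral rotamers plus
    Cartesian noise and uniform energies in [0, energy_spread].

    Returns the ensemble and a map conformer id -> exact reporter dihedral
    (the per-conformer geometric truth). The first ``n_conformers`` sit at
    the J-consistent ``true_state``; ``n_decoys`` more are placed at the
    decoy rotamers.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    states = [spec.true_state] * spec.n_conformers
    for k in range(spec.n_decoys):
        states.append(spec.decoy_states[k % len(spec.decoy_states)])
    conformers: list[Conformer] = []
    dihedral_truth: dict[str, float] = {}
    energies = rng.uniform(0.0, spec.energy_spread, size=len(states))
    energies[0] = 0.0
    energies -= energies.min()
    for k, state in enumerate(states):
        target = state + rng.normal(0.0, spec.rotamer_jitter)
        coords = set_reporter_dihedral(scaffold.coords, target)
        coords = coords + rng.normal(0.0, spec.perturbation, size=coords.shape)
        cid = f"c{k + 1}"
        conf = Conformer(
            id=cid,
            elements=list(scaffold.elements),
            coords=coords,
            rel_energy=float(energies[k]),
            ff_tag=ff_tag,
        )
        conformers.append(conf)
        dihedral_truth[cid] = measure_dihedral(conf, (1, 2, 3, 4))
    if spec.include_duplicates:
        dup = copy.deepcopy(conformers[0])
        dup.id = "dup1"
        conformers.append(dup)
        dihedral_truth["dup1"] = dihedral_truth["c1"]
    ens = Ensemble(
        molecule_id="synthetic",
        candidate_id=candidate_id,
        ff_tag=ff_tag,
        conformers=conformers,
    )
    return ens, dihedral_truth


# ---------------------------------------------------------------------------
# NMR data
# ---------------------------------------------------------------------------


def _boltzmann(energies: np.ndarray, T: float) -> np.ndarray:
    x = -np.asarray(energies) * 1000.0 / (GAS_CONSTANT_J * T)
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


def make_nmr_data(
    ensembles: Mapping[str, Ensemble],
    spec: FixtureSpec,
    *,
    true_candidate: str | None = None,
    rng: np.random.Generator | None = None,
    shared_truth: dict | None = None,
) -> tuple[dict[str, ShieldingTable], dict[str, CouplingTable], ExperimentalData, dict]:
    """Shieldings, couplings and experimental tables consistent with a chosen
    true candidate, with every intermediate stored in the ground truth.

    ``shared_truth`` (from a previous call) reuses the true shifts and the
    experimental draws, so several force-field ensembles can share one
    experiment while keeping independent geometry-linked perturbations.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    model = resolve_error_model(spec.error_model)
    cand_ids = list(ensembles)
    true_candidate = true_candidate or cand_ids[0]
    if true_candidate not in ensembles:
        raise ValueError(f"true candidate {true_candidate!r} not among ensembles")

    nH, nC = spec.n_H_signals, spec.n_C_signals
    h_atoms = list(range(1, nH + 1))
    c_atoms = list(range(nH + 1, nH + nC + 1))
    sig_H, sig_C = model.channel("H").sigma, model.channel("C").sigma
    nu_H, nu_C = model.channel("H").nu, model.channel("C").nu
    a_j, c_j = J_SCALING_PROFILES[spec.j_scaling]

    if shared_truth is None:
        true_H = rng.uniform(0.8, 5.5, size=nH)
        true_C = rng.uniform(10.0, 95.0, size=nC)
        # affine encoding absorbed later by the regression
        coeffs = {"H": (1.02, 0.30), "C": (1.05, -2.0)}
        tnoise_H = model.channel("H").mu + sig_H * rng.standard_t(nu_H, size=nH)
        tnoise_C = model.channel("C").mu + sig_C * rng.standard_t(nu_C, size=nC)
    else:
        true_H = np.asarray(shared_truth["true_shifts"]["H"])
        true_C = np.asarray(shared_truth["true_shifts"]["C"])
        coeffs = {k: tuple(v) for k, v in shared_truth["encoding"].items()}
        tnoise_H = np.asarray(shared_truth["exp_noise"]["H"])
        tnoise_C = np.asarray(shared_truth["exp_noise"]["C"])

    elements = {i: "H" for i in h_atoms}
    elements.update({i: "C" for i in c_atoms})

    # couplings: first one on the reporter dihedral (filtering-grade),
    # extras on successive backbone dihedrals (dJ channel only)
    quads = [(1, 2, 3, 4)]
    for q in range(1, spec.n_couplings):
        quads.append((q + 1, q + 2, q + 3, q + 4))
    any_ens = ensembles[true_candidate]
    n_chain = any_ens.conformers[0].n_atoms
    quads = [q for q in quads if q[3] <= n_chain]

    shieldings: dict[str, ShieldingTable] = {}
    couplings: dict[str, CouplingTable] = {}
    truth: dict = {
        "seed": spec.seed,
        "rng": "numpy.random.default_rng (PCG64)",
        "true_candidate": true_candidate,
        "true_shifts": {"H": true_H.tolist(), "C": true_C.tolist()},
        "encoding": {k: list(v) for k, v in coeffs.items()},
        "exp_noise": {"H": tnoise_H.tolist(), "C": tnoise_C.tolist()},
        "per_candidate": {},
    }

    for cid in cand_ids:
        ens = ensembles[cid]
        conf_ids = ens.conformer_ids()
        n_conf = len(conf_ids)
        is_true = cid == true_candidate

        if is_true:
            shift_H, shift_C = np.zeros(nH), np.zeros(nC)
        else:
            signs_H = rng.choice((-1.0, 1.0), size=nH)
            signs_C = rng.choice((-1.0, 1.0), size=nC)
            extra = max(spec.inflation_scale**2 - 1.0, 0.0) ** 0.5
            shift_H = spec.inflation_shift * sig_H * signs_H + extra * sig_H * rng.standard_t(nu_H, size=nH)
            shift_C = spec.inflation_shift * sig_C * signs_C + extra * sig_C * rng.standard_t(nu_C, size=nC)

        # per-conformer offsets on the decoded shift scale (channel sigmas)
        off_H = spec.sigma_spread * sig_H * rng.normal(size=(n_conf, nH))
        off_C = spec.sigma_spread * sig_C * rng.normal(size=(n_conf, nC))
        for k, conf_id in enumerate(conf_ids):
            is_decoy = conf_id.startswith("c") and not conf_id.startswith("dup") and (
                int(conf_id[1:]) > spec.n_conformers
            )
            if is_decoy and spec.decoy_offset_scale > 0:
                off_H[k] += spec.decoy_offset_scale * sig_H * rng.normal(size=nH)
                off_C[k] += spec.decoy_offset_scale * sig_C * rng.normal(size=nC)

        if spec.noise_target == "shieldings":
            off_H += sig_H * rng.standard_t(nu_H, size=(n_conf, nH))
            off_C += sig_C * rng.standard_t(nu_C, size=(n_conf, nC))

        mH, bH = coeffs["H"]
        mC, bC = coeffs["C"]
        sigmas: dict[str, dict[int, float]] = {}
        for k, conf_id in enumerate(conf_ids):
            row: dict[int, float] = {}
            for j, atom in enumerate(h_atoms):
                delta = true_H[j] + shift_H[j] + off_H[k, j]
                row[atom] = FIXTURE_REFERENCE.sigma0_H - (mH * delta + bH)
            for j, atom in enumerate(c_atoms):
                delta = true_C[j] + shift_C[j] + off_C[k, j]
                row[atom] = FIXTURE_REFERENCE.sigma0_C - (mC * delta + bC)
            sigmas[conf_id] = row
        shieldings[cid] = ShieldingTable(sigmas=sigmas, elements=dict(elements))

        # per-conformer couplings from the actual measured dihedrals
        jrows: dict[str, dict[tuple[int, int], float]] = {}
        if is_true:
            jshift = np.zeros(len(quads))
        else:
            jshift = (
                spec.inflation_shift
                * model.channel("J").sigma
                * rng.choice((-1.0, 1.0), size=len(quads))
                if "J" in model.channels
                else np.zeros(len(quads))
            )
        for conf in ens:
            row_j: dict[tuple[int, int], float] = {}
            for qi, quad in enumerate(quads):
                theta = measure_dihedral(conf, quad)
                pair = tuple(sorted((quad[0], quad[3])))
                row_j[pair] = float(
                    karplus_j(theta, spec.karplus_profile) + jshift[qi]
                )
            jrows[conf.id] = row_j
        couplings[cid] = CouplingTable(couplings=jrows)

        # ground truth intermediates
        energies = np.asarray([c.rel_energy for c in ens])
        w_full = _boltzmann(energies, spec.temperature)
        consistent = [
            k
            for k, conf_id in enumerate(conf_ids)
            if abs(_angdiff(measure_dihedral(ens.conformers[k], (1, 2, 3, 4)),
                            spec.true_state)) <= 30.0
        ]
        w_cons = np.zeros(n_conf)
        w_cons[consistent] = w_full[consistent]
        w_cons = w_cons / w_cons.sum()
        avg_sigma = {
            atom: float(
                sum(w_full[k] * sigmas[conf_ids[k]][atom] for k in range(n_conf))
            )
            for atom in list(h_atoms) + list(c_atoms)
        }
        truth["per_candidate"][cid] = {
            "weights_full": dict(zip(conf_ids, w_full.tolist())),
            "weights_consistent": dict(zip(conf_ids, w_cons.tolist())),
            "consistent_conformers": [conf_ids[k] for k in consistent],
            "averaged_sigma_full": avg_sigma,
            "prediction_shift": {"H": shift_H.tolist(), "C": shift_C.tolist()},
        }

    # experimental data: the true candidate's truth plus t noise
    exp_H = true_H + (tnoise_H if spec.noise_target == "experimental" else 0.0)
    exp_C = true_C + (tnoise_C if spec.noise_target == "experimental" else 0.0)
    signals = [
        Signal(f"H{j + 1}", "H", (h_atoms[j],), float(exp_H[j])) for j in range(nH)
    ] + [
        Signal(f"C{j + 1}", "C", (c_atoms[j],), float(exp_C[j])) for j in range(nC)
    ]

    obs: list[CouplingObservation] = []
    if quads and "J" in model.channels:
        ens_t = ensembles[true_candidate]
        conf_ids_t = ens_t.conformer_ids()
        info = truth["per_candidate"][true_candidate]
        w_cons_t = np.asarray([info["weights_consistent"][i] for i in conf_ids_t])
        if shared_truth is None:
            jnoise = model.channel("J").sigma * rng.standard_t(
                model.channel("J").nu, size=len(quads)
            )
        else:
            jnoise = np.asarray(shared_truth["exp_noise"]["J"])[: len(quads)]
        truth["exp_noise"]["J"] = jnoise.tolist()
        for qi, quad in enumerate(quads):
            j_cons = float(
                sum(
                    w_cons_t[k]
                    * couplings[true_candidate].couplings[conf_ids_t[k]][
                        tuple(sorted((quad[0], quad[3])))
                    ]
                    for k in range(len(conf_ids_t))
                )
            )
            j_exp = a_j * j_cons + c_j + float(jnoise[qi])
            obs.append(
                CouplingObservation(
                    pair_id=f"J{qi + 1}",
                    h1=quad[0],
                    h2=quad[3],
                    dihedral_atoms=quad,
                    j_exp=max(j_exp, 0.0),
                    use_for_filter=(qi == 0),
                )
            )
        truth["j_exp_pre_noise"] = [
            float(o.j_exp - jnoise[qi]) for qi, o in enumerate(obs)
        ]

    exp = ExperimentalData(shifts=signals, couplings=obs)
    return shieldings, couplings, exp, truth


# ---------------------------------------------------------------------------
# One-shot builders
# ---------------------------------------------------------------------------


def make_fixture(spec: FixtureSpec, ff_tag: str = "FFX") -> FixtureData:
    """Complete single-force-field system: ensembles for every candidate
    (shared geometry, candidate-specific NMR tables), experimental data and
    ground truth."""
    scaffold = make_scaffold(spec.n_atoms, spec.seed)
    cand_ids = [f"cand{k + 1}" for k in range(spec.n_candidates)]
    ensembles: dict[str, Ensemble] = {}
    base, dihedrals = make_ensemble(
        scaffold, spec, candidate_id=cand_ids[0], ff_tag=ff_tag
    )
    for cid in cand_ids:
        e = copy.deepcopy(base)
        e.candidate_id = cid
        ensembles[cid] = e
    shieldings, couplings, exp, truth = make_nmr_data(ensembles, spec)
    truth["reporter_dihedrals"] = dihedrals
    return FixtureData(
        spec=spec,
        ensembles=ensembles,
        shieldings=shieldings,
        couplings=couplings,
        exp=exp,
        reference=FIXTURE_REFERENCE,
        truth=truth,
    )


def make_mix_fixture(
    spec: FixtureSpec, ff_tags: Sequence[str] = ("AMBER", "MM3", "MMFF")
) -> dict[str, FixtureData]:
    """Per-force-field fixtures sharing one experiment.

    Each force field gets independently jittered geometries, energies and
    conformer offsets (emulating force-field dependence); the true shifts
    and the experimental noise draw are shared, because there is only one
    experiment."""
    scaffold = make_scaffold(spec.n_atoms, spec.seed)
    cand_ids = [f"cand{k + 1}" for k in range(spec.n_candidates)]
    out: dict[str, FixtureData] = {}
    shared: dict | None = None
    for f, tag in enumerate(ff_tags):
        sub = np.random.default_rng(spec.seed * 1000 + 7 * f + 1)
        base, dihedrals = make_ensemble(
            scaffold, spec, candidate_id=cand_ids[0], ff_tag=tag,
            seed=int(sub.integers(2**31 - 1)),
        )
        ensembles: dict[str, Ensemble] = {}
        for cid in cand_ids:
            e = copy.deepcopy(base)
            e.candidate_id = cid
            ensembles[cid] = e
        rng = np.random.default_rng(spec.seed * 1000 + 7 * f + 3)
        shieldings, couplings, exp, truth = make_nmr_data(
            ensembles, spec, rng=rng, shared_truth=shared
        )
        if shared is None:
            shared = {
                "true_shifts": truth["true_shifts"],
                "encoding": truth["encoding"],
                "exp_noise": truth["exp_noise"],
            }
        truth["reporter_dihedrals"] = dihedrals
        out[tag] = FixtureData(
            spec=spec,
            ensembles=ensembles,
            shieldings=shieldings,
            couplings=couplings,
            exp=exp,
            reference=FIXTURE_REFERENCE,
            truth=truth,
        )
    return out


# ---------------------------------------------------------------------------
# Demo bundle on disk
# ---------------------------------------------------------------------------


def write_demo_bundle(outdir: str | Path, spec: FixtureSpec, ff_tag: str = "FFX") -> Path:
    """Write a ready-to-run worked example in the exact formats the loaders
    read (multi-XYZ, CSVs), plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = make_fixture(spec, ff_tag=ff_tag)
    for cid, ens in fx.ensembles.items():
        write_xyz_multi(ens, outdir / f"{cid}.xyz")
        tbl = fx.shieldings[cid]
        with open(outdir / f"{cid}_shieldings.csv", "w") as fh:
            fh.write("conformer_id,atom_index,element,sigma_ppm\n")
            for conf_id, row in tbl.sigmas.items():
                for atom, sigma in sorted(row.items()):
                    fh.write(f"{conf_id},{atom},{tbl.elements[atom]},{sigma:.6f}\n")
        with open(outdir / f"{cid}_couplings.csv", "w") as fh:
            fh.write("conformer_id,h1,h2,j_fc_hz\n")
            for conf_id, row in fx.couplings[cid].couplings.items():
                for (h1, h2), j in sorted(row.items()):
                    fh.write(f"{conf_id},{h1},{h2},{j:.6f}\n")
    with open(outdir / "experimental_shifts.csv", "w") as fh:
        fh.write("signal_id,element,atom_indices,delta_exp_ppm\n")
        for s in fx.exp.shifts:
            idx = ";".join(map(str, s.atom_indices))
            fh.write(f"{s.signal_id},{s.element},{idx},{s.delta_exp:.6f}\n")
    with open(outdir / "experimental_couplings.csv", "w") as fh:
        fh.write("pair_id,h1,h2,dihedral_atoms,J_exp_hz,use_for_filter\n")
        for c in fx.exp.couplings:
            quad = ";".join(map(str, c.dihedral_atoms))
            fh.write(
                f"{c.pair_id},{c.h1},{c.h2},{quad},{c.j_exp:.6f},"
                f"{int(c.use_for_filter)}\n"
            )
    with open(outdir / "reference.json", "w") as fh:
        json.dump(
            {
                "sigma0_H": fx.reference.sigma0_H,
                "sigma0_C": fx.reference.sigma0_C,
                "provenance": fx.reference.provenance,
            },
            fh,
            indent=2,
        )
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(fx.truth, fh, indent=2)
    with open(outdir / "fixture_spec.json", "w") as fh:
        spec_d = asdict(fx.spec)
        if isinstance(spec_d.get("error_model"), ErrorModel):
            spec_d["error_model"] = fx.spec.error_model.provenance  # type: ignore[union-attr]
        json.dump(spec_d, fh, indent=2, default=str)
    return outdir
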