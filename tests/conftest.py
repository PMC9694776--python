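"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
superposition is re-derived through an explicit SVD Kabsch, regression
through the normal equations, and the Student-t density through the
gamma-function formula.
"""

import math

import numpy as np
import pytest

from mixjdp4 import Conformer, Ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(20220699)


def make_conformer(coords, cid="c1", energy=0.0, elements=None, **kw):
    coords = np.asarray(coords, dtype=float)
    if elements is None:
        elements = ["C"] * len(coords)
    return Conformer(id=cid, elements=elements, coords=coords, rel_energy=energy, **kw)


def make_ensemble_from(coords_list, energies, candidate_id="cand", ff_tag="FFX"):
    energies = np.asarray(energies, dtype=float)
    energies = energies - energies.min()
    confs = [
        make_conformer(c, cid=f"c{i + 1}", energy=float(e))
        for i, (c, e) in enumerate(zip(coords_list, energies))
    ]
    return Ensemble("mol", candidate_id, ff_tag, confs)


def random_cloud(rng, n=10, scale=2.0):
    """Non-degenerate random 3-D point cloud."""
    while True:
        pts = rng.normal(0, scale, size=(n, 3))
        if np.linalg.matrix_rank(pts - pts.mean(axis=0)) == 3:
            return pts


def rigid_motion(rng):
    """A random proper rotation matrix and translation vector."""
    A = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(A)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(0, 5.0, size=3)
    return q, t


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def kabsch_oracle(P, Q):
    """Independent SVD Kabsch: aligns Q onto P, returns (rmsd, mad)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc - Qc @ R.T
    dist = np.linalg.norm(diff, axis=1)
    return float(np.sqrt(np.mean(dist**2))), float(np.max(dist))


def t_logpdf_oracle(x, nu):
    """Student-t log density from the gamma-function formula."""
    return (
        math.lgamma((nu + 1) / 2)
        - math.lgamma(nu / 2)
        - 0.5 * math.log(nu * math.pi)
        - (nu + 1) / 2 * math.log1p(x * x / nu)
    )


def normal_equations_oracle(x, y):
    """OLS slope/intercept of y against x via the closed-form normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = np.sum(x * x) - np.sum(x) ** 2 / n
    sxy = np.sum(x * y) - np.sum(x) * np.sum(y) / n
    m = sxy / sxx
    b = (np.sum(y) - m * np.sum(x)) / n
    return float(m), float(b)


def pairwise_distance_matrix(ensemble, method, atom_subset="heavy"):
    """All-pairs MAD/RMSD matrix computed with the independent Kabsch oracle."""
    confs = ensemble.conformers
    n = len(confs)
    heavy = [
        i for i, el in enumerate(confs[0].elements) if el.upper() not in ("H", "D")
    ] or list(range(confs[0].n_atoms))
    sel = heavy if atom_subset == "heavy" else list(range(confs[0].n_atoms))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd, mad = kabsch_oracle(confs[i].coords[sel], confs[j].coords[sel])
            D[i, j] = D[j, i] = mad if method.upper() == "MAD" else rmsd
    return D


def greedy_dedup_oracle(ensemble, method, threshold, atom_subset="heavy"):
    """Literal re-implementation of the greedy keep-first contract on an
    independently computed distance matrix. Returns retained conformer ids."""
    D = pairwise_distance_matrix(ensemble, method, atom_subset)
    order = sorted(
        range(len(ensemble.conformers)),
        key=lambda i: (ensemble.conformers[i].rel_energy, i),
    )
    kept: list[int] = []
    for i in order:
        if all(D[i, j] >= threshold for j in kept):
            kept.append(i)
    return [ensemble.conformers[i].id for i in kept]


def component_dedup_oracle(ensemble, method, threshold, atom_subset="heavy"):
    """Connected-component clustering: link pairs below threshold, keep the
    lowest-energy member of each component. May legitimately disagree with
    the greedy contract on chain-linked clusters."""
    D = pairwise_distance_matrix(ensemble, method, atom_subset)
    n = len(ensemble.conformers)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] < threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    kept = []
    for members in comps.values():
        best = min(members, key=lambda i: (ensemble.conformers[i].rel_energy, i))
        kept.append(best)
    return sorted(
        (ensemble.conformers[i].id for i in kept),
        key=lambda cid: next(
            (c.rel_energy, k)
            for k, c in enumerate(ensemble.conformers)
            if c.id == cid
        ),
    )
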