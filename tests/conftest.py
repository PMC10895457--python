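"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from allofluct import synthetic
from allofluct.ensemble import Structure


def make_chain_model(n: int, k: float = 4.0, sigma: float = 0.5, seed: int = 7,
                     extra=()) -> synthetic.HarmonicModel:
    """Harmonic chain of n Cα-like sites with nearest-neighbour springs."""
    couplings = [(i, i + 1, k) for i in range(n - 1)] + list(extra)
    return synthetic.HarmonicModel(
        synthetic.helical_coords(n), couplings, sigma=sigma, seed=seed
    )


@pytest.fixture
def chain8():
    return make_chain_model(8)


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 3-atom PDB with known coordinates."""
    text = (
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00\n"
        "ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00\n"
        "ATOM      3  CA  SER A   3       7.000   8.000   9.500  1.00  0.00\n"
        "END\n"
    )
    p = tmp_path / "tiny.pdb"
    p.write_text(text)
    return p


@pytest.fixture
def backbone_structure():
    """Three-residue structure with N/CA/C/O plus one side-chain atom."""
    names, resids, resnames = [], [], []
    for r in (1, 2, 3):
        for nm in ("N", "CA", "C", "O", "CB"):
            names.append(nm)
            resids.append(r)
            resnames.append("ALA")
    rng = np.random.default_rng(0)
    return Structure(
        chain_ids=np.array(["A"] * 15),
        resids=np.array(resids),
        resnames=np.array(resnames),
        atom_names=np.array(names),
        coords=rng.normal(0, 5, size=(15, 3)),
    )


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_df(frames: np.ndarray) -> np.ndarray:
    """Naive per-frame double-loop distance variance (population)."""
    f, n, _ = frames.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = np.array(
                [np.sqrt(((frames[t, i] - frames[t, j]) ** 2).sum()) for t in range(f)]
            )
            out[i, j] = ((d - d.mean()) ** 2).mean()
    return out


def quaternion_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Horn's closed-form quaternion superposition, independent of the
    SVD-based implementation under test.  Returns the fitted mobile."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(k)
    qw, qx, qy, qz = v[:, -1]
    rot = np.array(
        [
            [1 - 2 * (qy**2 + qz**2), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
            [2 * (qx * qy + qz * qw), 1 - 2 * (qx**2 + qz**2), 2 * (qy * qz - qx * qw)],
            [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx**2 + qy**2)],
        ]
    )
    return p @ rot.T + tc


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
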