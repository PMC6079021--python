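"""Cyclic-symmetry inference and ring model arithmetic.

A homodimer whose two chains are related by a rotation of 360/n degrees is
the asymmetric unit of a Cn ring.  :func:`dimer_symmetry` recovers that
rotation by least-squares (Kabsch) superposition, :func:`build_ring`
replicates a subunit n times about the axis, and the small arithmetic
helpers reproduce the ring bookkeeping used when fitting models into EM
densities: chord–tangent angles, mass-derived volumes, stoichiometry
estimates and sequence coverage.

The chord–tangent angle of a regular n-gon, theta(n) = 180/n degrees, is
the angle between a polygon side and the tangent of the circumscribed
circle; it measures the curvature a subunit interface must accommodate and
is insensitive to n for large rings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from coevoring.errors import CoevoringError, ParameterError
from coevoring.structure import ChainModel, Residue, StructureModel

CHAIN_ID_CYCLE = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True)
class DimerSymmetry:
    """Rigid rotation superposing chain A onto chain B of a homodimer."""

    angle: float  # degrees
    axis: np.ndarray  # unit vector
    axis_point: np.ndarray  # a point on the axis
    implied_order: int  # round(360 / angle)
    superposition_rmsd: float


@dataclass(frozen=True)
class RingModel:
    """n-fold symmetrised coordinates with axis and quality metrics."""

    n: int
    structure: StructureModel
    coordinates: np.ndarray  # (n, m, 3): n copies of the m subunit atoms
    axis: np.ndarray
    axis_point: np.ndarray
    symmetry_rmsd: float
    diameter: float
    clash_count: int


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform R, t with R P_i + t ~ Q_i; returns rmsd."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def dimer_symmetry(
    s: StructureModel, chain_a: str = "A", chain_b: str = "B", min_angle: float = 1.0
) -> DimerSymmetry:
    """Infer the cyclic relation between two chains of a homodimer.

    Chains are paired on shared author residue numbers; a rotation below
    ``min_angle`` degrees (a pure translation) raises
    :class:`CoevoringError` since no closed ring is implied.
    """
    ca, cb = s.chain(chain_a).by_number(), s.chain(chain_b).by_number()
    shared = sorted(set(ca) & set(cb))
    if len(shared) < 3:
        raise ParameterError(
            f"chains {chain_a}/{chain_b} share only {len(shared)} residues (need >= 3)"
        )
    P = np.array([ca[r].coord for r in shared])
    Q = np.array([cb[r].coord for r in shared])
    R, t, rmsd = _kabsch(P, Q)
    rot = Rotation.from_matrix(R)
    angle_rad = rot.magnitude()
    angle = float(np.degrees(angle_rad))
    if angle < min_angle:
        raise CoevoringError(
            f"chains are related by a near-pure translation (angle {angle:.3f} deg); "
            "no cyclic relation"
        )
    axis = rot.as_rotvec() / angle_rad
    # point on the axis: least-squares (min-norm) solution of (I - R) x = t
    axis_point, *_ = np.linalg.lstsq(np.eye(3) - R, t, rcond=None)
    return DimerSymmetry(
        angle=angle,
        axis=axis,
        axis_point=axis_point,
        implied_order=int(round(360.0 / angle)),
        superposition_rmsd=rmsd,
    )


def build_ring(
    s: StructureModel,
    n: int,
    axis: Sequence[float] | None = None,
    axis_point: Sequence[float] | None = None,
    clash_cutoff: float = 3.0,
) -> RingModel:
    """Replicate the subunit model at rotations k*360/n about the axis.

    The axis defaults to z through the origin (for pre-aligned models);
    pass the axis inferred by :func:`dimer_symmetry` otherwise.  Chain
    identifiers of the copies cycle through A–Z, a–z, 0–9.
    """
    if n <= 0:
        raise ParameterError("ring order n must be positive")
    axis = np.asarray(axis if axis is not None else [0.0, 0.0, 1.0], dtype=float)
    axis = axis / np.linalg.norm(axis)
    p0 = np.asarray(axis_point if axis_point is not None else [0.0, 0.0, 0.0], dtype=float)

    sub_coords = s.all_coords()
    chains: list[ChainModel] = []
    copies = np.empty((n, sub_coords.shape[0], 3))
    cid = 0
    for k in range(n):
        R = Rotation.from_rotvec(axis * (2.0 * np.pi * k / n)).as_matrix()
        copies[k] = (sub_coords - p0) @ R.T + p0
        for chain in s.chains:
            residues = [
                Residue(
                    number=r.number,
                    icode=r.icode,
                    aa=r.aa,
                    coord=(r.coord - p0) @ R.T + p0,
                )
                for r in chain.residues
            ]
            chains.append(
                ChainModel(id=CHAIN_ID_CYCLE[cid % len(CHAIN_ID_CYCLE)], residues=residues)
            )
            cid += 1
    ring_structure = StructureModel(chains=chains)

    # symmetry residual: rotating copy k by 360/n must reproduce copy k+1
    if n == 1:
        symmetry_rmsd = 0.0
    else:
        R1 = Rotation.from_rotvec(axis * (2.0 * np.pi / n)).as_matrix()
        errs = []
        for k in range(n):
            rotated = (copies[k] - p0) @ R1.T + p0
            errs.append(np.mean(np.sum((rotated - copies[(k + 1) % n]) ** 2, axis=1)))
        symmetry_rmsd = float(np.sqrt(np.mean(errs)))

    diameter, clash_count = _metrics(copies, axis, p0, clash_cutoff)
    return RingModel(
        n=n,
        structure=ring_structure,
        coordinates=copies,
        axis=axis,
        axis_point=p0,
        symmetry_rmsd=symmetry_rmsd,
        diameter=diameter,
        clash_count=clash_count,
    )


def _metrics(
    copies: np.ndarray, axis: np.ndarray, axis_point: np.ndarray, clash_cutoff: float
) -> tuple[float, int]:
    n, m, _ = copies.shape
    flat = copies.reshape(n * m, 3)
    rel = flat - axis_point
    radial = rel - np.outer(rel @ axis, axis)
    diameter = 2.0 * float(np.linalg.norm(radial, axis=1).max())

    # clash pairs between non-adjacent subunits; in rings of order <= 3
    # every distinct pair of subunits is checked since none is "distant"
    subunit = np.repeat(np.arange(n), m)
    tree = cKDTree(flat)
    clash = 0
    for a, b in tree.query_pairs(clash_cutoff):
        ka, kb = subunit[a], subunit[b]
        if ka == kb:
            continue
        ring_dist = min(abs(ka - kb), n - abs(ka - kb))
        if n >= 4 and ring_dist == 1:
            continue
        if np.linalg.norm(flat[a] - flat[b]) < clash_cutoff:
            clash += 1
    return diameter, clash


def ring_metrics(ring: RingModel, clash_cutoff: float = 3.0) -> tuple[float, int]:
    """Diameter (2 x max radial C-alpha distance) and non-adjacent clash count."""
    return _metrics(ring.coordinates, ring.axis, ring.axis_point, clash_cutoff)


# ---------------------------------------------------------------------------
# Ring arithmetic


def tangent_angle_delta(n1: int, n2: int) -> tuple[float, float, float]:
    """Chord–tangent angles (180/n degrees) of two ring orders and their
    absolute difference."""
    for n in (n1, n2):
        if n < 3:
            raise ParameterError(f"ring order {n} < 3 has no polygon tangent angle")
    t1, t2 = 180.0 / n1, 180.0 / n2
    return t1, t2, abs(t1 - t2)


def volume_from_mass(monomer_mw: float, copies: int, gamma: float = 1.28) -> float:
    """Protein volume in cubic angstroms from mass: V = mw x copies x gamma.

    ``gamma`` is the specific volume in A^3/Da; the default 1.28 reproduces
    the reference worked example (100 kDa 26-mer -> 3.33e6 A^3), while the
    common literature value 1.21 may be passed instead.
    """
    if monomer_mw <= 0 or copies <= 0 or gamma <= 0:
        raise ParameterError("mass, copy number and gamma must all be positive")
    return monomer_mw * copies * gamma


def estimate_stoichiometry(
    observed_volume: float, monomer_mw: float, coverage: float, gamma: float = 1.28
) -> tuple[float, int]:
    """Invert :func:`volume_from_mass` for the subunit count.

    ``coverage`` is the fraction of the monomer sequence present in the
    fitted models, correcting the per-copy volume; returns the real-valued
    estimate and its rounding.
    """
    if not 0.0 < coverage <= 1.0:
        raise ParameterError("coverage must be in (0, 1]")
    if observed_volume <= 0 or monomer_mw <= 0 or gamma <= 0:
        raise ParameterError("volume, mass and gamma must all be positive")
    n_hat = observed_volume / (coverage * monomer_mw * gamma)
    return n_hat, int(round(n_hat))


def sequence_coverage(
    segments: Sequence[tuple[int, int]], total_length: int
) -> float:
    """Fraction of a sequence covered by the union of 1-based inclusive
    intervals."""
    if total_length <= 0:
        raise ParameterError("total length must be positive")
    ivs = []
    for lo, hi in segments:
        if lo > hi:
            raise ParameterError(f"inverted interval ({lo}, {hi})")
        if lo < 1 or hi > total_length:
            raise ParameterError(f"interval ({lo}, {hi}) outside [1, {total_length}]")
        ivs.append((lo, hi))
    if not ivs:
        return 0.0
    ivs.sort()
    covered = 0
    cur_lo, cur_hi = ivs[0]
    for lo, hi in ivs[1:]:
        if lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            covered += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    covered += cur_hi - cur_lo + 1
    return covered / total_length
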