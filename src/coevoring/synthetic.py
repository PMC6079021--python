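"""Synthetic alignments with planted covarying columns and toy Cn rings.

The alignment generator emulates the statistical structure a coevolution
analysis assumes: per-column amino-acid profiles, redundancy from a small
number of founder lineages, uniform gaps, and K planted column pairs whose
residues are drawn jointly from a small set of chemically compatible
amino-acid combinations (ionic, polar and hydrophobic pairings in equal
measure) with a configurable coupling probability.  The joint draw is a
compatibility-set mixture rather than a full Potts sampler: exact, fast,
and the planted signal strength is directly controllable.

The ring generator places a compact self-avoiding C-alpha blob at n
rotations about the z axis; the cross-subunit contacts of adjacent copies
are recorded as ground-truth interface pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from coevoring.coevolution import Coupling
from coevoring.errors import ParameterError
from coevoring.msa import AMINO_ACIDS, GAP, Msa
from coevoring.structure import ChainModel, Residue, StructureModel

# chemically compatible residue pairings, one tuple list per class
_IONIC = [("D", "K"), ("E", "R"), ("D", "R"), ("E", "K"), ("K", "E"), ("R", "D")]
_POLAR = [("S", "T"), ("N", "Q"), ("T", "N"), ("Q", "S"), ("S", "N"), ("T", "Q")]
_HYDROPHOBIC = [("L", "I"), ("V", "F"), ("I", "V"), ("F", "L"), ("L", "V"), ("I", "F")]
_CLASSES = [_IONIC, _POLAR, _HYDROPHOBIC]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulation, reproducible from (params, seed)."""

    planted_pairs: list[tuple[int, int]]  # 1-based column positions, i < j
    coupling_prob: float
    params: dict = field(default_factory=dict)
    interface_pairs: list[tuple[str, int, str, int]] = field(default_factory=list)


def _compatible_combos(rng: np.random.Generator, k: int) -> list[tuple[str, str]]:
    """k compatible (a, b) combinations cycling the pairing classes equally."""
    combos: list[tuple[str, str]] = []
    offsets = [rng.permutation(len(cls)) for cls in _CLASSES]
    idx = [0, 0, 0]
    c = 0
    while len(combos) < k:
        cls = _CLASSES[c % 3]
        combo = cls[offsets[c % 3][idx[c % 3] % len(cls)]]
        idx[c % 3] += 1
        if combo not in combos:
            combos.append(combo)
        c += 1
    return combos


def default_planted_pairs(
    L: int, k: int, min_separation: int = 5, seed: int = 0
) -> list[tuple[int, int]]:
    """Draw k disjoint column pairs (1-based) respecting the separation rule."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for _ in range(10_000):
        if len(pairs) == k:
            break
        i, j = sorted(rng.choice(np.arange(1, L + 1), size=2, replace=False).tolist())
        if j - i < min_separation or i in used or j in used:
            continue
        pairs.append((i, j))
        used.update((i, j))
    if len(pairs) < k:
        raise ParameterError(f"cannot place {k} disjoint pairs in {L} columns")
    return sorted(pairs)


def simulate_msa(
    L: int = 50,
    N: int = 2000,
    planted_pairs: Sequence[tuple[int, int]] | None = None,
    coupling_prob: float = 0.9,
    n_compat_states: int = 3,
    gap_rate: float = 0.05,
    n_founders: int = 50,
    founder_divergence: float = 0.3,
    min_separation: int = 5,
    profile_concentration: float = 0.5,
    seed: int = 0,
) -> tuple[Msa, SyntheticTruth]:
    """Simulate an alignment with planted coevolving column pairs.

    Column positions in ``planted_pairs`` are 1-based.  For a planted pair,
    each sequence draws the two residues jointly from one of
    ``n_compat_states`` compatible combinations with probability
    ``coupling_prob``, and independently from the combination alphabet
    otherwise.  Background columns descend from ``n_founders`` founder
    sequences with per-site substitution probability
    ``founder_divergence`` (phylogenetic redundancy).  Gaps are inserted
    i.i.d. at ``gap_rate`` except in the reference (first) row, which stays
    gap-free so column numbering is the identity.
    """
    if not 0.0 <= coupling_prob <= 1.0:
        raise ParameterError("coupling_prob must be in [0, 1]")
    planted = [(int(i), int(j)) for i, j in (planted_pairs or [])]
    used: set[int] = set()
    for i, j in planted:
        if not (1 <= i < j <= L):
            raise ParameterError(f"planted pair ({i}, {j}) outside 1..{L}")
        if j - i < min_separation:
            raise ParameterError(f"planted pair ({i}, {j}) closer than min_separation")
        if i in used or j in used:
            raise ParameterError("planted pairs overlap")
        used.update((i, j))

    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(len(AMINO_ACIDS), profile_concentration), size=L)

    founders = np.empty((n_founders, L), dtype=np.int64)
    for c in range(L):
        founders[:, c] = rng.choice(len(AMINO_ACIDS), size=n_founders, p=profiles[c])
    lineage = rng.integers(0, n_founders, size=N)
    seqs = founders[lineage]
    resample = rng.random((N, L)) < founder_divergence
    for c in range(L):
        hit = resample[:, c]
        if hit.any():
            seqs[hit, c] = rng.choice(len(AMINO_ACIDS), size=int(hit.sum()), p=profiles[c])

    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    combos_per_pair: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for i, j in planted:
        combos = _compatible_combos(rng, n_compat_states)
        combos_per_pair[(i, j)] = combos
        a_states = np.array([aa_index[a] for a, _ in combos])
        b_states = np.array([aa_index[b] for _, b in combos])
        coupled = rng.random(N) < coupling_prob
        m_joint = rng.integers(0, n_compat_states, size=N)
        m_a = rng.integers(0, n_compat_states, size=N)
        m_b = rng.integers(0, n_compat_states, size=N)
        seqs[:, i - 1] = np.where(coupled, a_states[m_joint], a_states[m_a])
        seqs[:, j - 1] = np.where(coupled, b_states[m_joint], b_states[m_b])

    gapped = rng.random((N, L)) < gap_rate
    gapped[0, :] = False  # reference row stays gap-free
    alphabet = np.array(list(AMINO_ACIDS))
    chars = alphabet[seqs]
    chars[gapped] = GAP
    rows = ["".join(r) for r in chars]
    ids = [f"seq{k:05d}" for k in range(N)]
    msa = Msa(ids=ids, rows=rows, reference_id=ids[0])
    truth = SyntheticTruth(
        planted_pairs=sorted(planted),
        coupling_prob=coupling_prob,
        params={
            "L": L,
            "N": N,
            "n_compat_states": n_compat_states,
            "gap_rate": gap_rate,
            "n_founders": n_founders,
            "founder_divergence": founder_divergence,
            "seed": seed,
            "combos": {f"{i},{j}": combos_per_pair[(i, j)] for i, j in planted},
        },
    )
    return msa, truth


# ---------------------------------------------------------------------------
# Toy ring structures


def _random_blob(rng: np.random.Generator, m: int, spacing: float = 3.8,
                 min_dist: float = 3.0) -> np.ndarray:
    """Compact self-avoiding C-alpha chain of m residues around the origin."""
    r_max = spacing * m ** (1.0 / 3.0)
    coords = [np.zeros(3)]
    while len(coords) < m:
        for _ in range(200):
            direction = rng.normal(size=3)
            pos = coords[-1] + spacing * direction / np.linalg.norm(direction)
            if np.linalg.norm(pos) > r_max:
                # steer back toward the blob centre to keep it compact
                direction = -coords[-1] + rng.normal(size=3)
                pos = coords[-1] + spacing * direction / np.linalg.norm(direction)
            if all(np.linalg.norm(pos - q) >= min_dist for q in coords[:-1]):
                coords.append(pos)
                break
        else:
            raise ParameterError("could not grow a self-avoiding subunit; retry with another seed")
    blob = np.array(coords)
    return blob - blob.mean(axis=0)


def simulate_ring_structure(
    n: int = 13,
    radius: float | None = None,
    subunit_size: int = 30,
    seed: int = 0,
    contact_cutoff: float = 10.0,
    seq_random: bool = True,
) -> tuple[StructureModel, SyntheticTruth]:
    """A Cn ring of identical compact subunits with known interface pairs.

    One self-avoiding C-alpha blob is centred at (radius, 0, 0) and
    replicated at n rotations about z.  ``radius=None`` picks the smallest
    radius at which adjacent subunits touch without interpenetrating
    (adjacent centre spacing = 2.2 x blob radius).  Ground truth interface
    pairs are the cross-subunit C-alpha pairs strictly below
    ``contact_cutoff`` between adjacent copies; a radius small enough for
    non-adjacent copies to also touch raises :class:`ParameterError`.
    """
    if n < 3:
        raise ParameterError("ring order must be >= 3")
    rng = np.random.default_rng(seed)
    blob = _random_blob(rng, subunit_size)
    blob_radius = float(np.linalg.norm(blob, axis=1).max())

    from scipy.spatial.transform import Rotation

    R1 = Rotation.from_rotvec([0.0, 0.0, 2.0 * np.pi / n]).as_matrix()

    def copy_gap(r: float, k: int) -> float:
        """Min atom distance between copy 0 and copy k at ring radius r."""
        sub0 = blob + np.array([r, 0.0, 0.0])
        Rk = Rotation.from_rotvec([0.0, 0.0, 2.0 * np.pi * k / n]).as_matrix()
        subk = sub0 @ Rk.T
        d = np.linalg.norm(sub0[:, None, :] - subk[None, :, :], axis=2)
        return float(d.min())

    def adjacent_gap(r: float) -> float:
        return copy_gap(r, 1)

    def feasible(r: float) -> bool:
        # clash-free adjacent copies, non-adjacent copies beyond the cutoff
        if adjacent_gap(r) < 3.2:
            return False
        return all(copy_gap(r, k) > contact_cutoff + 0.5 for k in range(2, n // 2 + 1))

    if radius is None:
        # smallest radius with clash-free adjacent copies and isolated
        # non-adjacent copies; adjacent surfaces then sit in contact range
        lo, hi = blob_radius * 0.25, blob_radius * 30.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if feasible(mid):
                hi = mid
            else:
                lo = mid
        radius = hi
        if adjacent_gap(radius) >= contact_cutoff:
            raise ParameterError(
                "could not place adjacent subunits within contact range; "
                "retry with another seed or larger subunit"
            )
    elif adjacent_gap(radius) < 3.0:
        raise ParameterError(
            f"radius {radius:.1f} too small for subunit extent {blob_radius:.1f} "
            f"at n={n}: adjacent copies clash"
        )
    sub = blob + np.array([radius, 0.0, 0.0])
    if seq_random:
        seq = rng.choice(list(AMINO_ACIDS), size=subunit_size)
    else:
        seq = np.array(["A"] * subunit_size)

    from coevoring.rings import CHAIN_ID_CYCLE, build_ring

    subunit_model = StructureModel(
        chains=[
            ChainModel(
                id="A",
                residues=[
                    Residue(number=k + 1, icode="", aa=str(seq[k]), coord=sub[k])
                    for k in range(subunit_size)
                ],
            )
        ]
    )
    ring = build_ring(subunit_model, n)
    structure = ring.structure

    # ground truth from direct pairwise distances, independent of contact_map
    chain_ids = structure.chain_ids
    coords = [structure.chain(cid).coords() for cid in chain_ids]
    interface: list[tuple[str, int, str, int]] = []
    for ka in range(n):
        for kb in range(ka + 1, n):
            d = np.linalg.norm(coords[ka][:, None, :] - coords[kb][None, :, :], axis=2)
            ii, jj = np.where(d < contact_cutoff)
            if ii.size == 0:
                continue
            ring_dist = min(kb - ka, n - (kb - ka))
            if ring_dist != 1:
                raise ParameterError(
                    f"non-adjacent subunits {chain_ids[ka]}/{chain_ids[kb]} are in "
                    "contact; increase the radius"
                )
            for i, j in zip(ii, jj):
                interface.append((chain_ids[ka], int(i) + 1, chain_ids[kb], int(j) + 1))
    truth = SyntheticTruth(
        planted_pairs=[],
        coupling_prob=0.0,
        params={
            "n": n,
            "radius": float(radius),
            "subunit_size": subunit_size,
            "seed": seed,
            "contact_cutoff": contact_cutoff,
        },
        interface_pairs=sorted(interface),
    )
    return structure, truth


@dataclass(frozen=True)
class RecoveryReport:
    precision_at_k: float
    recall: float
    k: int
    ranks: dict[tuple[int, int], int | None]


def recovery_report(
    predicted: Sequence[Coupling], truth: SyntheticTruth, k: int
) -> RecoveryReport:
    """Precision@k and recall of the planted pairs in a ranked prediction.

    ``ranks`` gives each planted pair's 1-based position in the prediction
    list (None when absent).  Predictions and truth are compared as
    unordered 1-based column pairs.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if not predicted:
        raise ParameterError("empty prediction list")
    pred_pairs = [tuple(sorted((c.i, c.j))) for c in predicted]
    planted = {tuple(sorted(p)) for p in truth.planted_pairs}
    top = set(pred_pairs[:k])
    hits = len(top & planted)
    ranks = {
        p: (pred_pairs.index(p) + 1 if p in pred_pairs else None) for p in sorted(planted)
    }
    return RecoveryReport(
        precision_at_k=hits / k,
        recall=hits / len(planted) if planted else 0.0,
        k=k,
        ranks=ranks,
    )
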