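"""Shared fixtures: tiny alignments, toy structures, and one medium
planted-pair simulation scored once per session."""

from __future__ import annotations

import numpy as np
import pytest

from coevoring import (
    Msa,
    compute_coevolution,
    simulate_msa,
)
from coevoring.structure import ChainModel, Residue, StructureModel


@pytest.fixture
def tiny_msa() -> Msa:
    rows = [
        "ACDEFGHIKL",
        "ACDEFGHIKL",
        "ACDEWGHIKL",
        "PCDEFGHIKM",
    ]
    ids = [f"s{k}" for k in range(len(rows))]
    return Msa(ids=ids, rows=rows, reference_id="s0")


@pytest.fixture(scope="session")
def planted_small():
    """Medium synthetic alignment with planted pairs, scored once."""
    pairs = [(2, 12), (7, 20), (15, 27)]
    msa, truth = simulate_msa(
        L=30, N=600, planted_pairs=pairs, coupling_prob=0.95, gap_rate=0.05,
        n_founders=40, seed=11,
    )
    result = compute_coevolution(msa, sigma_cut=2.5, seed=11)
    return msa, truth, result


def make_chain(chain_id: str, coords: np.ndarray, start: int = 1, seq: str | None = None) -> ChainModel:
    coords = np.asarray(coords, dtype=float)
    if seq is None:
        seq = "A" * len(coords)
    residues = [
        Residue(number=start + k, icode="", aa=seq[k], coord=coords[k])
        for k in range(len(coords))
    ]
    return ChainModel(id=chain_id, residues=residues)


@pytest.fixture
def two_chain_structure() -> StructureModel:
    """Two short parallel chains 8 A apart; residues 3.8 A apart along x."""
    xs = np.arange(6) * 3.8
    a = np.stack([xs, np.zeros(6), np.zeros(6)], axis=1)
    b = a + np.array([0.0, 8.0, 0.0])
    return StructureModel(chains=[make_chain("A", a, seq="ACDEFG"), make_chain("B", b, seq="ACDEFG")])


ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60  0.00           C
ATOM      3  CA BALA A   1      12.639   7.071  -4.147  0.40  0.00           C
ATOM      4  CA  GLY A   2      14.469   5.937  -5.600  1.00  0.00           C
ATOM      5  CA  VAL B   1       1.000   2.000   3.000  1.00  0.00           C
HETATM    6  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
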