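"""Atomic structures, contact maps, and projection of couplings onto them.

Structures are reduced to one C-alpha per residue (HETATM records, waters
and residues without a C-alpha are dropped).  Contacts are defined on
C-alpha/C-alpha distances with a strict ``< cutoff`` test (10 A by
default); intra-chain pairs closer than ``min_separation`` in residue
numbering are excluded, inter-chain pairs never are.

A coupling validated against a structure is classified as

* ``fold``      — explained by an intra-chain contact,
* ``interface`` — not a fold contact but in contact across chains,
* ``none``      — neither.

Surface exposure uses the C-alpha coordination number (neighbours within
10 A) as a dependency-free monotone proxy for solvent accessibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from coevoring.coevolution import Coupling
from coevoring.errors import MappingError, ParameterError, StructureError
from coevoring.msa import GAP, Msa

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Residue:
    """One residue reduced to its C-alpha."""

    number: int
    icode: str
    aa: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))


@dataclass(frozen=True)
class ChainModel:
    id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues])

    def by_number(self) -> dict[int, Residue]:
        return {r.number: r for r in self.residues}


@dataclass(frozen=True)
class StructureModel:
    """A C-alpha-only multi-chain model."""

    chains: list[ChainModel]

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in model (have {self.chain_ids})")

    def all_coords(self) -> np.ndarray:
        return np.vstack([c.coords() for c in self.chains])


@dataclass(frozen=True)
class ContactEntry:
    chain_i: str
    res_i: int
    chain_j: str
    res_j: int
    distance: float
    contact_class: Literal["intra", "inter"]


@dataclass(frozen=True)
class ContactMap:
    entries: list[ContactEntry]
    cutoff: float
    min_separation: int

    def pairs(self, contact_class: str | None = None) -> set[tuple[str, int, str, int]]:
        return {
            (e.chain_i, e.res_i, e.chain_j, e.res_j)
            for e in self.entries
            if contact_class is None or e.contact_class == contact_class
        }


@dataclass(frozen=True)
class ColumnResidueMap:
    """MSA column <-> structure residue correspondence for one chain.

    ``cols``/``refnums``/``resnums`` are parallel arrays: the MSA column,
    its 1-based reference residue number, and the matched author residue
    number in the chain.
    """

    chain_id: str
    cols: np.ndarray
    refnums: np.ndarray
    resnums: np.ndarray
    coverage: float

    def ref_to_resnum(self) -> dict[int, int]:
        return {int(r): int(s) for r, s in zip(self.refnums, self.resnums)}


@dataclass(frozen=True)
class MappedCoupling:
    """A coupling projected onto structure residues."""

    coupling: Coupling
    res_i: int | None
    res_j: int | None
    d_intra: float | None
    d_inter_min: float | None
    contact_class: Literal["fold", "interface", "none", "unmapped"]

    @property
    def mapped(self) -> bool:
        return self.contact_class != "unmapped"


@dataclass(frozen=True)
class ValidationReport:
    n_couplings: int
    n_fold: int
    n_interface: int
    n_none: int
    n_unmapped: int
    precision: float
    mean_d: float
    sem_d: float
    n_distances: int
    distance_choice: str
    table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_couplings": self.n_couplings,
            "n_fold": self.n_fold,
            "n_interface": self.n_interface,
            "n_none": self.n_none,
            "n_unmapped": self.n_unmapped,
            "precision": self.precision,
            "mean_d": self.mean_d,
            "sem_d": self.sem_d,
            "n_distances": self.n_distances,
            "distance_choice": self.distance_choice,
        }


# ---------------------------------------------------------------------------
# Reading / writing


def read_structure(
    path: str | Path,
    altloc_policy: Literal["highest_occupancy", "first"] = "highest_occupancy",
    chain_filter: Sequence[str] | None = None,
) -> StructureModel:
    """Parse a PDB file into a C-alpha-only model.

    HETATM records and waters are dropped; alternate locations are resolved
    per policy; residues without a C-alpha are skipped.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains: list[ChainModel] = []
    for chain in model:
        if chain_filter is not None and chain.id not in chain_filter:
            continue
        residues: list[Residue] = []
        seen: set[tuple[int, str]] = set()
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue  # HETATM / water
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                alts = atom.disordered_get_list()
                if altloc_policy == "highest_occupancy":
                    atom = max(alts, key=lambda a: (a.get_occupancy() or 0.0))
                else:
                    atom = sorted(alts, key=lambda a: a.get_altloc())[0]
            key = (resseq, icode.strip())
            if key in seen:
                raise StructureError(
                    f"duplicate residue {chain.id}:{resseq}{icode.strip()} after altloc resolution"
                )
            seen.add(key)
            residues.append(
                Residue(
                    number=resseq,
                    icode=icode.strip(),
                    aa=seq1(res.get_resname(), custom_map={}),
                    coord=atom.get_coord(),
                )
            )
        if residues:
            chains.append(ChainModel(id=chain.id, residues=residues))
    if not chains:
        raise StructureError(f"no C-alpha atoms in {path}")
    return StructureModel(chains=chains)


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_structure_pdb(s: StructureModel, path: str | Path) -> None:
    """Write the C-alpha trace as standard fixed-width PDB ATOM records."""
    serial = 0
    with open(path, "w") as fh:
        for chain in s.chains:
            for r in chain.residues:
                serial += 1
                name3 = _AA3.get(r.aa, "UNK")
                x, y, z = r.coord
                fh.write(
                    f"ATOM  {serial:5d}  CA  {name3:>3s} {chain.id:1s}"
                    f"{r.number:4d}{(r.icode or ' '):1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {' C':>2s}\n"
                )
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Contact maps


def contact_map(s: StructureModel, cutoff: float = 10.0, min_separation: int = 5) -> ContactMap:
    """All C-alpha pairs with distance strictly below ``cutoff``.

    Intra-chain pairs with residue-number separation below
    ``min_separation`` are excluded; inter-chain pairs are never
    separation-filtered.  Entries are canonicalised (chain order, then
    residue order).
    """
    entries: list[ContactEntry] = []
    n_chains = len(s.chains)
    for a in range(n_chains):
        ca = s.chains[a]
        coords_a = ca.coords()
        nums_a = np.array([r.number for r in ca.residues])
        # intra
        d = cdist(coords_a, coords_a)
        ii, jj = np.where(np.triu(np.ones_like(d, dtype=bool), 1))
        for i, j in zip(ii, jj):
            if abs(int(nums_a[j]) - int(nums_a[i])) < min_separation:
                continue
            if d[i, j] < cutoff:
                entries.append(
                    ContactEntry(ca.id, int(nums_a[i]), ca.id, int(nums_a[j]), float(d[i, j]), "intra")
                )
        for b in range(a + 1, n_chains):
            cb = s.chains[b]
            coords_b = cb.coords()
            nums_b = np.array([r.number for r in cb.residues])
            d = cdist(coords_a, coords_b)
            ii, jj = np.where(d < cutoff)
            for i, j in zip(ii, jj):
                entries.append(
                    ContactEntry(ca.id, int(nums_a[i]), cb.id, int(nums_b[j]), float(d[i, j]), "inter")
                )
    return ContactMap(entries=entries, cutoff=cutoff, min_separation=min_separation)


# ---------------------------------------------------------------------------
# Mapping MSA columns onto structures


def map_columns_to_residues(msa: Msa, s: StructureModel, chain: str) -> ColumnResidueMap:
    """Globally align the ungapped reference row to a chain sequence and
    pair aligned, matching positions (match +1, mismatch 0, gap -1).

    Raises :class:`MappingError` when fewer than 30% of columns map, or
    when fewer than 30% of the aligned positions are identical (an
    unrelated structure sequence).
    """
    from Bio.Align import PairwiseAligner

    ref_row = msa.reference_row
    ref_ungapped = ref_row.replace(GAP, "")
    ch = s.chain(chain)
    chain_seq = ch.sequence
    if not ref_ungapped or not chain_seq:
        raise MappingError("empty reference or chain sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(ref_ungapped, chain_seq)[0]
    # refpos (1-based position in ungapped reference) -> chain residue index
    ref_to_chain: dict[int, int] = {}
    blocks_ref, blocks_chain = aln.aligned
    n_identical = 0
    for (rs, re), (cs, _ce) in zip(blocks_ref, blocks_chain):
        for k in range(re - rs):
            ref_to_chain[rs + k + 1] = cs + k
            if ref_ungapped[rs + k] == chain_seq[cs + k]:
                n_identical += 1
    if ref_to_chain and n_identical / len(ref_to_chain) < 0.3:
        raise MappingError(
            f"only {n_identical}/{len(ref_to_chain)} aligned positions identical "
            "(reference/structure mismatch)"
        )
    cols, refnums, resnums = [], [], []
    for c in range(msa.L):
        refpos = int(msa.colmap[c])
        if refpos < 0:
            continue
        idx = ref_to_chain.get(refpos)
        if idx is None:
            continue
        cols.append(c)
        refnums.append(refpos)
        resnums.append(ch.residues[idx].number)
    coverage = len(cols) / msa.L
    if coverage < 0.3:
        raise MappingError(
            f"only {coverage:.0%} of columns map onto chain {chain} "
            "(reference/structure mismatch)"
        )
    return ColumnResidueMap(
        chain_id=chain,
        cols=np.asarray(cols, dtype=np.int64),
        refnums=np.asarray(refnums, dtype=np.int64),
        resnums=np.asarray(resnums, dtype=np.int64),
        coverage=coverage,
    )


def project_couplings(
    couplings: Iterable[Coupling],
    map_a: ColumnResidueMap,
    s: StructureModel,
    partner_chains: Sequence[str] | None,
    cutoff: float = 10.0,
) -> list[MappedCoupling]:
    """Project couplings onto the structure and classify them.

    ``d_intra`` is the within-chain distance, minimised over the mapped
    chain and any partner chain carrying the same author numbering (the
    homo-oligomer convention).  ``d_inter_min`` is the minimum over the
    ordered cross-chain pairings (A_i, B_j) and (B_i, A_j) for every
    partner chain B.  Couplings whose residues are absent from the map are
    flagged ``unmapped``.
    """
    if partner_chains is not None and len(partner_chains) == 0:
        raise ParameterError("partner_chains is empty; pass None to skip inter distances")
    ref_map = map_a.ref_to_resnum()
    primary = s.chain(map_a.chain_id)
    chain_lookup = {map_a.chain_id: primary.by_number()}
    for pc in partner_chains or []:
        chain_lookup[pc] = s.chain(pc).by_number()

    out: list[MappedCoupling] = []
    for cp in couplings:
        rn_i, rn_j = ref_map.get(cp.i), ref_map.get(cp.j)
        if rn_i is None or rn_j is None:
            out.append(MappedCoupling(cp, rn_i, rn_j, None, None, "unmapped"))
            continue
        d_intra = None
        for lookup in chain_lookup.values():
            ri, rj = lookup.get(rn_i), lookup.get(rn_j)
            if ri is not None and rj is not None:
                d = float(np.linalg.norm(ri.coord - rj.coord))
                d_intra = d if d_intra is None else min(d_intra, d)
        d_inter = None
        if partner_chains:
            prim = chain_lookup[map_a.chain_id]
            for pc in partner_chains:
                part = chain_lookup[pc]
                for ra, rb in ((prim.get(rn_i), part.get(rn_j)), (part.get(rn_i), prim.get(rn_j))):
                    if ra is not None and rb is not None:
                        d = float(np.linalg.norm(ra.coord - rb.coord))
                        d_inter = d if d_inter is None else min(d_inter, d)
        if d_intra is not None and d_intra < cutoff:
            klass = "fold"
        elif d_inter is not None and d_inter < cutoff:
            klass = "interface"
        else:
            klass = "none"
        out.append(MappedCoupling(cp, rn_i, rn_j, d_intra, d_inter, klass))
    return out


def validation_stats(
    mapped: Iterable[MappedCoupling],
    distance_choice: Literal["intra", "inter", "min"] = "min",
) -> ValidationReport:
    """Class counts, precision and the mean +/- sem of the chosen distance.

    ``precision`` is the fraction of mapped couplings explained by any
    contact (fold or interface).  The sem is sd/sqrt(n) with sample sd; a
    single distance reports sem 0.
    """
    mapped = list(mapped)
    usable = [m for m in mapped if m.mapped]
    if not usable:
        raise ParameterError("no mapped couplings to validate")
    n_fold = sum(1 for m in usable if m.contact_class == "fold")
    n_interface = sum(1 for m in usable if m.contact_class == "interface")
    n_none = sum(1 for m in usable if m.contact_class == "none")
    n_unmapped = len(mapped) - len(usable)

    def chosen(m: MappedCoupling) -> float | None:
        if distance_choice == "intra":
            return m.d_intra
        if distance_choice == "inter":
            return m.d_inter_min
        ds = [d for d in (m.d_intra, m.d_inter_min) if d is not None]
        return min(ds) if ds else None

    dists = np.array([d for m in usable if (d := chosen(m)) is not None])
    if dists.size == 0:
        raise ParameterError(f"no coupling has a defined {distance_choice!r} distance")
    mean_d = float(dists.mean())
    sem_d = float(dists.std(ddof=1) / np.sqrt(dists.size)) if dists.size > 1 else 0.0
    table = [
        {
            "i": m.coupling.i,
            "j": m.coupling.j,
            "res_i": m.res_i,
            "res_j": m.res_j,
            "z": m.coupling.z,
            "score_norm": m.coupling.score_norm,
            "d_intra": m.d_intra,
            "d_inter_min": m.d_inter_min,
            "class": m.contact_class,
        }
        for m in mapped
    ]
    return ValidationReport(
        n_couplings=len(usable),
        n_fold=n_fold,
        n_interface=n_interface,
        n_none=n_none,
        n_unmapped=n_unmapped,
        precision=(n_fold + n_interface) / len(usable),
        mean_d=mean_d,
        sem_d=sem_d,
        n_distances=int(dists.size),
        distance_choice=distance_choice,
        table=table,
    )


def interface_candidates(
    mapped: Iterable[MappedCoupling],
    s: StructureModel,
    monomer_chain: str,
    score_min: float = 0.2,
    exposure_max_neighbors: int = 14,
    cutoff: float = 10.0,
    neighbor_radius: float = 10.0,
) -> list[MappedCoupling]:
    """Couplings suitable as inter-subunit docking restraints.

    Keeps couplings with normalised score strictly above ``score_min`` that
    the monomer fold does not explain (``d_intra >= cutoff`` or undefined)
    and whose residues are both surface-exposed (C-alpha coordination
    number within ``neighbor_radius`` at most ``exposure_max_neighbors``).
    """
    chain = s.chain(monomer_chain)
    coords = chain.coords()
    tree = cKDTree(coords)
    neighbor_counts = {
        r.number: len(tree.query_ball_point(r.coord, neighbor_radius)) - 1
        for r in chain.residues
    }
    out = []
    for m in mapped:
        if not m.mapped:
            continue
        if not (m.coupling.score_norm > score_min):
            continue
        if m.d_intra is not None and m.d_intra < cutoff:
            continue  # explained by the fold
        ni = neighbor_counts.get(m.res_i)
        nj = neighbor_counts.get(m.res_j)
        if ni is None or nj is None:
            continue
        if ni > exposure_max_neighbors or nj > exposure_max_neighbors:
            continue  # buried
        out.append(m)
    out.sort(key=lambda m: (-m.coupling.z, m.coupling.i, m.coupling.j))
    return out
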