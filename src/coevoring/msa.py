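"""Reading, normalising, clustering, filtering, trimming, weighting and
concatenating multiple sequence alignments.

An :class:`Msa` stores aligned rows over the 20 standard amino acids plus
the gap character ``-``.  Internally everything is 0-based; the column map
(``colmap``) translates column indices to 1-based reference residue
numbers, which is the numbering used in all reports and restraint files.

Sequence identity between two aligned rows is defined as the number of
matching residues divided by the number of columns where *both* rows are
non-gap; columns with a gap in either row are excluded.  This definition is
robust to gappy family alignments and is used consistently by clustering,
family filtering and redundancy weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

from coevoring.errors import AlignmentFormatError, ParameterError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
N_STATES = 20
GAP_STATE = 20

_ENCODE = np.full(256, GAP_STATE, dtype=np.uint8)
for _k, _aa in enumerate(AMINO_ACIDS):
    _ENCODE[ord(_aa)] = _k


def encode_rows(rows: Sequence[str]) -> np.ndarray:
    """Encode aligned rows as a (N, L) uint8 matrix (0-19 = amino acid, 20 = gap)."""
    buf = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _ENCODE[buf].reshape(len(rows), -1)


@dataclass(frozen=True)
class Msa:
    """An aligned protein family.

    Parameters
    ----------
    ids : list of str
        Sequence identifiers, unique per row.
    rows : list of str
        Aligned sequences over ``ACDEFGHIKLMNPQRSTVWY-``; identical lengths.
    reference_id : str
        Identifier of the reference/seed row; defaults to the first row.
    colmap : ndarray of int
        1-based reference residue number per column; ``-1`` where the
        reference row is gapped.
    domain_boundary : int or None
        For concatenated two-protein alignments, the number of columns
        contributed by the first protein; ``None`` otherwise.
    """

    ids: list[str]
    rows: list[str]
    reference_id: str
    colmap: np.ndarray = field(default=None)  # type: ignore[assignment]
    domain_boundary: int | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in length")
        if self.reference_id not in self.ids:
            raise AlignmentFormatError(f"reference id {self.reference_id!r} not in alignment")
        if self.colmap is None:
            object.__setattr__(self, "colmap", default_colmap(self.reference_row))
        cm = np.asarray(self.colmap, dtype=np.int64)
        if cm.shape != (self.L,):
            raise AlignmentFormatError("colmap length does not match column count")
        object.__setattr__(self, "colmap", cm)

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def encoded(self) -> np.ndarray:
        return encode_rows(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def default_colmap(reference_row: str) -> np.ndarray:
    """1-based residue numbering of the reference row; -1 at gap columns."""
    out = np.full(len(reference_row), -1, dtype=np.int64)
    pos = 0
    for c, ch in enumerate(reference_row):
        if ch != GAP:
            pos += 1
            out[c] = pos
    return out


@dataclass(frozen=True)
class SequenceWeights:
    """Redundancy weights: weight of a row is 1 / (number of rows, itself
    included, within ``theta`` identity of it)."""

    weights: np.ndarray
    theta: float
    n_eff: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w <= 0) or np.any(w > 1):
            raise ParameterError("weights must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Reading / writing


def _normalize_row(raw: str, a2m_lower_is_insert: bool) -> str:
    """Normalise one aligned row to uppercase residues and '-' gaps.

    With ``a2m_lower_is_insert=True`` lowercase letters and '.' denote
    unaligned insert states and are removed; otherwise lowercase letters are
    uppercased and '.' becomes a gap.
    """
    if a2m_lower_is_insert:
        raw = "".join(ch for ch in raw if not (ch.islower() or ch == "."))
    else:
        raw = raw.upper().replace(".", GAP)
    out = []
    unknown: set[str] = set()
    for ch in raw:
        if ch == GAP or ch in AMINO_ACIDS:
            out.append(ch)
        else:
            unknown.add(ch)
            out.append(GAP)
    if unknown:
        logger.warning("unknown residue characters %s mapped to gap", sorted(unknown))
    return "".join(out)


def read_msa(
    path: str | Path,
    format: Literal["fasta", "stockholm", "auto"] = "auto",
    reference_id: str | None = None,
    a2m_lower_is_insert: bool = False,
) -> Msa:
    """Read an aligned FASTA/A2M or Stockholm file.

    The reference row defaults to the first sequence.  Residues are
    uppercased, ``.`` and unknown characters become gaps (with a logged
    warning for the latter), and ragged alignments raise
    :class:`AlignmentFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        with open(path) as fh:
            first = fh.readline()
        format = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise AlignmentFormatError(f"no sequences in {path}")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq), a2m_lower_is_insert) for r in records]
    ref = reference_id if reference_id is not None else ids[0]
    return Msa(ids=ids, rows=rows, reference_id=ref)


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write the alignment as aligned FASTA, preserving row order."""
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# Identity and clustering


def pairwise_identity(enc_a: np.ndarray, enc_b: np.ndarray) -> float:
    """Identity over mutually non-gap columns; 0.0 when no such column."""
    both = (enc_a != GAP_STATE) & (enc_b != GAP_STATE)
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((enc_a[both] == enc_b[both]).sum()) / n


def identity_matrix(enc: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Dense N x N identity matrix (mutually non-gap definition)."""
    n = enc.shape[0]
    nongap = enc != GAP_STATE
    out = np.empty((n, n), dtype=np.float64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        eq = enc[start:stop, None, :] == enc[None, :, :]
        both = nongap[start:stop, None, :] & nongap[None, :, :]
        matches = (eq & both).sum(axis=2)
        denom = both.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
        out[start:stop] = block
    return out


@dataclass(frozen=True)
class Cluster:
    """A cluster of row indices with a representative member."""

    members: list[int]
    representative: int


def cluster_sequences(msa: Msa, identity: float) -> list[Cluster]:
    """Greedy incremental clustering at the given identity threshold.

    Rows are processed in input order (CD-HIT-like): a row joins the first
    cluster whose founder it matches at >= ``identity``, otherwise it founds
    a new cluster.  The reported representative is the member with the most
    non-gap residues (ties broken by input order).
    """
    if not 0.0 <= identity <= 1.0:
        raise ParameterError(f"identity threshold {identity} outside [0, 1]")
    enc = msa.encoded()
    founders: list[int] = []
    members: list[list[int]] = []
    for r in range(msa.N):
        placed = False
        for ci, f in enumerate(founders):
            if pairwise_identity(enc[r], enc[f]) >= identity:
                members[ci].append(r)
                placed = True
                break
        if not placed:
            founders.append(r)
            members.append([r])
    ungapped = (enc != GAP_STATE).sum(axis=1)
    clusters = []
    for mem in members:
        rep = max(mem, key=lambda r: (ungapped[r], -r))
        clusters.append(Cluster(members=mem, representative=rep))
    return clusters


def filter_to_reference_family(
    msa: Msa, clusters: Iterable[Cluster], min_ref_identity: float
) -> Msa:
    """Drop clusters whose representative is < ``min_ref_identity`` identical
    to the reference row.  The reference row itself is always retained."""
    if not 0.0 <= min_ref_identity <= 1.0:
        raise ParameterError(f"min_ref_identity {min_ref_identity} outside [0, 1]")
    enc = msa.encoded()
    ref_idx = msa.ids.index(msa.reference_id)
    keep: set[int] = {ref_idx}
    for cl in clusters:
        if pairwise_identity(enc[cl.representative], enc[ref_idx]) >= min_ref_identity:
            keep.update(cl.members)
    order = sorted(keep)
    if order == [ref_idx] and msa.N > 1:
        logger.warning("family filter removed every non-reference sequence")
    return replace(
        msa,
        ids=[msa.ids[i] for i in order],
        rows=[msa.rows[i] for i in order],
    )


def trim_to_reference_columns(msa: Msa, structure_row_id: str) -> Msa:
    """Remove every column where the named row has a gap.

    The column map of the result numbers columns by the named row's residue
    numbering (1-based over its non-gap positions), so downstream couplings
    are reported in the structure sequence's coordinates.
    """
    if structure_row_id not in msa.ids:
        raise KeyError(f"row {structure_row_id!r} not in alignment")
    anchor = msa.row(structure_row_id)
    keep = [c for c, ch in enumerate(anchor) if ch != GAP]
    if not keep:
        raise AlignmentFormatError(f"row {structure_row_id!r} is entirely gaps")
    rows = ["".join(r[c] for c in keep) for r in msa.rows]
    colmap = np.arange(1, len(keep) + 1, dtype=np.int64)
    return replace(msa, rows=rows, colmap=colmap)


def sequence_weights(msa: Msa, theta: float = 0.62) -> SequenceWeights:
    """PSICOV-style redundancy weights at identity threshold ``theta``.

    The weight of row *s* is ``1 / |{t : identity(s, t) >= theta}|`` (self
    included); ``n_eff`` is the sum of weights.
    """
    if not 0.0 <= theta <= 1.0:
        raise ParameterError(f"theta {theta} outside [0, 1]")
    ident = identity_matrix(msa.encoded())
    counts = (ident >= theta).sum(axis=1)
    weights = 1.0 / counts
    return SequenceWeights(weights=weights, theta=theta, n_eff=float(weights.sum()))


def depth_ratio(msa: Msa, minimum: float = 0.3) -> tuple[float, bool]:
    """N/L depth ratio and whether it strictly exceeds ``minimum`` (0.3 by
    default, the accepted floor for a statistically meaningful coevolution
    signal)."""
    if msa.L == 0:
        raise ParameterError("alignment has zero columns")
    ratio = msa.N / msa.L
    return ratio, ratio > minimum


# ---------------------------------------------------------------------------
# Concatenation


def _pair_key(seq_id: str, pairing_key: str) -> str:
    if pairing_key == "exact_id":
        return seq_id
    if pairing_key == "organism_field":
        # Uniprot-style NAME_ORGANISM, optionally with a /start-end suffix
        stem = seq_id.split("/")[0]
        return stem.rsplit("_", 1)[-1]
    raise ParameterError(f"unknown pairing key {pairing_key!r}")


def concatenate_paired(
    msa_a: Msa, msa_b: Msa, pairing_key: Literal["exact_id", "organism_field"] = "exact_id"
) -> Msa:
    """Join rows of two alignments end-to-end by a shared pairing key.

    Unpaired rows are dropped (with a logged count); the result records the
    domain boundary (number of columns from ``msa_a``) so inter-protein
    couplings can be reported separately.  Column numbering restarts for the
    second protein, mirroring per-protein residue numbering of a fusion's
    parts.
    """
    keys_a = [_pair_key(i, pairing_key) for i in msa_a.ids]
    keys_b = [_pair_key(i, pairing_key) for i in msa_b.ids]
    for name, keys in (("first", keys_a), ("second", keys_b)):
        if len(set(keys)) != len(keys):
            raise ParameterError(f"duplicate pairing key in {name} alignment")
    index_b = {k: i for i, k in enumerate(keys_b)}
    shared = [(ia, index_b[k]) for ia, k in enumerate(keys_a) if k in index_b]
    if not shared:
        raise ParameterError("no shared pairing keys between alignments")
    dropped = (msa_a.N - len(shared)) + (msa_b.N - len(shared))
    if dropped:
        logger.info("concatenate_paired dropped %d unpaired rows", dropped)
    ids = [msa_a.ids[ia] for ia, _ in shared]
    rows = [msa_a.rows[ia] + msa_b.rows[ib] for ia, ib in shared]
    ref = msa_a.reference_id if msa_a.reference_id in ids else ids[0]
    colmap = np.concatenate([msa_a.colmap, msa_b.colmap])
    return Msa(
        ids=ids,
        rows=rows,
        reference_id=ref,
        colmap=colmap,
        domain_boundary=msa_a.L,
    )
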