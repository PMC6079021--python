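"""Export of interface couplings as docking distance restraints.

Two plain-text dialects are written:

* ``tsv`` — one line per pair with scores, round-trippable;
* ``air_text`` (dialect ``coevoring-air/1``) — one ambiguous-interaction
  restraint block per pair, restraining the C-alpha/C-alpha distance
  between two chain copies to at most the upper bound.  The assign
  statement follows the CNS convention ``d dminus dplus`` (allowed range
  ``[d - dminus, d + dplus]``); with ``d = dminus = upper_bound`` and
  ``dplus = 0`` the pair may approach freely but not exceed the bound.

Export order is deterministic: descending z, then residue numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from coevoring.coevolution import Coupling
from coevoring.errors import ParameterError
from coevoring.structure import MappedCoupling

AIR_DIALECT = "coevoring-air/1"


@dataclass(frozen=True)
class Restraint:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    upper_bound: float
    atom: str
    z: float
    score_norm: float


@dataclass(frozen=True)
class RestraintSet:
    restraints: list[Restraint]
    upper_bound: float
    atom: str = "CA"

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ParameterError("upper bound must be positive")
        keys = [(r.chain_a, r.res_a, r.chain_b, r.res_b) for r in self.restraints]
        if len(set(keys)) != len(keys):
            raise ParameterError("duplicate restraint pairs")


def build_restraint_set(
    candidates: Sequence[MappedCoupling],
    chain_a: str = "A",
    chain_b: str = "B",
    upper_bound: float = 10.0,
    top_k: int | None = None,
    atom: str = "CA",
) -> RestraintSet:
    """Turn interface candidate couplings into a restraint set.

    Candidates are ordered by descending z (ties by residue numbers); an
    optional ``top_k`` keeps only the strongest pairs.
    """
    ordered = sorted(candidates, key=lambda m: (-m.coupling.z, m.res_i, m.res_j))
    if top_k is not None:
        ordered = ordered[:top_k]
    restraints = [
        Restraint(
            chain_a=chain_a,
            res_a=m.res_i,
            chain_b=chain_b,
            res_b=m.res_j,
            upper_bound=upper_bound,
            atom=atom,
            z=m.coupling.z,
            score_norm=m.coupling.score_norm,
        )
        for m in ordered
    ]
    return RestraintSet(restraints=restraints, upper_bound=upper_bound, atom=atom)


def export_restraints(
    rs: RestraintSet, format: Literal["tsv", "air_text"] = "tsv"
) -> str:
    """Render a restraint set as text; deterministic and re-export-stable."""
    if format == "tsv":
        lines = ["chain_a\tres_a\tchain_b\tres_b\tatom\tupper_bound\tz\tscore_norm"]
        for r in rs.restraints:
            lines.append(
                f"{r.chain_a}\t{r.res_a}\t{r.chain_b}\t{r.res_b}\t{r.atom}\t"
                f"{r.upper_bound:.1f}\t{r.z:.4f}\t{r.score_norm:.4f}"
            )
        return "\n".join(lines) + "\n"
    if format == "air_text":
        if not rs.restraints:
            raise ParameterError("no candidate pairs; use format 'tsv' for an empty table")
        lines = [f"! {AIR_DIALECT} upper_bound={rs.upper_bound:.1f} atom={rs.atom}"]
        for k, r in enumerate(rs.restraints, start=1):
            lines.append(f"! restraint {k} z={r.z:.4f} score_norm={r.score_norm:.4f}")
            lines.append(
                f"assign (segid {r.chain_a} and resid {r.res_a} and name {r.atom}) "
                f"(segid {r.chain_b} and resid {r.res_b} and name {r.atom}) "
                f"{r.upper_bound:.1f} {r.upper_bound:.1f} 0.0"
            )
        return "\n".join(lines) + "\n"
    raise ParameterError(f"unknown restraint format {format!r}")


def parse_restraints_tsv(text: str) -> RestraintSet:
    """Parse the TSV dialect back into a :class:`RestraintSet`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParameterError("empty restraint table")
    header = lines[0].split("\t")
    expected = ["chain_a", "res_a", "chain_b", "res_b", "atom", "upper_bound", "z", "score_norm"]
    if header != expected:
        raise ParameterError(f"unexpected restraint TSV header: {header}")
    restraints = []
    for ln in lines[1:]:
        ca, ra, cb, rb, atom, ub, z, sn = ln.split("\t")
        restraints.append(
            Restraint(
                chain_a=ca,
                res_a=int(ra),
                chain_b=cb,
                res_b=int(rb),
                upper_bound=float(ub),
                atom=atom,
                z=float(z),
                score_norm=float(sn),
            )
        )
    ub = restraints[0].upper_bound if restraints else 10.0
    atom = restraints[0].atom if restraints else "CA"
    return RestraintSet(restraints=restraints, upper_bound=ub, atom=atom)


def write_restraints(
    rs: RestraintSet, path: str | Path, format: Literal["tsv", "air_text"] = "tsv"
) -> None:
    Path(path).write_text(export_restraints(rs, format=format))
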