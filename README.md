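# coevoring

Coevolution-guided contact prediction and cyclic-ring modelling for
oligomeric protein assemblies.

Ring-forming proteins — the FliF MS ring and FliG rotor of the bacterial
flagellar motor, injectisome SctJ-family scaffolds, and their relatives —
assemble from subunits whose interfaces are hard to observe directly:
crystal structures usually capture a monomer or an incidental dimer, and
electron-microscopy maps of the rings resolve envelopes, not residues.
Residue coevolution bridges the gap: column pairs of a deep multiple
sequence alignment (MSA) that substitute in a correlated way across
homologs tend to be in spatial contact, either within the fold or across a
conserved subunit interface.  `coevoring` scores that signal, validates it
against known structures, exports the inter-subunit couplings as docking
restraints, and analyses the Cn-symmetric rings the resulting dimers
imply.

## The method

**Coupling score.** For MSA columns *i, j* the coupling strength is the
PSICOV score

&nbsp;&nbsp;&nbsp;&nbsp;PS<sub>ij</sub> = Σ<sub>ab</sub> |Θ<sub>ij</sub><sup>ab</sup>|,

the sum of absolute values of the 20 × 20 block linking the two columns in
the sparse inverse covariance (precision) matrix Θ of amino-acid indicator
variables, estimated by graphical lasso with an L1 penalty ρ.  Frequencies
are computed over the 20 amino-acid states only (gap rows excluded),
redundancy-weighted at 62% identity and regularised with a uniform
pseudocount.  Raw scores receive the average product correction (APC),

&nbsp;&nbsp;&nbsp;&nbsp;APC<sub>ij</sub> = PS<sub>ij</sub> −
PS<sub>i·</sub> PS<sub>·j</sub> / PS<sub>··</sub>,

which removes entropic and phylogenetic background, and are standardised
to z-scores over all pairs separated by at least 5 positions.  Couplings
above a σ cut-off (default 3σ; 2.5σ for permissive runs) are reported.  A
within-column shuffle of the alignment provides the randomisation null:
it preserves every column's composition while destroying covariance, and
planted or real signal drops below the detection threshold.

**Validation and restraints.** Couplings are projected onto structures
through a reference-to-chain alignment; a pair is a *fold* contact if its
Cα–Cα distance within a chain is < 10 Å, an *interface* contact if only a
cross-chain distance is, and *none* otherwise.  High-scoring,
surface-exposed couplings not explained by the monomer fold are exported
as Cα–Cα upper-bound (10 Å) distance restraints in TSV or an
ambiguous-interaction-restraint text dialect for docking programs.

**Rings.** A homodimer whose chains are related by a rotation of 360/n°
is the asymmetric unit of a Cn ring; the rotation is recovered by Kabsch
superposition and the ring built by replication about the axis.  Helper
arithmetic covers the chord–tangent angle 180/n (subunit curvature),
protein volume from mass (V = m·copies·γ, γ = 1.28 Å³/Da), stoichiometry
from a fitted map volume, and sequence coverage of fitted models.

A synthetic-data module generates MSAs with planted coevolving column
pairs and toy Cn rings with known interface contacts, providing ground
truth for every stage.

## Worked example

Simulate an alignment with four planted coevolving pairs, score it, and
read off the top couplings:

```sh
$ coevoring simulate msa --l 40 --n 1500 --pairs 4 --pc 0.9 --seed 7 \
      --out synth.fasta --truth truth.json
wrote synth.fasta: N=1500 L=40 planted=[(10, 33), (12, 40), (24, 35), (26, 37)]

$ coevoring score --msa synth.fasta --sigma 3.0 --seed 7 --out scores.tsv
11 couplings > 3.0 sigma (1.75% of eligible pairs)

$ sort -t$'\t' -k5 -gr scores.tsv | head -4
12	40	27.8148	27.6777	7.64927
26	37	27.5494	27.4026	7.5732
10	33	23.7673	23.6509	6.53577
24	35	22.8923	22.7847	6.29626
```

The four planted pairs are exactly the four strongest z-scores (columns:
i, j, raw, APC, z), and the >3σ tail is ~2% of eligible pairs — the same
order as the ~1–0.2% seen for real protein families.  The ring
arithmetic answers the assembly bookkeeping questions directly:

```pycon
>>> from coevoring import tangent_angle_delta, volume_from_mass, estimate_stoichiometry
>>> tangent_angle_delta(26, 37)
(6.923076923076923, 4.864864864864865, 2.0582120582120584)
>>> volume_from_mass(100_000, 26)       # 100 kDa monomer, 26 copies
3328000.0
>>> estimate_stoichiometry(3.81e6, 1e5, coverage=0.78)
(38.16105769230769, 38)
```

A 26-mer and a 37-mer differ in subunit tangent angle by only 2.06°, so
ring curvature barely constrains the copy number; a 100 kDa × 26 ring
occupies 3.33 × 10⁶ Å³; a fitted volume of 3.81 × 10⁶ Å³ at 78% sequence
coverage implies ~38 copies.

The full pipeline (prep → score → validate → restraints → ring) runs from
one YAML file: `coevoring run --config run.yaml`.

## Documentation

`docs/methods.md` describes the statistical model, parameter defaults,
what the synthetic generator does and does not emulate, and the numerical
choices made.
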