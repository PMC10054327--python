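"""Synthetic fixtures: toy structures, profiles, reports, planted datasets.

Everything the pipeline consumes can be fabricated here deterministically:
ideal alpha-helical peptides (so burial, shells and SASA have realistic
gradients), integer PSSMs with a boosted self-column, pocket and pKa
reports in the formats the parsers accept, and fully synthetic labeled
feature tables with a controllable planted class signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tables import INTRINSIC_PKA, ONE_TO_THREE, PSSM_ALPHABET
from .dataset import FEATURE_COLUMNS, LABEL_COLUMN
from .sequence import PSSMProfile, write_ascii_pssm
from .structure import Atom, ProteinStructure, write_pdb

# Ideal alpha-helix parameters: 1.5 A rise and 100 degrees of twist per
# residue on a 2.3 A helical radius gives consecutive CA-CA ~ 3.8 A.
_HELIX_RISE = 1.5
_HELIX_TWIST = math.radians(100.0)
_HELIX_RADIUS = 2.3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-signal synthetic feature table."""

    n_pos: int = 200
    n_neg: int = 200
    effect_size: float = 1.0
    informative_columns: tuple[str, ...] = (
        "SASA", "pKa", "4Å.SASA.ave", "4Å.pka.ave",
        "Drug Score", "PSSM.C", "MG", "PSEE",
    )
    seed: int = 0
    peptide_length: int = 25

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")


def _cylindrical(angle: float, radius: float, z: float) -> np.ndarray:
    return np.array([radius * math.cos(angle), radius * math.sin(angle), z])


def make_helix_peptide(
    sequence: str, seed: int = 0, structure_id: str = "SYNTH"
) -> tuple[ProteinStructure, str]:
    """Build an ideal alpha-helical peptide with backbone, CB and CYS SG.

    Atom placement is deterministic (the seed is accepted for interface
    symmetry but geometry is ideal).  Returns the structure and its PDB
    text.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    unknown = [aa for aa in sequence if aa not in ONE_TO_THREE]
    if unknown:
        raise ValueError(f"non-standard residues: {unknown}")

    atoms: list[Atom] = []
    serial = 1

    def _add(name: str, element: str, resname: str, resnum: int, pos: np.ndarray) -> None:
        nonlocal serial
        from ._tables import DEFAULT_VDW_RADIUS, VDW_RADII
        atoms.append(Atom(
            serial=serial, name=name, element=element, residue_name=resname,
            chain="A", residue_number=resnum, position=pos,
            vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
        ))
        serial += 1

    for i, aa in enumerate(sequence):
        resname = ONE_TO_THREE[aa]
        resnum = i + 1
        theta = i * _HELIX_TWIST
        z = i * _HELIX_RISE
        ca = _cylindrical(theta, _HELIX_RADIUS, z)
        n = _cylindrical(theta - math.radians(31.0), _HELIX_RADIUS, z - 0.77)
        c = _cylindrical(theta + math.radians(31.0), _HELIX_RADIUS, z + 0.77)
        o = _cylindrical(theta + math.radians(31.0), _HELIX_RADIUS + 1.23, z + 0.77)
        _add("N", "N", resname, resnum, n)
        _add("CA", "C", resname, resnum, ca)
        _add("C", "C", resname, resnum, c)
        _add("O", "O", resname, resnum, o)
        if aa != "G":
            cb = _cylindrical(theta, _HELIX_RADIUS + 1.53, z)
            _add("CB", "C", resname, resnum, cb)
            if aa == "C":
                sg = _cylindrical(theta, _HELIX_RADIUS + 3.3, z + 0.3)
                _add("SG", "S", resname, resnum, sg)

    structure = ProteinStructure(atoms=atoms, structure_id=structure_id)
    return structure, write_pdb(structure)


def synth_pssm(
    sequence: str,
    seed: int = 0,
    motif: dict[int, np.ndarray] | None = None,
) -> tuple[PSSMProfile, str]:
    """Random integer PSSM with a conservation-like boosted self-column.

    Scores are uniform on [-8, 8] with +4 added in each residue's own
    column; ``motif`` rows (0-based position -> 20-vector) are injected
    verbatim.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)
    matrix = rng.integers(-8, 9, size=(L, 20))
    idx = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}
    for i, aa in enumerate(sequence):
        if aa in idx:
            matrix[i, idx[aa]] += 4
    if motif:
        for pos, row in motif.items():
            matrix[pos] = np.asarray(row, dtype=int)
    profile = PSSMProfile(sequence=sequence, matrix=matrix)
    return profile, write_ascii_pssm(profile)


def planted_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """A labeled 80-column feature table with a planted mean-shift signal.

    Non-informative columns are standard normal for both classes; the
    designated informative columns are shifted by ``effect_size`` standard
    deviations for the positive (covalent) class.
    """
    n = spec.n_pos + spec.n_neg
    if n == 0:
        raise ValueError("dataset must have at least one row")
    missing = [c for c in spec.informative_columns if c not in FEATURE_COLUMNS]
    if missing:
        raise ValueError(f"unknown informative columns: {missing}")
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((n, len(FEATURE_COLUMNS)))
    y = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    cols = list(FEATURE_COLUMNS)
    for c in spec.informative_columns:
        X[y == 1, cols.index(c)] += spec.effect_size
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    index = [f"synth:{i:05d}" for i in range(n)]
    table = pd.DataFrame(X, columns=cols, index=index)
    table.index.name = "site"
    table[LABEL_COLUMN] = y
    return table


def fabricate_reports(
    structure: ProteinStructure, seed: int = 0
) -> tuple[str, str]:
    """Fabricate parseable pocket and pKa report texts for a structure.

    One pocket containing every residue of the structure (hence every
    cysteine), with a drug score in [0.3, 0.9]; pKa lines for each
    ionizable residue at its intrinsic value plus small noise.
    """
    rng = np.random.default_rng(seed)
    members = sorted(
        {(a.chain, a.residue_number) for a in structure.polymer_atoms()}
    )
    drug = float(rng.uniform(0.3, 0.9))
    hydro = float(rng.uniform(10.0, 60.0))
    polar = float(rng.uniform(5.0, 25.0))
    residue_tokens = " ".join(f"{ch}:{rn}" for ch, rn in members)
    pocket_text = (
        "Pocket 1 :\n"
        f"\tDruggability Score : \t{drug:.3f}\n"
        f"\tHydrophobicity score : \t{hydro:.1f}\n"
        f"\tPolarity score : \t{polar:.1f}\n"
        f"\tResidues : {residue_tokens}\n"
    )

    pka_lines = ["SUMMARY OF THIS PREDICTION", "   Group      pKa  model-pKa"]
    for chain, seq in structure.chains.items():
        for resnum, aa in zip(structure.residue_numbers(chain), seq):
            if aa in INTRINSIC_PKA:
                value = INTRINSIC_PKA[aa] + float(rng.normal(0.0, 0.3))
                pka_lines.append(
                    f"   {ONE_TO_THREE[aa]} {resnum:3d} {chain}   {value:8.2f}"
                    f"   {INTRINSIC_PKA[aa]:8.2f}"
                )
    return pocket_text, "\n".join(pka_lines) + "\n"
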