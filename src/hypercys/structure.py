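"""Protein structures and the structure-derived cysteine descriptors.

This module owns the 3D side of the feature inventory: the PDB reader, the
per-cysteine neighbor shells (amino-acid composition at 4/6/8/10 A), the
SASA/pKa shell profile, pocket membership, and the parsers for external
pocket-detector and pKa-predictor reports.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._tables import (
    DEFAULT_HP_TABLE,
    DEFAULT_VDW_RADIUS,
    INTRINSIC_PKA,
    IONIZABLE_RESIDUES,
    ONE_TO_THREE,
    THREE_TO_ONE,
    VDW_RADII,
)

logger = logging.getLogger(__name__)

#: Shell radii (Angstrom) at which neighbor composition and SASA/pKa
#: profiles are aggregated, in the canonical (descending) column order.
SHELL_RADII = (10.0, 8.0, 6.0, 4.0)

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates and residue bookkeeping."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    position: np.ndarray
    vdw_radius: float
    is_hetero: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw radius must be positive")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")


@dataclass
class ProteinStructure:
    """An ordered collection of atoms plus per-chain residue sequences."""

    atoms: list[Atom]
    structure_id: str = ""

    def __post_init__(self) -> None:
        self._by_residue: dict[tuple[str, int], list[Atom]] = {}
        for atom in self.atoms:
            self._by_residue.setdefault((atom.chain, atom.residue_number), []).append(atom)

    @property
    def chains(self) -> dict[str, str]:
        """chain id -> 1-letter sequence ordered by residue number."""
        chains: dict[str, str] = {}
        seen: dict[str, list[tuple[int, str]]] = {}
        for (chain, resnum), atoms in self._by_residue.items():
            if atoms[0].is_hetero:
                continue
            seen.setdefault(chain, []).append((resnum, atoms[0].residue_name))
        for chain, entries in seen.items():
            entries.sort()
            chains[chain] = "".join(THREE_TO_ONE.get(name, "X") for _, name in entries)
        return chains

    def residue_numbers(self, chain: str) -> list[int]:
        """Polymer residue numbers of a chain in ascending order."""
        nums = sorted(
            rn for (ch, rn), atoms in self._by_residue.items()
            if ch == chain and not atoms[0].is_hetero
        )
        return nums

    def residue_atoms(self, chain: str, residue_number: int) -> list[Atom]:
        return self._by_residue.get((chain, residue_number), [])

    def residue_name(self, chain: str, residue_number: int) -> str | None:
        atoms = self.residue_atoms(chain, residue_number)
        return atoms[0].residue_name if atoms else None

    def polymer_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hetero]


@dataclass
class CysteineSite:
    """A candidate cysteine, identified by chain and residue number."""

    chain: str
    residue_number: int
    sg_position: np.ndarray | None = None
    in_pocket: bool = False
    label: str = "unlabeled"
    structure_id: str = ""

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.structure_id, self.chain, self.residue_number)


@dataclass(frozen=True)
class ShellComposition:
    """Neighbor residue counts (total / hydrophobic / polar) per radius."""

    counts: Mapping[float, tuple[int, int, int]]  # radius -> (total, H, P)

    def total(self, r: float) -> int:
        return self.counts[r][0]

    def hydrophobic(self, r: float) -> int:
        return self.counts[r][1]

    def polar(self, r: float) -> int:
        return self.counts[r][2]


@dataclass(frozen=True)
class SPPVector:
    """The 18-component SASA/pKa shell profile of one cysteine."""

    site_sasa: float
    site_pka: float
    shell_values: Mapping[float, tuple[float, float, float, float]]
    # radius -> (pka_total, pka_ave, sasa_total, sasa_ave)

    def as_array(self) -> np.ndarray:
        vals: list[float] = []
        for r in SHELL_RADII:
            vals.extend(self.shell_values[r])
        vals.extend([self.site_sasa, self.site_pka])
        return np.asarray(vals, dtype=float)


@dataclass
class PocketProfile:
    """One detected binding pocket with druggability-related scores."""

    pocket_id: int
    member_residues: set[tuple[str, int]]
    drug_score: float
    hydrophobicity_score: float
    polarity_score: float
    atom_depth: float = 0.0


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _element_from_record(line: str, name: str) -> str:
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    if elem:
        return elem
    stripped = name.strip()
    # Atom names like "1HB1" start with a digit; strip to the letter part.
    stripped = stripped.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in VDW_RADII:
        return stripped[:2].upper()
    return stripped[:1].upper()


def parse_pdb(
    text: str,
    structure_id: str = "",
    include_hetero: bool = False,
) -> ProteinStructure:
    """Parse fixed-width PDB ATOM/HETATM records into a ProteinStructure.

    Waters are always skipped; other HETATM groups only when
    ``include_hetero`` is set.  Alternate locations are resolved to the
    highest-occupancy conformer (ties broken by altloc letter).
    """
    candidates: dict[tuple[str, int, str, bool], list[tuple[float, str, Atom]]] = {}
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        is_het = record == "HETATM"
        resname = line[17:20].strip()
        if resname in _WATER_RESNAMES:
            continue
        if is_het and not include_hetero:
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            chain = line[21].strip() or "A"
            resnum = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed PDB record at line {lineno}: {exc}") from exc
        element = _element_from_record(line, name)
        atom = Atom(
            serial=serial,
            name=name,
            element=element,
            residue_name=resname,
            chain=chain,
            residue_number=resnum,
            position=np.array([x, y, z]),
            vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
            is_hetero=is_het,
        )
        key = (chain, resnum, name, is_het)
        candidates.setdefault(key, []).append((occupancy, altloc, atom))
        n_records += 1
    if n_records == 0:
        raise ValueError("no ATOM records found in PDB input")

    atoms: list[Atom] = []
    for variants in candidates.values():
        # highest occupancy wins; occupancy ties broken alphabetically.
        best = max(variants, key=lambda t: (t[0], [-ord(c) for c in t[1]] or [0]))
        atoms.append(best[2])
    atoms.sort(key=lambda a: a.serial)
    return ProteinStructure(atoms=atoms, structure_id=structure_id)


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure to fixed-width PDB text (ATOM records only)."""
    lines = []
    for atom in structure.atoms:
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.position
        lines.append(
            f"{record}{atom.serial:>5d} {name:<4s} {atom.residue_name:<3s} "
            f"{atom.chain:1s}{atom.residue_number:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cysteine sites and neighbor shells
# ---------------------------------------------------------------------------

def find_cysteines(
    structure: ProteinStructure, chain: str | None = None
) -> list[CysteineSite]:
    """Locate every CYS residue, ordered by (chain, residue number)."""
    sites: list[CysteineSite] = []
    chains = [chain] if chain is not None else sorted(structure.chains)
    for ch in chains:
        for resnum in structure.residue_numbers(ch):
            if structure.residue_name(ch, resnum) != "CYS":
                continue
            sg = next(
                (a.position for a in structure.residue_atoms(ch, resnum) if a.name == "SG"),
                None,
            )
            if sg is None:
                logger.warning("CYS %s:%d has no SG atom", ch, resnum)
            sites.append(
                CysteineSite(
                    chain=ch,
                    residue_number=resnum,
                    sg_position=sg,
                    structure_id=structure.structure_id,
                )
            )
    return sites


def shell_members(
    structure: ProteinStructure,
    site: CysteineSite,
    radii: Sequence[float] = SHELL_RADII,
    include_hetero: bool = False,
) -> dict[float, list[tuple[str, int]]]:
    """Residues whose minimum heavy-atom distance to the cysteine is <= r.

    The distance between a residue and the cysteine is the minimum over all
    heavy-atom pairs; the cysteine itself is excluded.
    """
    cys_atoms = [
        a for a in structure.residue_atoms(site.chain, site.residue_number)
        if a.element != "H"
    ]
    if not cys_atoms:
        raise ValueError(f"site {site.chain}:{site.residue_number} not present")
    cys_xyz = np.array([a.position for a in cys_atoms])

    residue_min: dict[tuple[str, int], float] = {}
    for atom in structure.atoms:
        if atom.element == "H":
            continue
        if atom.is_hetero and not include_hetero:
            continue
        key = (atom.chain, atom.residue_number)
        if key == (site.chain, site.residue_number):
            continue
        d = float(np.min(np.linalg.norm(cys_xyz - atom.position, axis=1)))
        if key not in residue_min or d < residue_min[key]:
            residue_min[key] = d

    out: dict[float, list[tuple[str, int]]] = {}
    for r in radii:
        out[r] = sorted(k for k, d in residue_min.items() if d <= r)
    return out


def neighbor_shells(
    structure: ProteinStructure,
    site: CysteineSite,
    hp_table: Mapping[str, str] | None = None,
    radii: Sequence[float] = SHELL_RADII,
) -> ShellComposition:
    """Count neighbor residues per radius and split them into H/P classes."""
    hp = dict(DEFAULT_HP_TABLE if hp_table is None else hp_table)
    members = shell_members(structure, site, radii=radii)
    counts: dict[float, tuple[int, int, int]] = {}
    for r in radii:
        total = h = p = 0
        for chain, resnum in members[r]:
            name3 = structure.residue_name(chain, resnum)
            one = THREE_TO_ONE.get(name3 or "", None)
            if one is None:
                # Unknown/non-standard residue: counted, classified polar.
                logger.warning("unknown residue %s at %s:%d counted as polar",
                               name3, chain, resnum)
                total += 1
                p += 1
                continue
            cls = hp.get(one)
            if cls is None:
                logger.warning("residue %s missing from H/P table; classified polar", one)
                cls = "P"
            total += 1
            if cls == "H":
                h += 1
            else:
                p += 1
        counts[r] = (total, h, p)
    return ShellComposition(counts=counts)


# ---------------------------------------------------------------------------
# SASA/pKa aggregation
# ---------------------------------------------------------------------------

def aggregate_spp(
    site: CysteineSite,
    shells: Mapping[float, Iterable[tuple[str, int]]],
    residue_sasa: Mapping[tuple[str, int], float],
    pka: Mapping[tuple[str, int], float],
    residue_names: Mapping[tuple[str, int], str] | None = None,
    fallback_pka: Mapping[tuple[str, int], float] | None = None,
) -> SPPVector:
    """Aggregate shell SASA and pKa into the 18-component profile.

    SASA totals/averages run over every shell residue; pKa totals/averages
    run only over residues that have a predicted pKa (the ionizable set).
    Empty shells yield zero totals and averages.
    """
    site_key = (site.chain, site.residue_number)
    site_sasa = float(residue_sasa.get(site_key, 0.0))
    if site_key in pka:
        site_pka = float(pka[site_key])
    elif fallback_pka is not None and site_key in fallback_pka:
        site_pka = float(fallback_pka[site_key])
    else:
        raise ValueError(
            f"no pKa available for cysteine {site.chain}:{site.residue_number}"
        )

    shell_values: dict[float, tuple[float, float, float, float]] = {}
    for r in SHELL_RADII:
        members = list(shells.get(r, []))
        sasa_vals = [float(residue_sasa.get(m, 0.0)) for m in members]
        pka_vals = [float(pka[m]) for m in members if m in pka]
        if fallback_pka is not None:
            pka_vals += [
                float(fallback_pka[m]) for m in members
                if m not in pka and m in fallback_pka
            ]
        sasa_total = float(sum(sasa_vals))
        sasa_ave = sasa_total / len(sasa_vals) if sasa_vals else 0.0
        pka_total = float(sum(pka_vals))
        pka_ave = pka_total / len(pka_vals) if pka_vals else 0.0
        shell_values[r] = (pka_total, pka_ave, sasa_total, sasa_ave)
    return SPPVector(site_sasa=site_sasa, site_pka=site_pka, shell_values=shell_values)


def intrinsic_pka_fallback(
    structure: ProteinStructure,
) -> dict[tuple[str, int], float]:
    """Model pKa per ionizable residue from the intrinsic side-chain table."""
    out: dict[tuple[str, int], float] = {}
    for chain, seq in structure.chains.items():
        for resnum, aa in zip(structure.residue_numbers(chain), seq):
            if aa in INTRINSIC_PKA:
                out[(chain, resnum)] = INTRINSIC_PKA[aa]
    return out


# ---------------------------------------------------------------------------
# External-report parsers
# ---------------------------------------------------------------------------

_PKA_LINE = re.compile(
    r"^\s*([A-Z][A-Z0-9]{1,2})\s+(\d+)\s+([A-Za-z0-9])\s+(-?\d+\.?\d*)"
)


def parse_pka_report(text: str) -> dict[tuple[str, int], float]:
    """Parse the summary section of a pKa-predictor report.

    Expects lines of the form ``CYS  38 A     9.53`` below a ``SUMMARY``
    header.  Non-residue groups (termini, ligands) are skipped; duplicated
    residues keep the last value.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if "SUMMARY" in line.upper():
            start = i + 1
            break
    if start is None:
        raise ValueError("no pKa summary section found")
    out: dict[tuple[str, int], float] = {}
    for line in lines[start:]:
        m = _PKA_LINE.match(line)
        if not m:
            continue
        group, resnum, chain, pka = m.groups()
        if group not in THREE_TO_ONE:  # skip N+/C- termini and ligands
            continue
        key = (chain, int(resnum))
        if key in out:
            logger.warning("duplicate pKa line for %s:%s; last value wins", chain, resnum)
        out[key] = float(pka)
    return out


def parse_pocket_report(text: str) -> list[PocketProfile]:
    """Parse a pocket-detector info report into PocketProfile objects.

    The format is the ``Pocket N:`` block layout with ``Druggability Score``,
    ``Hydrophobicity score`` and ``Polarity score`` lines, followed by an
    optional ``Residues:`` line listing ``chain:residue_number`` members.
    """
    pockets: list[PocketProfile] = []
    current: dict[str, object] | None = None

    def _finish(cur: dict[str, object]) -> None:
        pid = cur["id"]
        for field_name in ("drug", "hydro", "polar"):
            if field_name not in cur:
                raise ValueError(f"pocket {pid}: missing score field '{field_name}'")
        members = cur.get("members")
        if members is None:
            logger.warning("pocket %s has no residue listing", pid)
            members = set()
        pockets.append(
            PocketProfile(
                pocket_id=int(cur["id"]),  # type: ignore[arg-type]
                member_residues=set(members),  # type: ignore[arg-type]
                drug_score=float(cur["drug"]),  # type: ignore[arg-type]
                hydrophobicity_score=float(cur["hydro"]),  # type: ignore[arg-type]
                polarity_score=float(cur["polar"]),  # type: ignore[arg-type]
            )
        )

    for line in text.splitlines():
        stripped = line.strip()
        m = re.match(r"^Pocket\s+(\d+)\s*:?", stripped)
        if m:
            if current is not None:
                _finish(current)
            current = {"id": int(m.group(1))}
            continue
        if current is None:
            continue
        low = stripped.lower()
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            key_low = key.strip().lower()
            value = value.strip()
            if key_low.startswith("druggability"):
                current["drug"] = float(value)
            elif key_low.startswith("hydrophobicity"):
                current["hydro"] = float(value)
            elif key_low.startswith("polarity"):
                current["polar"] = float(value)
            elif key_low.startswith("residues"):
                members = set()
                for token in value.split():
                    ch, _, rn = token.partition(":")
                    members.add((ch, int(rn)))
                current["members"] = members
    if current is not None:
        _finish(current)
    return pockets


def pocket_membership(
    site: CysteineSite, pockets: Sequence[PocketProfile]
) -> PocketProfile | None:
    """Pocket containing the site; ties resolved by highest drug score."""
    key = (site.chain, site.residue_number)
    containing = [p for p in pockets if key in p.member_residues]
    if not containing:
        site.in_pocket = False
        return None
    best = max(containing, key=lambda p: p.drug_score)
    site.in_pocket = True
    return best
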