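"""Benchmark-table construction: labels, redundancy filtering, assembly.

The feature table has one row per candidate cysteine and exactly 80 named
feature columns: 34 structure-based (SASA/pKa profile, pocket profile,
shell amino-acid composition) and 46 sequence-based (conservation profile,
pseudo-energy, secondary-structure profile), plus a binary label
(1 = covalently modified).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from ._tables import DEFAULT_HP_TABLE, PSSM_ALPHABET
from . import sequence as seqmod
from . import structure as structmod
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, compute_sasa, residue_depth
from .structure import (
    CysteineSite,
    PocketProfile,
    ProteinStructure,
    SHELL_RADII,
    aggregate_spp,
    neighbor_shells,
    pocket_membership,
    shell_members,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Canonical feature schema (fixed order; byte-identical across runs)
# ---------------------------------------------------------------------------

def _radius_label(r: float) -> str:
    return f"{int(r)}Å"  # e.g. "10Å"


SPP_COLUMNS = tuple(
    f"{_radius_label(r)}.{kind}"
    for r in SHELL_RADII
    for kind in ("pka.total", "pka.ave", "SASA.total", "SASA.ave")
) + ("SASA", "pKa")

PP_COLUMNS = ("Atom Depth", "Drug Score", "Hydrophobicity Score", "Polarity Score")

AAC_COLUMNS = tuple(
    f"{_radius_label(r)}.{kind}" for r in SHELL_RADII for kind in ("Total", "H", "P")
)

CP_COLUMNS = (
    tuple(f"PSSM.{aa}" for aa in PSSM_ALPHABET)
    + ("MG",)
    + tuple(f"BG.{aa}" for aa in PSSM_ALPHABET)
)

EP_COLUMNS = ("PSEE",)

SSP_COLUMNS = (
    "Helix probability",
    "Beta-Strand probability",
    "Coil probability",
    "ASA",
)

STRUCTURE_COLUMNS = SPP_COLUMNS + PP_COLUMNS + AAC_COLUMNS          # 34
SEQUENCE_COLUMNS = CP_COLUMNS + EP_COLUMNS + SSP_COLUMNS            # 46
FEATURE_COLUMNS = STRUCTURE_COLUMNS + SEQUENCE_COLUMNS              # 80

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "SPP": SPP_COLUMNS,
    "PP": PP_COLUMNS,
    "AAC": AAC_COLUMNS,
    "CP": CP_COLUMNS,
    "EP": EP_COLUMNS,
    "SSP": SSP_COLUMNS,
}

STRUCTURE_GROUPS = ("SPP", "PP", "AAC")
SEQUENCE_GROUPS = ("CP", "EP", "SSP")

LABEL_COLUMN = "label"


def column_group(name: str) -> str:
    for group, cols in FEATURE_GROUPS.items():
        if name in cols:
            return group
    raise KeyError(f"feature column {name!r} is not in the schema")


def site_id(site: CysteineSite) -> str:
    return f"{site.structure_id or 'NA'}:{site.chain}:{site.residue_number}"


# ---------------------------------------------------------------------------
# Annotation and labeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovalentAnnotation:
    """One covalently modified cysteine: structure, chain, residue number."""

    structure_id: str
    chain: str
    residue_number: int

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.structure_id, self.chain, self.residue_number)


def read_annotations(path: str | Path) -> list[CovalentAnnotation]:
    """Read the covalent-site annotation CSV (header required)."""
    df = pd.read_csv(path)
    required = {"structure_id", "chain", "residue_number"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    return [
        CovalentAnnotation(str(r.structure_id), str(r.chain), int(r.residue_number))
        for r in df.itertuples()
    ]


def label_sites(
    sites: Sequence[CysteineSite],
    annotations: Iterable[CovalentAnnotation],
) -> list[CysteineSite]:
    """Label annotated sites covalent, other pocket sites noncovalent.

    Cysteines outside any detected pocket are dropped (annotated sites are
    retained regardless, since an observed covalent adduct implies a
    binding site).  Annotations that match no extracted site are an error.
    """
    by_key = {s.key: s for s in sites}
    ann_keys = {a.key for a in annotations}
    orphans = sorted(ann_keys - set(by_key))
    if orphans:
        raise ValueError(f"annotations reference absent cysteines: {orphans}")
    out: list[CysteineSite] = []
    for s in sites:
        if s.key in ann_keys:
            s.label = "covalent"
            out.append(s)
        elif s.in_pocket:
            s.label = "noncovalent"
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Redundancy filtering (greedy global-identity clustering)
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global alignment identity = matches / alignment length (with gaps)."""
    if not a or not b:
        return 0.0
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length if length else 0.0


def greedy_identity_filter(
    sequences: Mapping[str, str], threshold: float = 0.5
) -> set[str]:
    """Greedy redundancy reduction at a global-identity threshold.

    Sequences are visited by descending length (ties by id); each becomes a
    new representative unless it matches an existing representative at
    >= threshold identity.  Deterministic.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    aligner = _make_aligner()
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []
    for sid in order:
        seq = sequences[sid]
        if any(pairwise_identity(seq, sequences[r], aligner) >= threshold for r in reps):
            continue
        reps.append(sid)
    return set(reps)


def read_clstr(text: str) -> set[str]:
    """Adapter: representative ids from a CD-HIT .clstr file."""
    reps: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if line.endswith("*") and ">" in line:
            name = line.split(">", 1)[1].split("...", 1)[0]
            reps.add(name)
    return reps


# ---------------------------------------------------------------------------
# Feature extraction into tables
# ---------------------------------------------------------------------------

def extract_structure_features(
    structure: ProteinStructure,
    sites: Sequence[CysteineSite],
    pockets: Sequence[PocketProfile] = (),
    pka: Mapping[tuple[str, int], float] | None = None,
    hp_table: Mapping[str, str] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    pka_fallback: bool = False,
) -> pd.DataFrame:
    """The 34 structure-based features for each site, as a DataFrame.

    ``pka`` holds external pKa predictions; with ``pka_fallback`` the
    intrinsic side-chain table fills any gaps (and may stand alone).
    Sites outside every pocket get zero pocket scores.
    """
    from .structure import intrinsic_pka_fallback

    pka = dict(pka or {})
    fallback = intrinsic_pka_fallback(structure) if pka_fallback else None
    sasa = compute_sasa(structure, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    hp = dict(DEFAULT_HP_TABLE if hp_table is None else hp_table)

    rows: dict[str, list[float]] = {}
    for site in sites:
        shells = shell_members(structure, site)
        comp = neighbor_shells(structure, site, hp_table=hp)
        spp = aggregate_spp(
            site, shells, sasa.residue_sasa, pka,
            fallback_pka=fallback,
        )
        pocket = pocket_membership(site, pockets)
        depth = residue_depth(structure, site, sasa)
        values = list(spp.as_array())
        values += [
            depth,
            pocket.drug_score if pocket else 0.0,
            pocket.hydrophobicity_score if pocket else 0.0,
            pocket.polarity_score if pocket else 0.0,
        ]
        for r in SHELL_RADII:
            values += [comp.total(r), comp.hydrophobic(r), comp.polar(r)]
        rows[site_id(site)] = values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(STRUCTURE_COLUMNS))
    df.index.name = "site"
    return df


def extract_sequence_features(
    structure: ProteinStructure,
    pssms: Mapping[str, seqmod.PSSMProfile],
    sites: Sequence[CysteineSite],
    window_size: int = 21,
    ssp: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """The 46 sequence-based features at each site's chain position.

    ``ssp`` optionally supplies externally predicted L x 4 secondary
    structure / accessibility arrays per chain; otherwise the built-in
    propensity fallback is used.
    """
    chains = structure.chains
    per_chain: dict[str, dict[str, np.ndarray | seqmod.SmoothedPSSM]] = {}
    for chain, profile in pssms.items():
        if chain not in chains:
            raise ValueError(f"PSSM provided for unknown chain {chain!r}")
        if profile.sequence != chains[chain]:
            raise ValueError(
                f"PSSM sequence mismatch for chain {chain!r}: "
                f"{profile.sequence!r} vs {chains[chain]!r}"
            )
        smoothed = seqmod.smooth_pssm(profile, window_size)
        p_norm = seqmod.normalize_pssm(profile.matrix)
        consensus = seqmod.consensus_sequence(profile)
        mg = seqmod.monogram(p_norm, consensus)
        bg = seqmod.bigram(p_norm, consensus)
        ssp_arr = (
            np.asarray(ssp[chain]) if ssp is not None and chain in ssp
            else seqmod.propensity_ssp_fallback(profile.sequence)
        )
        if ssp_arr.shape != (len(profile), 4):
            raise ValueError(f"SSP array for chain {chain!r} has wrong shape")
        psee_vals = seqmod.psee(profile.sequence, ssp_arr[:, 3])
        per_chain[chain] = {
            "smoothed": smoothed, "mg": mg, "bg": bg,
            "psee": psee_vals, "ssp": ssp_arr,
        }

    rows: dict[str, np.ndarray] = {}
    for site in sites:
        if site.chain not in per_chain:
            raise ValueError(f"no PSSM for chain {site.chain!r}")
        resnums = structure.residue_numbers(site.chain)
        pos = resnums.index(site.residue_number)
        ch = per_chain[site.chain]
        rows[site_id(site)] = seqmod.residue_seq_features(
            ch["smoothed"], ch["mg"], ch["bg"], ch["psee"], ch["ssp"], pos,
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(SEQUENCE_COLUMNS))
    df.index.name = "site"
    return df


def assemble_features(
    struct_rows: pd.DataFrame,
    seq_rows: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Join the 34-column and 46-column tables into the 80-column table.

    Keys must match exactly on both sides; no imputation is performed.
    """
    left = set(struct_rows.index)
    right = set(seq_rows.index)
    if left != right:
        only_left = sorted(left - right)
        only_right = sorted(right - left)
        raise ValueError(
            "site keys disagree between structure and sequence tables; "
            f"structure-only={only_left}, sequence-only={only_right}"
        )
    table = struct_rows.join(seq_rows, how="inner")[list(FEATURE_COLUMNS)]
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values after assembly in columns {bad}")
    if labels is not None:
        lab = pd.Series(labels).reindex(table.index)
        if lab.isna().any():
            raise ValueError("labels missing for some sites")
        if not set(lab.unique()) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        table[LABEL_COLUMN] = lab.astype(int)
    return table


def summarize(
    table: pd.DataFrame,
    features: Sequence[str],
    by_label: bool = True,
) -> pd.DataFrame:
    """Min/Q1/median/Q3/max/mean/SD per feature (and label group).

    Quartiles use linear interpolation between order statistics; SD uses
    the population (n) denominator.
    """
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    groups: list[tuple[str, pd.DataFrame]] = []
    if by_label and LABEL_COLUMN in table.columns:
        for value, sub in table.groupby(LABEL_COLUMN):
            name = "covalent" if value == 1 else "noncovalent"
            groups.append((name, sub))
    else:
        groups.append(("all", table))
    records = []
    for gname, sub in groups:
        if sub.empty:
            raise ValueError(f"empty group {gname!r}")
        for feat in features:
            v = sub[feat].to_numpy(dtype=float)
            records.append({
                "feature": feat,
                "group": gname,
                "min": float(np.min(v)),
                "Q1": float(np.percentile(v, 25)),
                "median": float(np.percentile(v, 50)),
                "Q3": float(np.percentile(v, 75)),
                "max": float(np.max(v)),
                "mean": float(np.mean(v)),
                "SD": float(np.std(v)),
            })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def write_feature_table(
    table: pd.DataFrame, path: str | Path, config: Mapping[str, object] | None = None
) -> None:
    """Write the table as CSV plus a JSON sidecar recording the schema."""
    path = Path(path)
    table.to_csv(path, index=True)
    sidecar = {
        "columns": list(table.columns),
        "n_rows": int(table.shape[0]),
        "hp_table": DEFAULT_HP_TABLE,
        "config": dict(config or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
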