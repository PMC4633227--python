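"""Compound-target profile assembly and structural deduplication.

Profiles are built from two evidence streams: chemical-protein interaction
tables carrying an evidence channel per record (only the reliable
``experimental`` and ``database`` channels are kept), and protein bioassay
records (a target is associated when the compound inhibits it at
IC50 <= 1 uM).  Structurally identical compounds appearing under different
identifiers are then collapsed: compounds whose path-based fingerprints
have Tanimoto coefficient exactly 1 are grouped transitively and merged
into a single record whose target set is the union over the group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurization import SmilesParseError, _mol_from_smiles

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundTargetProfile",
    "compute_fingerprint",
    "tanimoto",
    "filter_interaction_channels",
    "targets_from_bioassays",
    "parse_concentration_um",
    "map_protein_ids",
    "dedup_and_merge",
    "profiles_from_interactions",
    "write_profiles",
    "read_profiles",
    "ALLOWED_CHANNELS",
]

#: Evidence channels retained when building profiles from interaction tables.
ALLOWED_CHANNELS = frozenset({"experimental", "database"})

KNOWN_CHANNELS = frozenset({"experimental", "database", "textmining", "predicted"})

# Fingerprint convention: hashed linear/branched paths up to 7 bonds folded
# into 1024 bits (RDKit path fingerprint). Duplicate detection requires the
# Tanimoto coefficient to be exactly 1 at this resolution.
FP_SIZE = 1024
FP_MAX_PATH = 7


@dataclass
class CompoundTargetProfile:
    """A compound identifier, its canonical structure and its target gene set."""

    compound_id: str
    smiles: str
    targets: frozenset[str]
    source: str = "curated"
    merged_from: tuple[str, ...] = ()

    def __post_init__(self):
        self.targets = frozenset(str(t) for t in self.targets)


def compute_fingerprint(smiles: str, compound_id: str | None = None) -> np.ndarray:
    """Path-based hashed fingerprint (1024 bits, paths <= 7 bonds) as a bool array."""
    mol = _mol_from_smiles(smiles, compound_id)
    bv = Chem.RDKFingerprint(mol, maxPath=FP_MAX_PATH, fpSize=FP_SIZE)
    arr = np.zeros(FP_SIZE, dtype=bool)
    for bit in bv.GetOnBits():
        arr[bit] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| on bit vectors; 1.0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def filter_interaction_channels(
    records: pd.DataFrame, allowed: frozenset[str] = ALLOWED_CHANNELS
) -> pd.DataFrame:
    """Keep interaction records whose evidence channel is in ``allowed``.

    Unknown channel values are dropped with a warning (they indicate a
    malformed table rather than a low-confidence channel).
    """
    if "channel" not in records.columns:
        raise ValueError("interaction table must have a 'channel' column")
    chan = records["channel"].astype(str)
    unknown = records[~chan.isin(KNOWN_CHANNELS)]
    if len(unknown):
        warnings.warn(
            f"dropping {len(unknown)} records with unknown channels "
            f"{sorted(unknown['channel'].astype(str).unique())}", stacklevel=2)
    return records[chan.isin(allowed)].copy()


def parse_concentration_um(value: float, unit: str) -> float | None:
    """Normalize an assay concentration to micromolar.

    Unit dialects are matched on the first letter, case-insensitively:
    'u...' (or the micro sign) means micromolar, 'n...' nanomolar —
    mirroring LIKE 'u%' / LIKE 'n%' filters on free-text unit columns.
    Returns None for unrecognized units.
    """
    u = str(unit).strip().lower()
    if not u:
        return None
    if u[0] in ("u", "µ", "μ"):
        return float(value)
    if u[0] == "n":
        return float(value) / 1000.0
    return None


def targets_from_bioassays(
    records: pd.DataFrame,
    threshold_um: float = 1.0,
    assay_types: frozenset[str] = frozenset({"IC50"}),
) -> dict[str, set[str]]:
    """Associate targets with compounds from potent protein-assay records.

    A record associates its target with its compound when the assay type is
    accepted and the value, normalized to micromolar, is <= ``threshold_um``
    (boundary inclusive: 1000 nM associates at the default 1 uM cutoff).
    Records with unknown units are skipped with a warning.
    """
    needed = {"compound_id", "target_id", "assay_type", "value", "unit"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"bioassay table missing columns: {sorted(missing)}")
    out: dict[str, set[str]] = {}
    n_bad_unit = 0
    for rec in records.itertuples(index=False):
        if str(rec.assay_type) not in assay_types:
            continue
        um = parse_concentration_um(rec.value, rec.unit)
        if um is None:
            n_bad_unit += 1
            continue
        if um <= threshold_um:
            out.setdefault(str(rec.compound_id), set()).add(str(rec.target_id))
    if n_bad_unit:
        warnings.warn(f"skipped {n_bad_unit} bioassay records with unknown units",
                      stacklevel=2)
    return out


def map_protein_ids(records: pd.DataFrame, mapping: pd.DataFrame,
                    id_column: str = "protein_id") -> pd.DataFrame:
    """Translate protein identifiers to gene ids via a two-column mapping table.

    ``mapping`` has columns (source_id, gene_id); duplicate mapping rows are
    collapsed before the join.  Records whose identifier is absent from the
    map are dropped, with the count logged.
    """
    if list(mapping.columns[:2]) != ["source_id", "gene_id"]:
        mapping = mapping.rename(columns=dict(zip(mapping.columns[:2],
                                                  ["source_id", "gene_id"])))
    mapping = mapping.drop_duplicates(subset=["source_id", "gene_id"])
    merged = records.merge(mapping, left_on=id_column, right_on="source_id", how="left")
    n_unmapped = int(merged["gene_id"].isna().sum())
    if n_unmapped:
        logger.warning("map_protein_ids dropped %d unmapped records", n_unmapped)
    merged = merged.dropna(subset=["gene_id"]).drop(columns=["source_id"])
    merged["gene_id"] = merged["gene_id"].astype(str)
    return merged


def profiles_from_interactions(records: pd.DataFrame,
                               smiles_by_id: Mapping[str, str],
                               source: str = "stitch-like") -> list[CompoundTargetProfile]:
    """Aggregate (compound_id, gene_id) interaction rows into profiles.

    Records are expected to be channel-filtered and id-mapped already.
    Compounds with no SMILES in ``smiles_by_id`` are skipped with a warning.
    """
    target_col = "gene_id" if "gene_id" in records.columns else "protein_id"
    grouped = records.groupby("compound_id")[target_col].agg(lambda s: frozenset(map(str, s)))
    profiles = []
    n_missing = 0
    for cid, targets in grouped.items():
        smi = smiles_by_id.get(str(cid))
        if smi is None:
            n_missing += 1
            continue
        profiles.append(CompoundTargetProfile(str(cid), smi, targets, source=source))
    if n_missing:
        warnings.warn(f"{n_missing} compounds had no SMILES and were skipped",
                      stacklevel=2)
    return profiles


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # keep the smaller input index as root so representatives are
            # first-seen compounds
            if ri > rj:
                ri, rj = rj, ri
            self.parent[rj] = ri


def dedup_and_merge(profiles: Sequence[CompoundTargetProfile]) -> list[CompoundTargetProfile]:
    """Collapse structurally identical compounds, merging their target sets.

    Profiles whose fingerprints have Tanimoto coefficient exactly 1 are
    grouped by transitive closure (union-find); each group becomes one
    record whose id and SMILES come from its first member in input order,
    whose targets are the union over members, and whose ``merged_from``
    audit field lists every member id.  Profiles with unparseable SMILES
    are passed through unmerged with a warning.
    """
    fps: list[np.ndarray | None] = []
    for p in profiles:
        try:
            fps.append(compute_fingerprint(p.smiles, p.compound_id))
        except SmilesParseError:
            warnings.warn(f"unparseable SMILES for {p.compound_id}; left unmerged",
                          stacklevel=2)
            fps.append(None)
    uf = _UnionFind(len(profiles))
    # Tanimoto == 1 on equal-length bit vectors is bit-for-bit equality, so
    # grouping hashes the fingerprint bytes instead of an O(n^2) scan.
    by_key: dict[bytes, int] = {}
    for i, fp in enumerate(fps):
        if fp is None:
            continue
        key = np.packbits(fp).tobytes()
        if key in by_key:
            uf.union(by_key[key], i)
        else:
            by_key[key] = i
    groups: dict[int, list[int]] = {}
    for i in range(len(profiles)):
        groups.setdefault(uf.find(i), []).append(i)
    merged: list[CompoundTargetProfile] = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = sorted(groups[root])
        head = profiles[members[0]]
        if len(members) == 1:
            merged.append(head)
            continue
        targets = frozenset().union(*(profiles[i].targets for i in members))
        merged.append(CompoundTargetProfile(
            compound_id=head.compound_id,
            smiles=head.smiles,
            targets=targets,
            source=head.source,
            merged_from=tuple(profiles[i].compound_id for i in members),
        ))
    return merged


def write_profiles(profiles: Iterable[CompoundTargetProfile], path: str | Path) -> None:
    rows = [{
        "compound_id": p.compound_id,
        "smiles": p.smiles,
        "targets": ",".join(sorted(p.targets)),
        "merged_from": ",".join(p.merged_from),
        "source": p.source,
    } for p in profiles]
    pd.DataFrame(rows, columns=["compound_id", "smiles", "targets",
                                "merged_from", "source"]).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[CompoundTargetProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for rec in df.itertuples(index=False):
        out.append(CompoundTargetProfile(
            compound_id=rec.compound_id,
            smiles=rec.smiles,
            targets=frozenset(t for t in rec.targets.split(",") if t),
            source=rec.source or "curated",
            merged_from=tuple(t for t in rec.merged_from.split(",") if t),
        ))
    return out
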