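"""Drug-likeness and bioactivity annotation of screened compounds.

Each selected compound is annotated with six physicochemical properties
(MW, logP, H-bond donors/acceptors, TPSA, rotatable bonds), a Lipinski
rule-of-five pass flag, a TPSA poor-absorption flag (>= 140 A^2), a
medicinal-chemistry friendliness tag (absence of catalogued undesirable
functional groups), and whether any GI50 cell-proliferation assay reports
activity at <= 50 uM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .featurization import SmartsCatalog, SmilesParseError, _mol_from_smiles
from .pls import OCScoreRecord
from .targets import parse_concentration_um

logger = logging.getLogger(__name__)

__all__ = [
    "PhyschemProfile",
    "AnnotationRecord",
    "compute_properties",
    "rule_of_five",
    "tpsa_flag",
    "medchem_friendly",
    "gi50_active",
    "build_report",
    "TPSA_THRESHOLD",
    "GI50_CUTOFF_UM",
]

TPSA_THRESHOLD = 140.0  # A^2; inclusive poor-absorption threshold
GI50_CUTOFF_UM = 50.0  # inclusive activity cutoff for GI50 assays


@dataclass(frozen=True)
class PhyschemProfile:
    mw: float  # g/mol
    logp: float  # Crippen atom-contribution logP
    hbd: int
    hba: int
    tpsa: float  # A^2, Ertl fragment-contribution TPSA
    nrot: int

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError("molecular weight must be positive")
        if min(self.hbd, self.hba, self.nrot) < 0 or self.tpsa < 0:
            raise ValueError("counts and TPSA must be non-negative")


@dataclass
class AnnotationRecord:
    compound_id: str
    physchem: PhyschemProfile
    rule_of_five_pass: bool
    tpsa_poor_absorption: bool
    medchem_friendly: str  # 'Y' / 'N'
    gi50_active: bool
    oc_score: float


def compute_properties(smiles: str, compound_id: str | None = None) -> PhyschemProfile:
    """Six standard physicochemical properties of a molecule.

    logP is the Crippen atom-contribution estimate and TPSA the Ertl
    fragment-contribution value; both are method-dependent conventions and
    the flags below inherit them.
    """
    mol = _mol_from_smiles(smiles, compound_id)
    return PhyschemProfile(
        mw=float(Descriptors.MolWt(mol)),
        logp=float(Crippen.MolLogP(mol)),
        hbd=int(Lipinski.NumHDonors(mol)),
        hba=int(Lipinski.NumHAcceptors(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        nrot=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
    )


def rule_of_five(p: PhyschemProfile) -> bool:
    """Lipinski pass: violations only on strict excess of each threshold.

    Poor absorption is predicted when HBD > 5, HBA > 10, MW > 500 or
    logP > 5; a value sitting exactly on a threshold passes.
    """
    return p.hbd <= 5 and p.hba <= 10 and p.mw <= 500.0 and p.logp <= 5.0


def tpsa_flag(p: PhyschemProfile, threshold: float = TPSA_THRESHOLD) -> bool:
    """Poor-intestinal-absorption flag: TPSA >= threshold (inclusive)."""
    return p.tpsa >= threshold


def medchem_friendly(smiles: str, bad_groups: SmartsCatalog,
                     compound_id: str | None = None) -> str:
    """'N' iff any catalogued undesirable functional group is present.

    Unparseable structures are conservatively tagged 'N' with a warning.
    """
    try:
        mol = _mol_from_smiles(smiles, compound_id)
    except SmilesParseError:
        warnings.warn(f"unparseable SMILES for {compound_id}; tagged 'N'", stacklevel=2)
        return "N"
    for query in bad_groups.compiled():
        if mol.HasSubstructMatch(query):
            return "N"
    return "Y"


def gi50_active(value: float, unit: str, cutoff_um: float = GI50_CUTOFF_UM) -> bool:
    """GI50 activity: value <= 50 uM (equivalently <= 50000 nM), inclusive.

    Unit dialects are resolved on the first letter ('u...' micromolar,
    'n...' nanomolar); unknown units are inactive with a warning.
    """
    um = parse_concentration_um(value, unit)
    if um is None:
        warnings.warn(f"unknown assay unit {unit!r}; treated as inactive", stacklevel=2)
        return False
    return um <= cutoff_um


def build_report(
    scored: Sequence[OCScoreRecord],
    smiles_by_id: Mapping[str, str],
    assays: pd.DataFrame | None = None,
    bad_groups: SmartsCatalog | None = None,
    gi50_cutoff_um: float = GI50_CUTOFF_UM,
    tpsa_threshold: float = TPSA_THRESHOLD,
) -> list[AnnotationRecord]:
    """Assemble the per-compound annotation table for a screened list.

    ``assays`` is a bioassay table with columns (compound_id, assay_type,
    value, unit); a compound is GI50-active if any of its GI50 records is
    active at the cutoff.  Compounds whose SMILES is missing or unparseable
    are dropped with a warning.  Summary counts are logged.
    """
    active_ids: set[str] = set()
    if assays is not None and len(assays):
        for rec in assays.itertuples(index=False):
            if str(rec.assay_type) == "GI50" and gi50_active(rec.value, rec.unit,
                                                             gi50_cutoff_um):
                active_ids.add(str(rec.compound_id))
    records: list[AnnotationRecord] = []
    for s in scored:
        smi = smiles_by_id.get(s.compound_id)
        if smi is None:
            warnings.warn(f"no SMILES for screened compound {s.compound_id}; dropped",
                          stacklevel=2)
            continue
        try:
            phys = compute_properties(smi, s.compound_id)
        except SmilesParseError:
            warnings.warn(f"unparseable SMILES for {s.compound_id}; dropped",
                          stacklevel=2)
            continue
        tag = ("Y" if bad_groups is None or len(bad_groups) == 0
               else medchem_friendly(smi, bad_groups, s.compound_id))
        records.append(AnnotationRecord(
            compound_id=s.compound_id,
            physchem=phys,
            rule_of_five_pass=rule_of_five(phys),
            tpsa_poor_absorption=tpsa_flag(phys, tpsa_threshold),
            medchem_friendly=tag,
            gi50_active=s.compound_id in active_ids,
            oc_score=s.oc_score,
        ))
    logger.info(
        "annotation summary: %d compounds, %d rule-of-five pass, %d medchem friendly, "
        "%d GI50 active",
        len(records),
        sum(r.rule_of_five_pass for r in records),
        sum(r.medchem_friendly == "Y" for r in records),
        sum(r.gi50_active for r in records),
    )
    return records


def report_to_frame(records: Iterable[AnnotationRecord]) -> pd.DataFrame:
    rows = [{
        "CompoundId": r.compound_id,
        "OC_Score": r.oc_score,
        "TPSA": r.physchem.tpsa,
        "HBD": r.physchem.hbd,
        "MW": r.physchem.mw,
        "logP": r.physchem.logp,
        "HBA": r.physchem.hba,
        "NROT": r.physchem.nrot,
        "TPSA_poor_absorption": r.tpsa_poor_absorption,
        "Med_chem_friendly": r.medchem_friendly,
        "Active_GI50_assay": int(r.gi50_active),
        "RuleOfFive_Pass": r.rule_of_five_pass,
    } for r in records]
    return pd.DataFrame(rows)


def write_report(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    report_to_frame(records).to_csv(path, index=False)
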