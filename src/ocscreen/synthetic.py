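"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real inputs —
compound libraries with known functional-group content, a three-class
drug-target training matrix with a planted oral-cancer target signal,
multi-channel chemical-protein interaction records, and bioassay records
spanning the micromolar/nanomolar unit dialects — without any database
access, so each stage can be tested against construction-time truth.

Molecules are assembled from a fixed fragment library: an alkane backbone
with functional-group branches drawn from a set of mutually orthogonal
fragments (no fragment's group is matched by another fragment's pattern),
so the true feature vector of every generated compound is exact by
construction.

One global seed drives independent per-generator streams (seed, stream-id),
so adding a generator never perturbs the output of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .featurization import SmartsCatalog, default_catalog
from .pls import TrainingMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticLibrary",
    "FRAGMENTS",
    "synthetic_group_catalog",
    "generate_compound_library",
    "generate_training_matrix",
    "generate_interaction_table",
    "generate_bioassay_records",
]

# Stream ids for the per-generator derived RNG streams.
_STREAM_LIBRARY = 1
_STREAM_MATRIX = 2
_STREAM_INTERACTIONS = 3
_STREAM_BIOASSAYS = 4

IC50_CUTOFF_UM = 1.0
GI50_CUTOFF_UM = 50.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for all generators; same seed => byte-identical output."""

    seed: int = 0
    n_oral: int = 33  # class-1 training compounds (oral-cancer actives)
    n_cancer: int = 100  # class-0 (other-cancer actives)
    n_other: int = 100  # class-(-1) (no anticancer activity)
    n_targets: int = 50
    n_signal_targets: int = 5  # targets enriched in class-1 profiles
    signal_strength: float = 0.9  # P(class-1 compound carries a signal target)
    mean_targets_per_compound: float = 2.5  # sets the background presence rate
    background_rate: float | None = None  # overrides mean_targets_per_compound/n_targets
    include_prior_instance: bool = False  # extra class-1 row carrying all signal targets
    n_compounds: int = 200  # library size for the featurization/classifier stages
    n_interactions: int = 1000
    channel_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    signal_compound_fraction: float = 0.1  # screening compounds planted with the signal profile
    n_assays: int = 200
    unit_dialects: tuple[str, ...] = ("uM", "nM")

    def __post_init__(self):
        for name in ("n_oral", "n_cancer", "n_other", "n_targets", "n_signal_targets",
                     "n_compounds", "n_interactions", "n_assays"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_signal_targets > self.n_targets:
            raise ValueError("n_signal_targets cannot exceed n_targets")
        if self.mean_targets_per_compound <= 0:
            raise ValueError("mean_targets_per_compound must be positive")
        if abs(sum(self.channel_proportions) - 1.0) > 1e-9:
            raise ValueError("channel_proportions must sum to 1")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    @property
    def effective_background_rate(self) -> float:
        if self.background_rate is not None:
            return self.background_rate
        return self.mean_targets_per_compound / self.n_targets


# ---------------------------------------------------------------------------
# Compound library from an orthogonal fragment library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A branch SMILES attachable to a backbone carbon and the groups it adds."""

    name: str
    branch: str  # SMILES fragment placed in parentheses on a backbone carbon
    groups: tuple[str, ...]  # catalog group names this fragment introduces


# Branches are attached to distinct sp3 backbone carbons, so no combination
# of fragments creates a group outside its declared set.  Orthogonality
# against the patterns below is asserted by the test suite.
FRAGMENTS: tuple[Fragment, ...] = (
    Fragment("alcohol", "O", ("alcohol",)),
    Fragment("primary_amine", "N", ("primary_amine",)),
    Fragment("ketone", "C(C)=O", ("ketone",)),
    Fragment("carboxylic_acid", "C(=O)O", ("carboxylic_acid",)),
    Fragment("chloro", "Cl", ("chloro",)),
    Fragment("fluoro", "F", ("fluoro",)),
    Fragment("nitrile", "C#N", ("nitrile",)),
    Fragment("benzene_ring", "c1ccccc1", ("benzene_ring",)),
    Fragment("thioether", "SC", ("thioether",)),
    Fragment("ether", "OC", ("ether",)),
)

#: Groups whose presence marks a compound "active" in labelled libraries,
#: making class membership a deterministic function of the feature vector.
ACTIVE_GROUPS: tuple[str, ...] = ("carboxylic_acid", "primary_amine", "ketone")


def synthetic_group_catalog() -> SmartsCatalog:
    """The fragment-library feature space: the default-catalog patterns
    restricted to the groups the generator can build in."""
    full = default_catalog()
    names = [f.name for f in FRAGMENTS]
    keep = [full.index(n) for n in names]
    return full.subset(keep)


@dataclass
class SyntheticLibrary:
    """Generated compounds with construction-time ground truth."""

    compound_ids: list[str]
    smiles: list[str]
    features: np.ndarray  # true binary vectors over ``catalog``
    labels: np.ndarray  # 1 iff any ACTIVE_GROUPS member present
    catalog: SmartsCatalog

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"compound_id": self.compound_ids, "smiles": self.smiles,
                           "label": self.labels})
        for j, name in enumerate(self.catalog.names):
            df[name] = self.features[:, j]
        return df

    def records(self) -> list[tuple[str, str]]:
        return list(zip(self.compound_ids, self.smiles))


def _assemble(backbone_len: int, branches: Sequence[str]) -> str:
    """Linear alkane backbone with one branch per carbon, e.g. C(O)C(Cl)CC."""
    n = max(backbone_len, len(branches), 1)
    parts = []
    for i in range(n):
        if i < len(branches):
            parts.append(f"C({branches[i]})")
        else:
            parts.append("C")
    return "".join(parts)


def generate_compound_library(
    config: SyntheticConfig,
    group_catalog: SmartsCatalog | None = None,
    p_fragment: float = 0.35,
) -> SyntheticLibrary:
    """Assemble ``config.n_compounds`` molecules with exact known features.

    Each compound is an alkane backbone (3-8 carbons) decorated with each
    fragment independently with probability ``p_fragment``.  The recorded
    feature vector is the union of the built-in fragments' group sets; the
    label is 1 iff an ACTIVE_GROUPS member is present.
    """
    catalog = group_catalog if group_catalog is not None else synthetic_group_catalog()
    if len(catalog) == 0:
        raise ValueError("group catalog must be non-empty")
    usable = [f for f in FRAGMENTS if all(g in catalog.names for g in f.groups)]
    if not usable:
        raise ValueError("no fragment maps onto the supplied catalog")
    rng = config._rng(_STREAM_LIBRARY)
    ids, smiles_list, rows, labels = [], [], [], []
    for k in range(config.n_compounds):
        backbone = int(rng.integers(3, 9))
        mask = rng.random(len(usable)) < p_fragment
        chosen = [f for f, m in zip(usable, mask) if m]
        smiles = _assemble(backbone, [f.branch for f in chosen])
        bits = np.zeros(len(catalog), dtype=np.uint8)
        for f in chosen:
            for g in f.groups:
                bits[catalog.index(g)] = 1
        ids.append(f"SYN{k:05d}")
        smiles_list.append(smiles)
        rows.append(bits)
        labels.append(int(any(f.name in ACTIVE_GROUPS for f in chosen)))
    features = (np.array(rows, dtype=np.uint8) if rows
                else np.zeros((0, len(catalog)), dtype=np.uint8))
    return SyntheticLibrary(ids, smiles_list, features,
                            np.array(labels, dtype=np.int64), catalog)


# ---------------------------------------------------------------------------
# Three-class training matrix with planted signal targets
# ---------------------------------------------------------------------------

def generate_training_matrix(config: SyntheticConfig) -> tuple[TrainingMatrix, list[str]]:
    """Drug-target presence matrix with a planted oral-cancer signal.

    Exactly ``n_oral`` class-1, ``n_cancer`` class-0 and ``n_other``
    class-(-1) rows.  The first ``n_signal_targets`` target columns are the
    planted signal: present in class-1 rows with probability
    ``signal_strength``; every other cell is filled at the background rate.
    Returns the matrix and the ground-truth signal-target id list.
    """
    if config.n_targets == 0:
        raise ValueError("n_targets must be positive")
    rng = config._rng(_STREAM_MATRIX)
    bg = config.effective_background_rate
    target_ids = [f"G{j + 1:04d}" for j in range(config.n_targets)]
    signal = target_ids[: config.n_signal_targets]
    classes = [1] * config.n_oral + [0] * config.n_cancer + [-1] * config.n_other
    record_ids = [f"REC{i + 1:04d}" for i in range(len(classes))]
    presence = (rng.random((len(classes), config.n_targets)) < bg).astype(np.uint8)
    for i, cls in enumerate(classes):
        if cls == 1 and config.n_signal_targets:
            hit = rng.random(config.n_signal_targets) < config.signal_strength
            presence[i, : config.n_signal_targets] |= hit.astype(np.uint8)
    if config.include_prior_instance:
        record_ids.append("PRIOR0001")
        classes.append(1)
        prior = (np.arange(config.n_targets) < config.n_signal_targets).astype(np.uint8)
        presence = np.vstack([presence, prior])
    matrix = TrainingMatrix(record_ids=record_ids,
                            classes=np.array(classes, dtype=np.int64),
                            presence=presence, target_ids=target_ids)
    return matrix, list(signal)


# ---------------------------------------------------------------------------
# Interaction and bioassay tables
# ---------------------------------------------------------------------------

_CHANNELS = ("experimental", "database", "textmining", "predicted")


def generate_interaction_table(config: SyntheticConfig) -> pd.DataFrame:
    """Chemical-protein interaction records with one evidence channel each.

    Most records pair a random compound with a random protein under a
    channel drawn from ``channel_proportions``.  A planted fraction of the
    compound universe (``signal_compound_fraction``, the ground-truth
    oral-cancer-like screening hits) additionally receives experimental-
    channel interactions with every signal protein (the first
    ``n_signal_targets`` ids), so downstream scoring has recoverable truth.
    """
    rng = config._rng(_STREAM_INTERACTIONS)
    n = config.n_interactions
    if n == 0:
        return pd.DataFrame(columns=["compound_id", "protein_id", "channel", "score"])
    n_universe = max(n // 4, 1)
    channels = rng.choice(_CHANNELS, size=n, p=config.channel_proportions)
    compounds = [f"CID{int(i):05d}" for i in rng.integers(0, n_universe, size=n)]
    proteins = [f"ENSP{int(j):05d}" for j in rng.integers(0, config.n_targets or 1, size=n)]
    scores = rng.integers(150, 1000, size=n)
    df = pd.DataFrame({"compound_id": compounds, "protein_id": proteins,
                       "channel": channels, "score": scores})
    n_planted = int(config.signal_compound_fraction * n_universe)
    if n_planted and config.n_signal_targets:
        planted = rng.choice(n_universe, size=n_planted, replace=False)
        extra = pd.DataFrame([
            {"compound_id": f"CID{int(i):05d}", "protein_id": f"ENSP{j:05d}",
             "channel": "experimental", "score": 900}
            for i in sorted(planted) for j in range(config.n_signal_targets)])
        df = pd.concat([df, extra], ignore_index=True)
    return df


def generate_bioassay_records(config: SyntheticConfig) -> pd.DataFrame:
    """IC50/GI50 assay records with ground-truth activity flags.

    Values are drawn log-uniformly either below the relevant activity
    cutoff (IC50: 1 uM for target association, GI50: 50 uM) or above it,
    then expressed in a randomly chosen configured unit dialect; the
    ``true_active`` column records the construction-time flag.
    """
    rng = config._rng(_STREAM_BIOASSAYS)
    n = config.n_assays
    cols = ["compound_id", "target_id", "assay_type", "value", "unit", "true_active"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for k in range(n):
        assay = "IC50" if rng.random() < 0.5 else "GI50"
        cutoff = IC50_CUTOFF_UM if assay == "IC50" else GI50_CUTOFF_UM
        active = bool(rng.random() < 0.5)
        if active:
            value_um = cutoff * 10 ** float(rng.uniform(-2.0, 0.0))
        else:
            value_um = cutoff * 10 ** float(rng.uniform(0.05, 2.0))
        unit = str(rng.choice(config.unit_dialects))
        value = value_um * 1000.0 if unit.lower().startswith("n") else value_um
        if value <= 0:
            raise RuntimeError("generated a non-positive assay value")
        rows.append({
            "compound_id": f"CID{int(rng.integers(0, max(n // 2, 1))):05d}",
            "target_id": f"G{int(rng.integers(1, config.n_targets + 1)):04d}",
            "assay_type": assay,
            "value": value,
            "unit": unit,
            "true_active": active,
        })
    return pd.DataFrame(rows, columns=cols)
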