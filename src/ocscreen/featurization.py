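"""Binary functional-group featurization of compound libraries.

Compounds are described by the presence/absence of named substructures
(functional groups and common drug metals) given as SMARTS patterns in an
ordered catalog.  Each compound becomes a binary vector whose i-th bit says
whether catalog pattern i matches the molecule; a labelled set of such
vectors forms an M x N feature matrix (M compounds, N catalog entries) that
feeds the activity classifier.

Matrices are serialized in the sparse ``<label> <index>:<value> ...`` text
format used by SVM tools: 1-based ascending indices, zero features omitted,
one newline-terminated line per compound.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "SmartsCatalog",
    "FeatureMatrix",
    "SmilesParseError",
    "load_smarts_catalog",
    "default_catalog",
    "undesirable_group_catalog",
    "match_substructure",
    "featurize_compound",
    "featurize_table",
    "prune_uninformative_patterns",
    "write_sparse_matrix",
    "read_sparse_matrix",
    "read_smiles_table",
    "write_smiles_table",
    "canonical_smiles",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the compound id."""

    def __init__(self, smiles: str, compound_id: str | None = None):
        self.smiles = smiles
        self.compound_id = compound_id
        ident = f" (compound {compound_id})" if compound_id else ""
        super().__init__(f"unparseable SMILES{ident}: {smiles!r}")


def _mol_from_smiles(smiles: str, compound_id: str | None = None) -> Chem.Mol:
    """Parse and sanitize a SMILES string with RDKit's default aromaticity model.

    Canonicalization + aromaticity perception happen here once, so kekulized
    and aromatic notations of the same molecule featurize identically.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, compound_id)
    return mol


def canonical_smiles(smiles: str, compound_id: str | None = None) -> str:
    """Return RDKit canonical SMILES (used for dedup and audit columns)."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles, compound_id))


@dataclass(frozen=True)
class SmartsCatalog:
    """Ordered list of (name, SMARTS) substructure patterns.

    The catalog order defines the feature space: feature index = 1-based
    catalog position.  Names are unique; every pattern compiles.
    """

    names: tuple[str, ...]
    patterns: tuple[str, ...]
    _compiled: tuple[Chem.Mol, ...] = field(repr=False, compare=False, default=())

    def __post_init__(self):
        if len(self.names) != len(self.patterns):
            raise ValueError("names and patterns must have equal length")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate pattern names: {dupes}")
        compiled = []
        for name, patt in zip(self.names, self.patterns):
            query = Chem.MolFromSmarts(patt)
            if query is None:
                raise ValueError(f"invalid SMARTS for {name!r}: {patt!r}")
            compiled.append(query)
        object.__setattr__(self, "_compiled", tuple(compiled))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SmartsCatalog":
        names, patterns = zip(*pairs) if (pairs := list(pairs)) else ((), ())
        return cls(tuple(names), tuple(patterns))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.names, self.patterns))

    def index(self, name: str) -> int:
        """0-based position of a named pattern."""
        return self.names.index(name)

    def compiled(self) -> tuple[Chem.Mol, ...]:
        return self._compiled

    def subset(self, keep: Sequence[int]) -> "SmartsCatalog":
        return SmartsCatalog(
            tuple(self.names[i] for i in keep),
            tuple(self.patterns[i] for i in keep),
        )

    def fingerprint(self) -> str:
        """Stable hash of the catalog contents, stored with trained models."""
        import hashlib

        h = hashlib.sha256()
        for name, patt in self:
            h.update(name.encode())
            h.update(b"\t")
            h.update(patt.encode())
            h.update(b"\n")
        return h.hexdigest()


def load_smarts_catalog(path: str | Path) -> SmartsCatalog:
    """Read a two-column (FunctionalGroup, SMARTS) TSV into a catalog.

    A header line whose first field is ``FunctionalGroup`` is skipped.
    Malformed SMARTS raise with the offending 1-based line number; an empty
    file yields an empty catalog with a warning.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name, patt = fields[0].strip(), fields[1].strip()
            if lineno == 1 and name.lower() in {"functionalgroup", "funtionalgroup", "name"}:
                continue
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pattern name {name!r}")
            seen.add(name)
            if Chem.MolFromSmarts(patt) is None:
                raise ValueError(f"{path}:{lineno}: invalid SMARTS {patt!r} for {name!r}")
            pairs.append((name, patt))
    if not pairs:
        warnings.warn(f"empty SMARTS catalog loaded from {path}", stacklevel=2)
    return SmartsCatalog.from_pairs(pairs)


def _packaged_catalog(resource: str) -> SmartsCatalog:
    with resources.as_file(resources.files("ocscreen.data").joinpath(resource)) as p:
        return load_smarts_catalog(p)


def default_catalog() -> SmartsCatalog:
    """The curated default functional-group + drug-metal catalog shipped in-repo."""
    return _packaged_catalog("functional_groups.tsv")


def undesirable_group_catalog() -> SmartsCatalog:
    """Default medicinal-chemistry undesirable-group catalog."""
    return _packaged_catalog("undesirable_groups.tsv")


def match_substructure(smiles: str, pattern: str | Chem.Mol,
                       compound_id: str | None = None) -> bool:
    """True iff the SMARTS pattern matches the molecule at least once."""
    mol = _mol_from_smiles(smiles, compound_id)
    query = Chem.MolFromSmarts(pattern) if isinstance(pattern, str) else pattern
    if query is None:
        raise ValueError(f"invalid SMARTS pattern: {pattern!r}")
    return mol.HasSubstructMatch(query)


def featurize_compound(smiles: str, catalog: SmartsCatalog,
                       compound_id: str | None = None) -> np.ndarray:
    """Binary feature vector of a single compound over the catalog (uint8)."""
    mol = _mol_from_smiles(smiles, compound_id)
    bits = np.zeros(len(catalog), dtype=np.uint8)
    for i, query in enumerate(catalog.compiled()):
        if mol.HasSubstructMatch(query):
            bits[i] = 1
    return bits


@dataclass
class FeatureMatrix:
    """M x N binary feature matrix with per-row compound ids and class labels."""

    compound_ids: list[str]
    bits: np.ndarray  # shape (M, N), values in {0, 1}
    labels: np.ndarray  # shape (M,), integer class labels

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D array")
        if len(self.compound_ids) != self.bits.shape[0] or len(self.labels) != self.bits.shape[0]:
            raise ValueError("compound_ids, bits and labels must agree on row count")
        if self.bits.size and not np.isin(self.bits, (0, 1)).all():
            raise ValueError("feature values must be binary")

    @property
    def n_compounds(self) -> int:
        return self.bits.shape[0]

    @property
    def n_features(self) -> int:
        return self.bits.shape[1]


def featurize_table(records: Iterable[tuple[str, str]], catalog: SmartsCatalog,
                    labels: Iterable[int] | None = None,
                    on_error: str = "skip") -> FeatureMatrix:
    """Featurize (compound_id, smiles) records into a FeatureMatrix.

    ``on_error='skip'`` logs and drops unparseable SMILES (batch mode);
    ``on_error='raise'`` propagates, for single-compound use.
    """
    if on_error not in ("skip", "raise"):
        raise ValueError("on_error must be 'skip' or 'raise'")
    records = list(records)
    label_list = [0] * len(records) if labels is None else list(labels)
    if len(label_list) != len(records):
        raise ValueError("labels length must match records")
    ids, rows, kept_labels = [], [], []
    n_skipped = 0
    for (cid, smi), lab in zip(records, label_list):
        try:
            rows.append(featurize_compound(smi, catalog, compound_id=cid))
        except SmilesParseError:
            if on_error == "raise":
                raise
            n_skipped += 1
            logger.warning("skipping unparseable SMILES for compound %s", cid)
            continue
        ids.append(cid)
        kept_labels.append(lab)
    if n_skipped:
        logger.warning("featurize_table skipped %d unparseable compounds", n_skipped)
    bits = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, len(catalog)), dtype=np.uint8)
    return FeatureMatrix(ids, bits, np.array(kept_labels, dtype=np.int64))


def prune_uninformative_patterns(
    matrix: FeatureMatrix, catalog: SmartsCatalog
) -> tuple[FeatureMatrix, SmartsCatalog, dict[int, int]]:
    """Drop catalog columns absent from every compound in the matrix.

    Patterns never observed in the data carry no information for the
    classifier and are removed; the catalog is reindexed to the surviving
    columns.  Returns (pruned matrix, pruned catalog, old->new 0-based
    column index map).
    """
    if matrix.n_features != len(catalog):
        raise ValueError("matrix width does not match catalog size")
    keep = [j for j in range(matrix.n_features) if matrix.bits[:, j].any()]
    if not keep:
        warnings.warn("all catalog patterns are absent from the data; catalog emptied",
                      stacklevel=2)
    mapping = {old: new for new, old in enumerate(keep)}
    pruned = FeatureMatrix(
        list(matrix.compound_ids),
        matrix.bits[:, keep] if keep else np.zeros((matrix.n_compounds, 0), dtype=np.uint8),
        matrix.labels.copy(),
    )
    return pruned, catalog.subset(keep), mapping


def write_sparse_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write ``<label> <index>:<value>`` lines, 1-based ascending indices."""
    with open(path, "w") as fh:
        for row, label in zip(matrix.bits, matrix.labels):
            nz = np.flatnonzero(row)
            parts = [str(int(label))] + [f"{j + 1}:{int(row[j])}" for j in nz]
            fh.write(" ".join(parts) + "\n")


def read_sparse_matrix(path: str | Path, n_features: int | None = None) -> FeatureMatrix:
    """Read the sparse text format back into a dense FeatureMatrix.

    Indices must be 1-based and strictly ascending within each line.  Row ids
    are synthesized as ``row<k>`` (the format stores no compound ids).
    """
    labels: list[int] = []
    rows: list[dict[int, int]] = []
    max_idx = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            labels.append(int(parts[0]))
            entries: dict[int, int] = {}
            prev = 0
            for tok in parts[1:]:
                idx_s, val_s = tok.split(":")
                idx = int(idx_s)
                if idx <= prev:
                    raise ValueError(
                        f"{path}:{lineno}: indices must be ascending and 1-based "
                        f"(saw {idx} after {prev})")
                prev = idx
                entries[idx] = int(val_s)
                max_idx = max(max_idx, idx)
            rows.append(entries)
    width = n_features if n_features is not None else max_idx
    bits = np.zeros((len(rows), width), dtype=np.uint8)
    for i, entries in enumerate(rows):
        for idx, val in entries.items():
            if idx > width:
                raise ValueError(f"feature index {idx} exceeds declared width {width}")
            bits[i, idx - 1] = val
    ids = [f"row{k}" for k in range(len(rows))]
    return FeatureMatrix(ids, bits, np.array(labels, dtype=np.int64))


def read_smiles_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi table (SMILES<TAB>ID per line, '#' comments) as (id, smiles)."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected SMILES and identifier")
            out.append((fields[1], fields[0]))
    return out


def write_smiles_table(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, smiles) records as SMILES<TAB>ID lines."""
    with open(path, "w") as fh:
        for cid, smi in records:
            fh.write(f"{smi}\t{cid}\n")
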