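"""End-to-end orchestration: featurize -> predict -> assemble targets ->
merge -> weight -> score -> screen -> annotate.

``run_pipeline`` executes the whole process-flow on either user-supplied
input files or the synthetic generators, writing every stage output plus a
provenance manifest (seed, parameters, SHA-256 of each output) so reruns
are verifiable and any stage can be re-entered from the previous stage's
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classifier as clf
from . import featurization as feat
from . import pls
from . import synthetic as syn
from . import targets as tgt

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and tuning knobs for a full run.

    Any input path left as None is produced by the synthetic generators
    under ``synthetic``; thresholds default to the screening conventions
    (IC50 <= 1 uM target association, GI50 <= 50 uM activity, TPSA >= 140,
    inclusive score cutoff derived from the oral-cancer class mean).
    """

    out_dir: Path
    seed: int = 0
    catalog_path: Path | None = None
    compounds_path: Path | None = None  # .smi screening library
    interactions_path: Path | None = None
    bioassays_path: Path | None = None
    training_matrix_path: Path | None = None
    bad_groups_path: Path | None = None
    svm_params: clf.SvmParams | None = None  # None -> reference defaults
    grid: clf.GridSpec | None = None  # set to run a grid search before training
    ic50_um: float = 1.0
    gi50_um: float = 50.0
    tpsa_threshold: float = 140.0
    cutoff_override: float | None = None
    cutoff_decimals: int = 2
    chunk_size: int = clf.DEFAULT_CHUNK_SIZE
    synthetic: syn.SyntheticConfig | None = None

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        for name in ("ic50_um", "gi50_um", "tpsa_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("catalog_path", "compounds_path", "interactions_path",
                     "bioassays_path", "training_matrix_path", "bad_groups_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


@dataclass
class PipelineResult:
    manifest: dict
    selected: list[pls.OCScoreRecord]
    report: list[ann.AnnotationRecord]
    cutoff: float


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    counts: dict[str, int] = {}

    syn_cfg = config.synthetic or syn.SyntheticConfig(seed=config.seed)

    # --- stage: inputs ------------------------------------------------------
    if config.catalog_path is not None:
        catalog = feat.load_smarts_catalog(config.catalog_path)
    else:
        catalog = syn.synthetic_group_catalog()

    if config.compounds_path is not None:
        screen_records = feat.read_smiles_table(config.compounds_path)
        train_lib = syn.generate_compound_library(syn_cfg, catalog)
    else:
        # one library trains the classifier, a second (distinct stream via a
        # shifted config seed) is the screening universe referenced by the
        # interaction/bioassay compound ids
        train_lib = syn.generate_compound_library(syn_cfg, catalog)
        n_universe = max(syn_cfg.n_interactions // 4, 1)
        universe_cfg = syn.SyntheticConfig(seed=syn_cfg.seed + 1,
                                           n_compounds=n_universe,
                                           n_targets=syn_cfg.n_targets)
        universe = syn.generate_compound_library(universe_cfg, catalog)
        screen_records = [(f"CID{i:05d}", smi) for i, smi in enumerate(universe.smiles)]
        p = out / "screening_library.smi"
        feat.write_smiles_table(screen_records, p)
        written["screening_library"] = p
    smiles_by_id = dict(screen_records)
    counts["screening_compounds"] = len(screen_records)

    interactions = (pd.read_csv(config.interactions_path, sep="\t")
                    if config.interactions_path is not None
                    else syn.generate_interaction_table(syn_cfg))
    bioassays = (pd.read_csv(config.bioassays_path, sep="\t")
                 if config.bioassays_path is not None
                 else syn.generate_bioassay_records(syn_cfg))

    # --- stage: featurize + train classifier -------------------------------
    train_matrix = feat.featurize_table(train_lib.records(), catalog,
                                        labels=train_lib.labels)
    p = out / "training_features.dat"
    feat.write_sparse_matrix(train_matrix, p)
    written["training_features"] = p

    params = config.svm_params
    if config.grid is not None:
        params, surface = clf.grid_search(train_matrix, config.grid, seed=config.seed)
        p = out / "grid_surface.tsv"
        surface.to_csv(p, sep="\t", index=False)
        written["grid_surface"] = p
    model = clf.train_final(train_matrix, params, catalog)
    p = out / "activity_model.joblib"
    clf.save_model(model, p)
    written["activity_model"] = p

    # --- stage: predict activity over the screening library ----------------
    labels = clf.predict_activity(model, screen_records, catalog,
                                  chunk_size=config.chunk_size)
    pred = pd.DataFrame({"compound_id": [cid for cid, _ in screen_records],
                         "predicted": labels})
    p = out / "predictions.tsv"
    pred.to_csv(p, sep="\t", index=False)
    written["predictions"] = p
    active_ids = set(pred.loc[pred["predicted"] == 1, "compound_id"])
    counts["predicted_active"] = len(active_ids)

    # --- stage: assemble target profiles ------------------------------------
    kept = tgt.filter_interaction_channels(interactions)
    counts["interactions_kept"] = len(kept)
    mapping = pd.DataFrame({
        "source_id": [f"ENSP{j:05d}" for j in range(syn_cfg.n_targets)],
        "gene_id": [f"G{j + 1:04d}" for j in range(syn_cfg.n_targets)],
    }) if config.interactions_path is None else None
    if mapping is not None:
        kept = tgt.map_protein_ids(kept, mapping)
    kept = kept[kept["compound_id"].astype(str).isin(active_ids)]
    profiles = tgt.profiles_from_interactions(kept, smiles_by_id)

    assay_targets = tgt.targets_from_bioassays(bioassays, threshold_um=config.ic50_um)
    by_id = {pr.compound_id: pr for pr in profiles}
    for cid, extra in assay_targets.items():
        if cid not in active_ids or cid not in smiles_by_id:
            continue
        if cid in by_id:
            old = by_id[cid]
            by_id[cid] = tgt.CompoundTargetProfile(
                cid, old.smiles, old.targets | frozenset(extra), source=old.source)
        else:
            by_id[cid] = tgt.CompoundTargetProfile(
                cid, smiles_by_id[cid], frozenset(extra), source="chembl-like")
    profiles = list(by_id.values())
    counts["profiles"] = len(profiles)

    merged = tgt.dedup_and_merge(profiles)
    counts["merged_profiles"] = len(merged)
    p = out / "merged_profiles.tsv"
    tgt.write_profiles(merged, p)
    written["merged_profiles"] = p

    # --- stage: PLS weights + OC_Score ---------------------------------------
    if config.training_matrix_path is not None:
        tmatrix = pls.read_training_matrix(config.training_matrix_path)
        signal = []
    else:
        tmatrix, signal = syn.generate_training_matrix(syn_cfg)
    p = out / "training_matrix.tsv"
    pls.write_training_matrix(tmatrix, p)
    written["training_matrix"] = p

    fit = pls.fit_target_weights(tmatrix)
    p = out / "target_weights.tsv"
    pls.write_target_weights(fit.weights, p)
    written["target_weights"] = p

    class1_scores = []
    for i in range(tmatrix.n_records):
        if tmatrix.classes[i] != 1:
            continue
        row_targets = [tmatrix.target_ids[j]
                       for j in np.flatnonzero(tmatrix.presence[i])]
        class1_scores.append(pls.oc_score(row_targets, fit.weights,
                                          compound_id=tmatrix.record_ids[i],
                                          group="oral_cancer"))
    cutoff = (config.cutoff_override if config.cutoff_override is not None
              else pls.derive_cutoff(class1_scores, decimals=config.cutoff_decimals))

    scored = [pls.oc_score(sorted(pr.targets), fit.weights, compound_id=pr.compound_id,
                           group="predicted_active") for pr in merged]
    scores_df = pd.DataFrame({"compound_id": [s.compound_id for s in scored],
                              "oc_score": [s.oc_score for s in scored]})
    p = out / "oc_scores.tsv"
    scores_df.to_csv(p, sep="\t", index=False)
    written["oc_scores"] = p

    selected = pls.screen_compounds(scored, cutoff)
    counts["selected"] = len(selected)
    p = out / "selected_compounds.tsv"
    scores_df[scores_df["oc_score"] >= cutoff].to_csv(p, sep="\t", index=False)
    written["selected_compounds"] = p

    # --- stage: annotation ----------------------------------------------------
    bad_groups = (feat.load_smarts_catalog(config.bad_groups_path)
                  if config.bad_groups_path is not None
                  else feat.undesirable_group_catalog())
    merged_smiles = {pr.compound_id: pr.smiles for pr in merged}
    report = ann.build_report(selected, merged_smiles, assays=bioassays,
                              bad_groups=bad_groups,
                              gi50_cutoff_um=config.gi50_um,
                              tpsa_threshold=config.tpsa_threshold)
    p = out / "annotation_report.csv"
    ann.write_report(report, p)
    written["annotation_report"] = p

    manifest = {
        "seed": config.seed,
        "cutoff": cutoff,
        "svm_params": {"C": model.params.C, "gamma": model.params.gamma},
        "thresholds": {"ic50_um": config.ic50_um, "gi50_um": config.gi50_um,
                       "tpsa": config.tpsa_threshold},
        "synthetic": asdict(syn_cfg) if (config.compounds_path is None) else None,
        "signal_targets": signal,
        "counts": counts,
        "outputs": {name: {"path": str(path), "sha256": _sha256(path)}
                    for name, path in written.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return PipelineResult(manifest=manifest, selected=selected, report=report,
                          cutoff=cutoff)
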