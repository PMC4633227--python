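"""Profile assembly, Tanimoto fingerprints and duplicate merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem, DataStructs

from ocscreen.targets import (ALLOWED_CHANNELS, CompoundTargetProfile,
                              compute_fingerprint, dedup_and_merge,
                              filter_interaction_channels, map_protein_ids,
                              parse_concentration_um, tanimoto,
                              targets_from_bioassays)


def profile(cid, smiles, targets, **kw):
    return CompoundTargetProfile(cid, smiles, frozenset(map(str, targets)), **kw)


class TestChannelFilter:
    def test_only_reliable_channels_survive(self):
        df = pd.DataFrame({
            "compound_id": ["a", "b", "c", "d"],
            "protein_id": ["p1", "p2", "p3", "p4"],
            "channel": ["experimental", "database", "textmining", "predicted"],
            "score": [900, 800, 700, 600],
        })
        kept = filter_interaction_channels(df)
        assert sorted(kept["channel"]) == ["database", "experimental"]

    def test_unknown_channel_dropped_with_warning(self):
        df = pd.DataFrame({"compound_id": ["a"], "protein_id": ["p"],
                           "channel": ["rumor"], "score": [1]})
        with pytest.warns(UserWarning, match="unknown"):
            kept = filter_interaction_channels(df)
        assert kept.empty

    def test_empty_input_empty_output(self):
        df = pd.DataFrame(columns=["compound_id", "protein_id", "channel", "score"])
        assert filter_interaction_channels(df).empty

    def test_binomial_retention_rate(self):
        rng = np.random.default_rng(0)
        channels = rng.choice(["experimental", "database", "textmining", "predicted"],
                              size=1000)
        df = pd.DataFrame({"compound_id": "c", "protein_id": "p",
                           "channel": channels, "score": 1})
        kept = filter_interaction_channels(df)
        # 50% retention expected; 4 sigma of Binomial(1000, .5) is ~63
        assert abs(len(kept) - 500) < 4 * np.sqrt(1000 * 0.25)


class TestBioassayAssociation:
    @pytest.mark.parametrize("value,unit,associated", [
        (500, "nM", True),
        (1000, "nM", True),  # boundary inclusive: 1000 nM == 1 uM
        (1.0, "uM", True),
        (2, "uM", False),
        (1001, "nM", False),
        (0.5, "µM", True),  # micro-sign dialect
    ])
    def test_ic50_threshold(self, value, unit, associated):
        df = pd.DataFrame([{"compound_id": "c1", "target_id": "g1",
                            "assay_type": "IC50", "value": value, "unit": unit}])
        out = targets_from_bioassays(df)
        assert ("c1" in out and "g1" in out["c1"]) is associated

    def test_unknown_unit_skipped_with_warning(self):
        df = pd.DataFrame([{"compound_id": "c1", "target_id": "g1",
                            "assay_type": "IC50", "value": 0.1, "unit": "mg/kg"}])
        with pytest.warns(UserWarning, match="unknown unit"):
            assert targets_from_bioassays(df) == {}

    def test_non_ic50_assays_ignored_by_default(self):
        df = pd.DataFrame([{"compound_id": "c1", "target_id": "g1",
                            "assay_type": "GI50", "value": 0.1, "unit": "uM"}])
        assert targets_from_bioassays(df) == {}

    @pytest.mark.parametrize("unit,factor", [("uM", 1.0), ("nM", 1e-3),
                                             ("um", 1.0), ("nm", 1e-3)])
    def test_unit_normalization(self, unit, factor):
        assert parse_concentration_um(10.0, unit) == pytest.approx(10.0 * factor)

    def test_unrecognized_unit_returns_none(self):
        assert parse_concentration_um(1.0, "mM") is None


class TestTanimoto:
    def test_identical_fingerprints(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        assert tanimoto(a, a) == 1.0

    def test_disjoint_fingerprints(self):
        assert tanimoto(np.array([1, 1, 0, 0], dtype=bool),
                        np.array([0, 0, 1, 1], dtype=bool)) == 0.0

    def test_hand_counted_example(self):
        # intersection 1 bit, union 3 bits
        assert tanimoto(np.array([1, 1, 0, 0], dtype=bool),
                        np.array([1, 0, 1, 0], dtype=bool)) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros(8, dtype=bool)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(np.zeros(4, dtype=bool), np.zeros(8, dtype=bool))

    @pytest.mark.parametrize("smi_a,smi_b", [
        ("CCO", "CCN"), ("c1ccccc1O", "c1ccccc1N"), ("CC(=O)O", "CCC(=O)O"),
    ])
    def test_agrees_with_rdkit_on_real_fingerprints(self, smi_a, smi_b):
        ours = tanimoto(compute_fingerprint(smi_a), compute_fingerprint(smi_b))
        bv_a = Chem.RDKFingerprint(Chem.MolFromSmiles(smi_a), maxPath=7, fpSize=1024)
        bv_b = Chem.RDKFingerprint(Chem.MolFromSmiles(smi_b), maxPath=7, fpSize=1024)
        assert ours == pytest.approx(DataStructs.TanimotoSimilarity(bv_a, bv_b))


class TestDedupAndMerge:
    def test_worked_three_way_merge(self):
        # same structure under three ids; targets union to 1,2,3,5,6,8,9
        profiles = [
            profile("A", "CCO", {1, 2, 3}),
            profile("B", "OCC", {2, 5, 6, 8}),
            profile("C", "C(O)C", {3, 9}),
        ]
        merged = dedup_and_merge(profiles)
        assert len(merged) == 1
        assert merged[0].compound_id == "A"
        assert merged[0].targets == frozenset(map(str, {1, 2, 3, 5, 6, 8, 9}))
        assert merged[0].merged_from == ("A", "B", "C")

    def test_similar_but_not_identical_stay_separate(self):
        profiles = [profile("A", "CCCCO", {1}), profile("B", "CCCCCO", {2})]
        a, b = compute_fingerprint("CCCCO"), compute_fingerprint("CCCCCO")
        assert 0 < tanimoto(a, b) < 1  # high similarity is not identity
        assert len(dedup_and_merge(profiles)) == 2

    def test_singleton_unchanged(self):
        p = profile("A", "CCO", {1})
        assert dedup_and_merge([p]) == [p]

    def test_unparseable_smiles_passes_through_with_warning(self):
        profiles = [profile("A", "CCO", {1}), profile("bad", "((((", {2}),
                    profile("B", "OCC", {3})]
        with pytest.warns(UserWarning, match="unparseable"):
            merged = dedup_and_merge(profiles)
        ids = {m.compound_id for m in merged}
        assert "bad" in ids and len(merged) == 2

    def test_idempotent(self):
        profiles = [profile("A", "CCO", {1}), profile("B", "OCC", {2}),
                    profile("C", "c1ccccc1", {3})]
        once = dedup_and_merge(profiles)
        assert dedup_and_merge(once) == once

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_union_find_oracle(self, seed):
        """Random <=50-profile instances versus an O(n^2) pairwise oracle."""
        rng = np.random.default_rng(seed)
        pool = ["CCO", "OCC", "c1ccccc1", "C1=CC=CC=C1", "CC(=O)O", "OC(C)=O",
                "CCN", "NCC", "CCCC", "CCOC", "CS", "CCS"]
        n = int(rng.integers(1, 51))
        profiles = [profile(f"P{i}", pool[rng.integers(len(pool))],
                            set(rng.integers(0, 20, size=rng.integers(1, 5))))
                    for i in range(n)]
        merged = dedup_and_merge(profiles)

        # oracle: transitive closure over pairwise Tanimoto == 1
        fps = [compute_fingerprint(p.smiles) for p in profiles]
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if tanimoto(fps[i], fps[j]) == 1.0:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        expected = {
            profiles[min(members)].compound_id:
                frozenset().union(*(profiles[i].targets for i in members))
            for members in groups.values()
        }
        got = {m.compound_id: m.targets for m in merged}
        assert got == expected
        # global target union is conserved and no output pair is identical
        assert frozenset().union(*(m.targets for m in merged)) == \
            frozenset().union(*(p.targets for p in profiles))
        out_fps = [compute_fingerprint(m.smiles) for m in merged]
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                assert tanimoto(out_fps[i], out_fps[j]) < 1.0


class TestIdMapping:
    def test_present_ids_translated_absent_dropped(self):
        records = pd.DataFrame({"compound_id": ["c1", "c2"],
                                "protein_id": ["ENSP1", "ENSP404"]})
        mapping = pd.DataFrame({"source_id": ["ENSP1"], "gene_id": ["111"]})
        out = map_protein_ids(records, mapping)
        assert list(out["gene_id"]) == ["111"]
        assert list(out["compound_id"]) == ["c1"]

    def test_duplicate_mapping_rows_do_not_duplicate_records(self):
        records = pd.DataFrame({"compound_id": ["c1"], "protein_id": ["ENSP1"]})
        mapping = pd.DataFrame({"source_id": ["ENSP1", "ENSP1"],
                                "gene_id": ["111", "111"]})
        out = map_protein_ids(records, mapping)
        # brute-force join after de-dup gives exactly one row
        assert len(out) == 1
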