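"""Curation, deduplication, scaffold analysis and splitting."""

import numpy as np
import pytest

from pcfkit import datakit
from pcfkit.datakit import ChemicalRecord, Dataset, SplitSpec
from pcfkit.featurize import InvalidStructureError

from conftest import random_smiles_pool


class TestCuration:
    def test_toy_inventory_keeps_exactly_the_four_organics(self, curation_fixture):
        res = datakit.curate(curation_fixture)
        assert res.dataset.smiles == ["CCO", "c1ccccc1", "CCOC(C)=O", "Nc1ccccc1"]
        rules = dict(res.exclusions)
        assert rules == {
            "CC(=O)[O-].[Na+]": "metal",
            "[Fe](C)(C)": "metal",
            "CC.OC": "mixture",
            "O": "inorganic",
            "Cc1ccccc1": "low_purity",
            "X#Y!": "parse_failure",
        }

    def test_empty_input_gives_empty_dataset(self):
        res = datakit.curate([])
        assert len(res.dataset) == 0 and res.exclusions == []

    def test_unset_purity_is_retained(self):
        res = datakit.curate([ChemicalRecord("CCN", 1.0, purity=None)])
        assert len(res.dataset) == 1

    def test_polymer_marker_excluded(self):
        res = datakit.curate([ChemicalRecord("*CC*", 1.0)])
        assert res.exclusions == [("*CC*", "polymer")]

    def test_curation_is_idempotent(self, curation_fixture):
        once = datakit.curate(curation_fixture).dataset
        twice = datakit.curate(once.records).dataset
        assert once.smiles == twice.smiles


class TestMergeDuplicates:
    def test_pcf_values_are_averaged(self):
        ds = datakit.curate([
            ChemicalRecord("CCO", 2.0, source="a"),
            ChemicalRecord("OCC", 4.0, source="b"),  # same molecule
        ]).dataset
        merged = datakit.merge_duplicates(ds)
        assert len(merged) == 1
        assert merged.records[0].pcf == pytest.approx(3.0)
        assert merged.records[0].source == "a;b"

    def test_three_copies_average(self):
        ds = datakit.curate([ChemicalRecord("CCO", v) for v in (1.0, 1.0, 7.0)]).dataset
        merged = datakit.merge_duplicates(ds)
        assert merged.records[0].pcf == pytest.approx(3.0)

    def test_all_unique_dataset_unchanged(self):
        ds = datakit.curate([
            ChemicalRecord("CCO", 1.0), ChemicalRecord("CCN", 2.0),
        ]).dataset
        merged = datakit.merge_duplicates(ds)
        assert merged.smiles == ds.smiles

    def test_merge_conserves_identity(self, curation_fixture):
        ds = datakit.curate(curation_fixture).dataset
        merged = datakit.merge_duplicates(ds)
        assert set(merged.smiles) <= set(ds.smiles)


class TestMurckoScaffold:
    @pytest.mark.parametrize("smiles,scaffold", [
        ("C=CC(=O)OCCCC", ""),            # butyl acrylate: acyclic
        ("OCCN1CCNCC1", "C1CNCCN1"),      # side chains pruned to piperazine
        ("c1ccccc1", "c1ccccc1"),          # a bare ring is its own scaffold
    ])
    def test_known_scaffolds(self, smiles, scaffold):
        assert datakit.murcko_scaffold(smiles) == scaffold

    def test_parse_failure_raises(self):
        with pytest.raises(InvalidStructureError):
            datakit.murcko_scaffold("not-a-molecule")

    def test_scaffold_counting(self):
        ds = Dataset([ChemicalRecord(s, 1.0)
                      for s in ("c1ccccc1", "Cc1ccccc1", "CCO")])
        assert datakit.count_unique_scaffolds(ds) == 2
        assert datakit.count_unique_scaffolds(Dataset([])) == 0
        copies = Dataset([ChemicalRecord("c1ccccc1", 1.0)] * 5)
        assert datakit.count_unique_scaffolds(copies) == 1


def _dataset(n, seed=0):
    smiles = random_smiles_pool(n, seed=seed)
    ds = Dataset([ChemicalRecord(s, 1.0) for s in smiles])
    return datakit.merge_duplicates(datakit.curate(ds.records).dataset)


class TestSplit:
    def test_random_split_sizes_follow_fractions(self):
        ds = Dataset([ChemicalRecord("CCO", 1.0, name=str(i)) for i in range(100)])
        tr, va, te = datakit.split(ds, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_largest_remainder_rounding(self):
        ds = Dataset([ChemicalRecord("CCO", 1.0, name=str(i)) for i in range(13)])
        tr, va, te = datakit.split(ds, SplitSpec(seed=0))
        assert len(tr) + len(va) + len(te) == 13
        assert len(tr) == 11  # 10.4 -> 11 via largest remainder (0.4 > 0.3)

    def test_split_is_exhaustive_and_disjoint(self):
        ds = _dataset(60)
        names = [r.smiles for r in ds.records]
        tr, va, te = datakit.split(ds, SplitSpec(seed=1, method="scaffold"))
        out = [r.smiles for part in (tr, va, te) for r in part.records]
        assert sorted(out) == sorted(names)

    def test_same_spec_reproduces_split(self):
        ds = _dataset(50)
        a = datakit.split(ds, SplitSpec(seed=2, repeat_index=1))
        b = datakit.split(ds, SplitSpec(seed=2, repeat_index=1))
        assert [p.smiles for p in a] == [p.smiles for p in b]

    @pytest.mark.parametrize("method", ["random", "scaffold"])
    def test_repeats_differ(self, method):
        ds = _dataset(80)
        parts = [datakit.split(ds, SplitSpec(seed=0, repeat_index=r, method=method))
                 for r in range(3)]
        train_sets = [tuple(p[0].smiles) for p in parts]
        assert len(set(train_sets)) == 3

    def test_scaffold_split_keeps_scaffolds_whole(self):
        ds = _dataset(80)
        tr, va, te = datakit.split(ds, SplitSpec(seed=0, method="scaffold"))
        s_tr = {datakit.murcko_scaffold(s) for s in tr.smiles}
        s_te = {datakit.murcko_scaffold(s) for s in te.smiles}
        assert s_tr & s_te == set()

    def test_too_few_records_raise(self):
        ds = Dataset([ChemicalRecord("CCO", 1.0)] * 2)
        with pytest.raises(ValueError):
            datakit.split(ds, SplitSpec())

    def test_fractions_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SplitSpec(method="bogus")


class TestIO:
    def test_table_round_trip(self, tmp_path):
        ds = Dataset([ChemicalRecord("CCO", 1.25, source="x", purity=0.9, name="ethanol")])
        path = tmp_path / "d.csv"
        datakit.write_table(ds, path)
        back = datakit.read_table(path)
        assert back.smiles == ["CCO"]
        assert back.records[0].pcf == pytest.approx(1.25)
        assert back.records[0].purity == pytest.approx(0.9)

    def test_invalid_record_fields_raise(self):
        with pytest.raises(ValueError):
            ChemicalRecord("CCO", -1.0)
        with pytest.raises(ValueError):
            ChemicalRecord("CCO", 1.0, purity=1.5)

    def test_sdf_input_with_named_target_property(self, tmp_path):
        from rdkit import Chem

        path = tmp_path / "mols.sdf"
        writer = Chem.SDWriter(str(path))
        for smi, pcf in (("CCO", 1.5), ("c1ccccc1", 3.25)):
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("pcf", str(pcf))
            writer.write(mol)
        writer.close()
        ds = datakit.read_sdf(path)
        assert ds.smiles == ["CCO", "c1ccccc1"]
        assert ds.targets.tolist() == [1.5, 3.25]
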