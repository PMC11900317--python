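import numpy as np
import pytest
from rdkit import Chem

from kinasepred.curation import (
    LabeledDataset,
    RawActivityRecord,
    RejectReason,
    apply_filters,
    build_family_dataset,
    curate_structures,
    curation_report,
    deduplicate,
    label_family_active,
    make_split,
    split_sizes,
    standardize_structure,
    subtract_by_structure,
)


def _kept(smiles, cid="x"):
    rec = standardize_structure(smiles, cid)
    assert rec.kept, rec.reject_reason
    return rec


class TestStandardize:
    def test_benzene_passthrough(self):
        rec = _kept("c1ccccc1")
        assert rec.smiles_std == "c1ccccc1"
        assert rec.heavy_atoms == 6

    def test_salt_stripping_and_reionization(self):
        # sodium dropped as non-largest fragment; carboxylate stays anionic
        # at pH 7.4 (frozen regression value of the rule table)
        rec = _kept("CC(=O)[O-].[Na+]")
        assert rec.smiles_std == "CC(=O)[O-]"

    def test_unclosed_ring_is_parse_error(self):
        rec = standardize_structure("C1CC")
        assert rec.status == "rejected"
        assert rec.reject_reason == RejectReason.PARSE_ERROR

    def test_empty_string(self):
        rec = standardize_structure("")
        assert rec.reject_reason == RejectReason.PARSE_ERROR

    def test_valence_error(self):
        rec = standardize_structure("F(C)(C)C")
        assert rec.reject_reason == RejectReason.VALENCE_ERROR

    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCCCCCCC(=O)O", "CCCCCCCC(=O)[O-]"),  # carboxylic acid
            ("O=S(=O)(O)c1ccccc1", "O=S(=O)([O-])c1ccccc1"),  # sulfonic
            ("CCN", "CC[NH3+]"),  # primary aliphatic amine
            ("CN(C)c1ccccc1", "CN(C)c1ccccc1"),  # aniline stays neutral
            ("CC(=O)Nc1ccccc1", "CC(=O)Nc1ccccc1"),  # amide stays neutral
        ],
    )
    def test_reionization_rule_table(self, smiles, expected):
        assert _kept(smiles).smiles_std == expected

    def test_idempotent(self):
        first = _kept("CCN(CC)CC.Cl")
        second = _kept(first.smiles_std)
        assert second.smiles_std == first.smiles_std

    def test_canonicality_over_atom_permutations(self, rng):
        smiles = "CC(=O)Nc1ccc(O)cc1"
        ref = _kept(smiles).smiles_std
        mol = Chem.MolFromSmiles(smiles)
        n = mol.GetNumAtoms()
        for _ in range(100):
            perm = rng.permutation(n).tolist()
            shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
            assert _kept(shuffled).smiles_std == ref


class TestFilters:
    def test_disallowed_element(self):
        rec = standardize_structure("CC(C)[As](C)c1ccc(CCCCCCCCCC)cc1")
        rec = apply_filters(rec)
        assert rec.reject_reason == RejectReason.DISALLOWED_ELEMENT

    def test_too_few_heavy_atoms(self):
        rec = standardize_structure("CCCCCCCCCCCCCC")  # 14 heavy atoms
        assert rec.heavy_atoms == 14
        assert apply_filters(rec).reject_reason == RejectReason.TOO_FEW_HEAVY_ATOMS

    def test_15_heavy_atoms_kept(self):
        rec = apply_filters(standardize_structure("CCCCCCCCCCCCCCC"))
        assert rec.kept

    def test_mw_boundary_inclusive(self):
        rec = standardize_structure("C" * 40)  # C40H82, MW ~563
        rec = apply_filters(rec)
        assert rec.kept
        big = apply_filters(standardize_structure("C" * 60))  # MW ~843
        assert big.reject_reason == RejectReason.MW_TOO_HIGH

    def test_idempotence(self):
        for smiles in ["CCCCCCCCCCCCCCCC", "CCO", "c1ccccc1CCCCCCCCCCCC"]:
            rec = standardize_structure(smiles)
            once = apply_filters(rec)
            assert apply_filters(once) == once


class TestDeduplicate:
    def test_canonical_collapse(self):
        recs = [standardize_structure(s, str(i)) for i, s in enumerate(["CCO", "OCC"])]
        out = deduplicate(recs)
        assert out[0].kept
        assert out[1].reject_reason == RejectReason.DUPLICATE

    def test_empty(self):
        assert deduplicate([]) == []

    def test_three_distinct_two_repeats(self):
        smiles = ["CCO", "CCN", "CCC", "OCC", "NCC"]
        out = deduplicate([standardize_structure(s, str(i)) for i, s in enumerate(smiles)])
        assert sum(1 for r in out if r.kept) == 3
        assert [r.compound_id for r in out if r.kept] == ["0", "1", "2"]

    def test_order_stable(self):
        smiles = ["CCC", "CCO", "CCN"]
        out = deduplicate([standardize_structure(s, str(i)) for i, s in enumerate(smiles)])
        assert [r.compound_id for r in out] == ["0", "1", "2"]


class TestLabeling:
    def _rec(self, value, conf, cid="C1", atype="IC50"):
        return RawActivityRecord(cid, "CCO", "T1", atype, value, conf)

    def test_active_at_threshold(self):
        assert label_family_active([self._rec(5000, 9)]) == "active"
        assert label_family_active([self._rec(10000, 9)]) == "active"

    def test_above_threshold_excluded(self):
        assert label_family_active([self._rec(20000, 9, atype="Ki")]) == "excluded"

    def test_low_confidence_excluded(self):
        assert label_family_active([self._rec(100, 8, atype="Kd")]) == "excluded"

    def test_any_qualifying_record_suffices(self):
        recs = [self._rec(50000, 9), self._rec(100, 9)]
        assert label_family_active(recs) == "active"

    def test_empty_excluded(self):
        assert label_family_active([]) == "excluded"

    def test_mixed_compounds_rejected(self):
        with pytest.raises(ValueError):
            label_family_active([self._rec(10, 9, "A"), self._rec(10, 9, "B")])

    def test_bad_activity_type(self):
        with pytest.raises(ValueError):
            RawActivityRecord("C1", "CCO", "T1", "AC50", 100, 9)


def _labeled(smiles_list, label="active"):
    recs = [
        apply_filters(standardize_structure(s, f"c{i}"))
        for i, s in enumerate(smiles_list)
    ]
    return LabeledDataset(records=[(r, label) for r in recs])


def _pool(n, prefix="D"):
    # distinct linear hetero-ethers, all pass the filters (15-40 heavy atoms)
    out = []
    for i in range(n):
        hetero = "S" if i < 25 else "O"
        smiles = "CCCCCCC" + hetero + "C" * (8 + i % 25)
        rec = apply_filters(standardize_structure(smiles, f"{prefix}{i}"))
        assert rec.kept, (smiles, rec.reject_reason)
        out.append(rec)
    return out


class TestFamilyDataset:
    def test_balanced_by_construction(self):
        actives = _labeled(["C" * n for n in range(15, 25)])
        ds = build_family_dataset(actives, _pool(50), seed=0)
        assert len(ds) == 20
        assert ds.class_counts == (10, 10)

    def test_insufficient_pool(self):
        actives = _labeled(["C" * n for n in range(15, 25)])
        with pytest.raises(ValueError, match="shortfall"):
            build_family_dataset(actives, _pool(5), seed=0)

    def test_seed_determinism(self):
        actives = _labeled(["C" * n for n in range(15, 25)])
        pool = _pool(50)
        a = build_family_dataset(actives, pool, seed=42)
        b = build_family_dataset(actives, pool, seed=42)
        assert [r.compound_id for r, _ in a.records] == [
            r.compound_id for r, _ in b.records
        ]


class TestSplit:
    def test_exact_division(self):
        assert split_sizes(10, 0.8) == (8, 2)

    def test_paper_scale_arithmetic(self):
        assert split_sizes(118816, 0.8) == (95052, 23764)

    def test_floor_convention(self):
        assert split_sizes(11, 0.8) == (8, 3)

    def test_split_conservation_and_stratification(self, family_ds):
        split = make_split(family_ds, 0.8, seed=5)
        n = len(family_ds)
        assert len(split.train_indices) + len(split.test_indices) == n
        assert len(split.train_indices) == int(np.floor(0.8 * n))
        labels = family_ds.labels
        for c in (0, 1):
            n_c = int((labels == c).sum())
            in_train = sum(1 for i in split.train_indices if labels[i] == c)
            assert abs(in_train - 0.8 * n_c) <= 1

    def test_determinism(self, family_ds):
        a = make_split(family_ds, 0.8, seed=9)
        b = make_split(family_ds, 0.8, seed=9)
        assert a.train_indices == b.train_indices

    def test_too_small(self):
        ds = _labeled(["C" * 16])
        with pytest.raises(ValueError):
            make_split(ds, 0.8, seed=0)


class TestSubtract:
    def test_subset_gives_empty(self):
        lib = _pool(5)
        assert subtract_by_structure(lib, lib) == []

    def test_disjoint_unchanged(self):
        lib = _pool(5)
        ref = _pool(5, prefix="R")
        for r in ref:
            r.smiles_std = r.smiles_std + "x-not-real"  # force disjoint keys
        assert subtract_by_structure(lib, ref) == lib

    def test_partial_overlap(self):
        lib = _pool(5)
        ref = lib[:2]
        out = subtract_by_structure(lib, ref)
        assert len(out) == 3
        assert all(m.smiles_std not in {r.smiles_std for r in ref} for m in out)


class TestReport:
    def test_conservation(self):
        inputs = [
            ("CCO", "a"),  # too few heavy atoms
            ("C1CC", "b"),  # parse error
            ("CCCCCCCCCCCCCCCC", "c"),  # kept
            ("CCCCCCCCCCCCCCCC", "d"),  # duplicate
            ("F(C)(C)C", "e"),  # valence
        ]
        records = curate_structures(inputs)
        report = curation_report(records)
        assert report["input"] == len(inputs)
        assert report["kept"] + sum(report["rejected"].values()) == report["input"]
        assert report["rejected"]["duplicate"] == 1
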