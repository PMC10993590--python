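"""Cleaning, canonicalization, enumeration, tokenization, alerts, fixtures."""

import numpy as np
import pytest
from rdkit import Chem

from xairob import chem_data as cd
from xairob.vocab import BOS, EOS, PAD, DEFAULT_VOCAB, TokenizationError


class TestCleaning:
    def test_salt_stripping_keeps_largest_organic_fragment(self):
        result = cd.clean_structures(["CC(=O)O.[Na+]"])
        assert [r.smiles_canonical for r in result.records] == ["CC(=O)O"]

    def test_duplicates_collapse_to_first_occurrence(self):
        result = cd.clean_structures(["CCO", "OCC", "CCN"])
        assert [r.smiles_canonical for r in result.records] == ["CCO", "CCN"]

    def test_invalid_smiles_skipped_with_reason(self):
        result = cd.clean_structures(["C("])
        assert result.records == []
        assert len(result.failures) == 1

    def test_stereochemistry_removed(self):
        result = cd.clean_structures(["C[C@H](N)C(=O)O"])
        assert "@" not in result.records[0].smiles_canonical

    def test_conflicting_duplicate_labels_dropped(self):
        result = cd.clean_structures(["CCO", "OCC"], labels=[1, 0])
        assert result.records == []
        assert any("conflict" in f["reason"] for f in result.failures)

    def test_agreeing_duplicate_labels_kept(self):
        result = cd.clean_structures(["CCO", "OCC"], labels=[1, 1])
        assert len(result.records) == 1 and result.records[0].label == 1


class TestRemoveOverlap:
    def test_overlap_removed_and_disjoint_kept(self):
        a = cd.clean_structures(["CCO"]).records
        b = cd.clean_structures(["CCO", "CCN"]).records
        remaining = cd.remove_overlap(a, b)
        assert [r.smiles_canonical for r in remaining] == ["CCN"]
        assert cd.remove_overlap(a, a) == []


class TestCanonicalize:
    def test_idempotent_and_form_invariant(self):
        for smiles in ["OCC", "C(O)C", "c1ccccc1C"]:
            once = cd.canonicalize(smiles)
            assert cd.canonicalize(once) == once
        assert cd.canonicalize("OCC") == cd.canonicalize("C(O)C")

    def test_rdkit_oracle_agreement(self):
        # independent canonicalization route through a mol object
        assert cd.canonicalize("OCC") == Chem.MolToSmiles(Chem.MolFromSmiles("OCC"))

    def test_invalid_input_raises(self):
        with pytest.raises(cd.InvalidStructureError):
            cd.canonicalize("C(")


class TestEnumeration:
    def test_single_atom_yields_copies(self):
        assert cd.enumerate_smiles("C", 5, seed=0) == ["C"] * 5

    @pytest.mark.parametrize("smiles", ["O=C=O", "CCOc1ccccc1", "CC(C)NC(=O)C"])
    def test_round_trip_to_same_canonical_form(self, smiles):
        canonical = cd.canonicalize(smiles)
        for variant in cd.enumerate_smiles(smiles, 8, seed=3):
            assert cd.canonicalize(variant) == canonical

    def test_deterministic_under_seed(self):
        a = cd.enumerate_smiles("CCOc1ccccc1", 6, seed=9)
        b = cd.enumerate_smiles("CCOc1ccccc1", 6, seed=9)
        assert a == b
        assert a != cd.enumerate_smiles("CCOc1ccccc1", 6, seed=10)


class TestCanonicalRanks:
    def test_ranks_are_a_permutation(self):
        for smiles in ["CCO", "c1ccc(CCN)cc1", "CC(C)(C)O"]:
            ranks = cd.canonical_atom_ranks(smiles)
            assert sorted(ranks) == list(range(len(ranks)))

    def test_atom_identity_preserved_across_forms(self):
        # the oxygen atom must land on the same canonical rank in both strings
        ranks_a = cd.canonical_atom_ranks("OCC")  # O at index 0
        ranks_b = cd.canonical_atom_ranks("CCO")  # O at index 2
        assert ranks_a[0] == ranks_b[2]

    def test_element_agreement_across_enumerations(self):
        smiles = "CCOc1ccncc1"
        base = cd.canonical_atom_ranks(smiles)
        symbols = [a.GetSymbol() for a in Chem.MolFromSmiles(smiles).GetAtoms()]
        by_rank = {r: s for r, s in zip(base, symbols)}
        for variant in cd.enumerate_smiles(smiles, 6, seed=2):
            ranks = cd.canonical_atom_ranks(variant)
            syms = [a.GetSymbol() for a in Chem.MolFromSmiles(variant).GetAtoms()]
            assert {r: s for r, s in zip(ranks, syms)} == by_rank


class TestTokenize:
    def test_carbon_dioxide_layout(self):
        seq = cd.tokenize("O=C=O", pad_to=9)
        assert seq.tokens[:7] == (BOS, "O", "=", "C", "=", "O", EOS)
        assert seq.tokens[7:] == (PAD, PAD)
        assert seq.atom_of_token == {1: 0, 3: 1, 5: 2}

    def test_two_letter_halogen_is_one_token(self):
        seq = cd.tokenize("CCl")
        assert len(seq.atom_of_token) == Chem.MolFromSmiles("CCl").GetNumHeavyAtoms()

    def test_bracket_atom_is_one_token(self):
        seq = cd.tokenize("C[N+](=O)[O-]")
        assert "[N+]" in seq.tokens and "[O-]" in seq.tokens
        assert len(seq.atom_of_token) == 4

    @pytest.mark.parametrize(
        "smiles", ["O=C=O", "CCOc1ccccc1", "C[N+](=O)[O-]", "BrCCCl", "C%11CC%11"]
    )
    def test_detokenize_round_trip(self, smiles):
        assert cd.tokenize(smiles, pad_to=30).detokenize() == smiles

    def test_heavy_atom_count_matches_structure_parser(self, synthetic_corpus):
        for rec in synthetic_corpus[:20]:
            seq = cd.tokenize(rec.smiles_canonical)
            mol = Chem.MolFromSmiles(rec.smiles_canonical)
            assert len(seq.atom_of_token) == mol.GetNumHeavyAtoms()

    def test_vocabulary_is_68_codes(self):
        assert len(DEFAULT_VOCAB) == 68

    def test_out_of_vocabulary_is_hard_error(self):
        with pytest.raises(TokenizationError, match="Zr"):
            cd.tokenize("C[Zr]C")

    def test_over_length_is_error(self):
        with pytest.raises(TokenizationError):
            cd.tokenize("C" * 200)


class TestMasking:
    def test_specials_never_selected_and_seed_reproducible(self):
        seq = cd.tokenize("CCOCCNc1ccccc1", pad_to=25)
        corrupted, plan = cd.mask_tokens(seq, seed=5)
        special_positions = {0, seq.tokens.index(EOS)} | {
            i for i, t in enumerate(seq.tokens) if t == PAD
        }
        assert not plan.selected_positions & special_positions
        again, plan2 = cd.mask_tokens(seq, seed=5)
        assert again.tokens == corrupted.tokens
        assert plan2.selected_positions == plan.selected_positions

    def test_rates_converge_to_contract(self):
        # ~1.4e5 positions: selection 15%, actions 80/10/10 within 4 sigma
        seq = cd.tokenize("CCOCCNCCOCCNCCOCCNCCOCCOCCNCC")
        n_positions = len(seq.smiles_positions())
        trials = 5000
        n_sel = 0
        actions = {"MASK": 0, "RANDOM": 0, "KEEP": 0}
        for s in range(trials):
            _, plan = cd.mask_tokens(seq, seed=s)
            n_sel += len(plan.selected_positions)
            for act in plan.action_of_position.values():
                actions[act] += 1
        total = trials * n_positions
        sd = np.sqrt(0.15 * 0.85 / total)
        assert abs(n_sel / total - 0.15) < 4 * sd
        for act, p in [("MASK", 0.8), ("RANDOM", 0.1), ("KEEP", 0.1)]:
            sd_a = np.sqrt(p * (1 - p) / n_sel)
            assert abs(actions[act] / n_sel - p) < 4 * sd_a


class TestAlerts:
    def test_no_match_on_plain_alkane(self, nitro_alerts):
        assert cd.match_alerts("CC", nitro_alerts).matches == ()

    def test_nitrobenzene_matches_three_atoms(self, nitro_alerts):
        result = cd.match_alerts("c1ccccc1[N+](=O)[O-]", nitro_alerts)
        assert len(result.matches) == 1
        name, atoms = result.matches[0]
        assert name == "nitro" and len(atoms) == 3
        # oracle: RDKit substructure search called directly
        patt = Chem.MolFromSmarts(cd.NITRO_ALERT_SMARTS)
        oracle = Chem.MolFromSmiles("c1ccccc1[N+](=O)[O-]").GetSubstructMatches(patt)
        assert atoms == frozenset(oracle[0])

    def test_empty_alert_set(self):
        empty = cd.AlertSet(entries=())
        assert cd.match_alerts("CCO", empty).atom_union == frozenset()

    def test_bad_smarts_rejected(self):
        with pytest.raises(ValueError):
            cd.AlertSet(entries=(("broken", "[[["),))


class TestSyntheticGenerator:
    def test_all_molecules_survive_cleaning(self, synthetic_corpus):
        smiles = [r.smiles_canonical for r in synthetic_corpus]
        cleaned = cd.clean_structures(smiles)
        assert len(cleaned.records) == len(synthetic_corpus)
        assert not cleaned.failures

    def test_noise_free_labels_equal_alert_presence(
        self, synthetic_corpus, nitro_alerts
    ):
        for rec in synthetic_corpus:
            has = bool(cd.match_alerts(rec.smiles_canonical, nitro_alerts).matches)
            assert rec.label == int(has)

    def test_alert_prevalence_near_half(self, synthetic_corpus):
        rate = np.mean([r.label for r in synthetic_corpus])
        assert 0.25 < rate < 0.75

    def test_deterministic_under_seed(self):
        a = cd.generate_synthetic_molecules(30, seed=4)
        b = cd.generate_synthetic_molecules(30, seed=4)
        assert [r.smiles_canonical for r in a] == [r.smiles_canonical for r in b]

    def test_unique_ids_and_canonical_keys(self, synthetic_corpus):
        ids = [r.id for r in synthetic_corpus]
        keys = [r.smiles_canonical for r in synthetic_corpus]
        assert len(set(ids)) == len(ids)
        assert len(set(keys)) == len(keys)


class TestSplits:
    def test_scaffold_split_partitions_and_separates_scaffolds(self, synthetic_corpus):
        from rdkit.Chem.Scaffolds import MurckoScaffold

        train, valid, test = cd.scaffold_split(synthetic_corpus)
        assert len(train) + len(valid) + len(test) == len(synthetic_corpus)
        scaffold = lambda r: MurckoScaffold.MurckoScaffoldSmiles(r.smiles_canonical)
        train_sc = {scaffold(r) for r in train}
        assert not train_sc & {scaffold(r) for r in test}

    def test_random_split_is_seeded_partition(self, synthetic_corpus):
        a = cd.random_split(synthetic_corpus, seed=1)
        b = cd.random_split(synthetic_corpus, seed=1)
        assert [r.id for r in a[0]] == [r.id for r in b[0]]


class TestIO:
    def test_csv_round_trip(self, tmp_path, synthetic_corpus):
        path = tmp_path / "mols.csv"
        cd.write_records_csv(synthetic_corpus, path)
        smiles, labels, ids = cd.read_molecule_table(path)
        assert smiles == [r.smiles_canonical for r in synthetic_corpus]
        assert labels == [r.label for r in synthetic_corpus]

    def test_smi_file(self, tmp_path):
        path = tmp_path / "mols.smi"
        path.write_text("CCO\nCCN\n")
        smiles, labels, _ = cd.read_molecule_table(path)
        assert smiles == ["CCO", "CCN"] and labels == [None, None]

    def test_alert_tsv(self, tmp_path):
        path = tmp_path / "alerts.tsv"
        path.write_text("# comment\nnitro\t[N+](=O)[O-]\n")
        alerts = cd.AlertSet.from_tsv(path)
        assert len(alerts) == 1
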