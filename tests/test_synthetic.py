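"""Curation rules, toy corpus generator, substructure oracle."""

import numpy as np
import pandas as pd
import pytest

from smilesrl.chem import parse_and_canonicalize
from smilesrl.synthetic import (
    CurationConfig,
    SyntheticConfig,
    curate_activity_records,
    generate_synthetic_activity_table,
    generate_toy_corpus,
    substructure_oracle,
)


def _record(smiles, pchembl, conf=9, assay="binding", organism="Homo sapiens", cid="X"):
    return {
        "compound_id": cid,
        "smiles": smiles,
        "pchembl_value": pchembl,
        "assay_type": assay,
        "confidence_score": conf,
        "organism": organism,
    }


def brute_force_curate(records: pd.DataFrame, cfg: CurationConfig):
    """Independent re-application of the curation rules, one naive loop."""
    by_canonical = {}
    for _, row in records.iterrows():
        if row["confidence_score"] < cfg.min_confidence:
            continue
        if row["assay_type"] not in cfg.allowed_assay_types:
            continue
        if row["organism"] != cfg.organism:
            continue
        rec = parse_and_canonicalize(row["smiles"])
        if not rec.is_valid:
            continue
        by_canonical.setdefault(rec.canonical_smiles, []).append(
            float(row["pchembl_value"])
        )
    out = {}
    for smi, vals in by_canonical.items():
        if max(vals) - min(vals) > cfg.replicate_tolerance_log:
            continue
        rep = float(np.median(vals))
        out[smi] = int(rep >= cfg.binarization_pchembl)
    return out


class TestCurationRules:
    def test_low_confidence_removed(self):
        df = pd.DataFrame(
            [_record("CCO", 7.0, conf=7), _record("CCN", 7.0, conf=8)]
        )
        ds = curate_activity_records(df)
        assert ds.frame["canonical_smiles"].tolist() == ["CCN"]

    def test_wide_replicates_exclude_the_compound(self):
        df = pd.DataFrame(
            [_record("CCO", 6.0), _record("CCO", 7.5), _record("CCN", 7.0)]
        )
        ds = curate_activity_records(df)
        assert ds.frame["canonical_smiles"].tolist() == ["CCN"]

    def test_close_replicates_collapse_to_median(self):
        df = pd.DataFrame(
            [_record("CCO", 6.2), _record("CCO", 6.4), _record("CCO", 7.0),
             _record("CCCCN", 4.0)]
        )
        ds = curate_activity_records(df)
        row = ds.frame[ds.frame["canonical_smiles"] == "CCO"].iloc[0]
        assert row["label"] == 1  # median 6.4 >= 6.0

    def test_submicromolar_compound_labeled_active(self):
        # pChEMBL 6.5 is ~0.32 uM, more potent than the 1 uM cutoff
        df = pd.DataFrame([_record("CCO", 6.5), _record("CCCCN", 4.0)])
        ds = curate_activity_records(df)
        labels = dict(zip(ds.frame["canonical_smiles"], ds.frame["label"]))
        assert labels["CCO"] == 1 and labels["CCCCN"] == 0

    def test_boundary_compound_respects_config_flag(self):
        df = pd.DataFrame([_record("CCO", 6.0)])
        assert curate_activity_records(df).frame["label"].iloc[0] == 1
        flipped = curate_activity_records(
            df, CurationConfig(boundary_active=False)
        )
        assert flipped.frame["label"].iloc[0] == 0

    def test_disallowed_assay_and_organism_removed(self):
        df = pd.DataFrame(
            [
                _record("CCO", 7.0, assay="ADMET"),
                _record("CCN", 7.0, organism="Rattus norvegicus"),
                _record("CCC", 7.0),
            ]
        )
        ds = curate_activity_records(df)
        assert ds.frame["canonical_smiles"].tolist() == ["CCC"]

    def test_invalid_smiles_dropped_not_fatal(self):
        df = pd.DataFrame([_record("CC(", 7.0), _record("CCO", 7.0)])
        assert curate_activity_records(df).frame["canonical_smiles"].tolist() == ["CCO"]

    def test_zero_survivors_is_an_error(self):
        df = pd.DataFrame([_record("CCO", 7.0, conf=3)])
        with pytest.raises(ValueError):
            curate_activity_records(df)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_synthetic_tables(self, seed):
        records, _ = generate_synthetic_activity_table(n=120, seed=seed)
        cfg = CurationConfig()
        ds = curate_activity_records(records, cfg)
        expected = brute_force_curate(records, cfg)
        got = dict(zip(ds.frame["canonical_smiles"], ds.frame["label"]))
        assert got == expected

    def test_order_stable(self):
        records, _ = generate_synthetic_activity_table(n=100, seed=4)
        shuffled = records.iloc[::-1].reset_index(drop=True)
        a = curate_activity_records(records).frame
        b = curate_activity_records(shuffled).frame
        pd.testing.assert_frame_equal(a, b)


class TestToyCorpus:
    def test_all_emitted_molecules_valid_canonical_unique(self, toy_corpus):
        assert len(set(toy_corpus)) == len(toy_corpus) == 1000
        for smi in toy_corpus[:100]:
            rec = parse_and_canonicalize(smi)
            assert rec.is_valid and rec.canonical_smiles == smi

    def test_fixed_seed_reproduces_corpus(self):
        cfg = SyntheticConfig(corpus_size=50, seed=5)
        assert generate_toy_corpus(cfg) == generate_toy_corpus(cfg)

    def test_motif_frequency_near_target(self):
        corpus = generate_toy_corpus(
            SyntheticConfig(corpus_size=1000, motif_frequency=0.02, seed=3)
        )
        oracle = substructure_oracle("c1ccsc1")
        freq = np.mean([oracle(s) for s in corpus])
        assert 0.01 <= freq <= 0.03

    def test_sparse_frequency_band_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(motif_frequency=0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(motif_frequency=0.0)

    def test_baseline_active_fraction_is_sparse(self, pretrained_model, oracle):
        """The pretrained-only model generates <2% predicted actives:
        the sparse-reward regime holds before any RL."""
        from smilesrl.policy import decode_samples, sample_trajectories

        smis = decode_samples(
            pretrained_model, sample_trajectories(pretrained_model, 1000, seed=31)
        )
        uniq = {
            r.canonical_smiles
            for r in map(parse_and_canonicalize, smis)
            if r.is_valid
        }
        active = sum(1 for s in uniq if oracle(s) > 0.75)
        assert active / len(uniq) < 0.02


class TestSubstructureOracle:
    def test_motif_bearing_molecule_scores_p_hit(self):
        oracle = substructure_oracle("c1ccsc1", p_hit=0.9, p_miss=0.1)
        assert oracle("Cc1cccs1") == 0.9

    def test_acyclic_molecule_scores_p_miss(self):
        oracle = substructure_oracle("c1ccsc1", p_hit=0.9, p_miss=0.1)
        assert oracle("CCCC") == 0.1

    def test_invalid_smiles_scores_zero(self):
        oracle = substructure_oracle("c1ccsc1", p_hit=0.9, p_miss=0.1)
        assert oracle("CC(") == 0.0

    def test_unparseable_motif_rejected(self):
        with pytest.raises(ValueError):
            substructure_oracle("](")


class TestActivityTable:
    def test_every_curation_rule_removes_records(self):
        records, truth = generate_synthetic_activity_table(n=200, seed=11)
        assert (records["confidence_score"] < 8).sum() >= 1
        assert (~records["assay_type"].isin({"binding", "functional"})).sum() >= 1
        assert (records["organism"] != "Homo sapiens").sum() >= 1
        spreads = records.groupby("smiles")["pchembl_value"].agg(
            lambda v: v.max() - v.min()
        )
        assert (spreads > 1.0).sum() >= 1
        assert (~truth["survives_curation"]).sum() >= 4
        invalid = [
            s for s in records["smiles"] if not parse_and_canonicalize(s).is_valid
        ]
        assert len(invalid) >= 1

    def test_truth_sidecar_matches_curation(self):
        records, truth = generate_synthetic_activity_table(n=150, seed=2)
        ds = curate_activity_records(records)
        survivors = set(ds.frame["canonical_smiles"])
        expected = set(truth[truth["survives_curation"]]["canonical_smiles"])
        assert survivors == expected
        labels = dict(zip(ds.frame["canonical_smiles"], ds.frame["label"]))
        for _, row in truth[truth["survives_curation"]].iterrows():
            assert labels[row["canonical_smiles"]] == row["expected_label"]

    def test_fixed_seed_reproduces_table(self):
        a, _ = generate_synthetic_activity_table(n=80, seed=9)
        b, _ = generate_synthetic_activity_table(n=80, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_activity_table(n=20, seed=0)
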