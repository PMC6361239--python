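"""KsP table ingestion, site mapping, clustering and negative sampling."""

import numpy as np
import pytest

from akid import fixtures
from akid.dataset import (
    KsPInteraction,
    cluster_70,
    dataset_manifest,
    deduplicate_vs_training,
    exclude_multidomain,
    load_ksp_table,
    make_negatives,
    map_sites,
    window_identity,
)
from akid.encoding import PhosphoPeptide, extract_peptide
from akid.profile_hmm import DomainAlignment, KinaseDomainHit

from oracles import brute_identity


def _hit(pid):
    return KinaseDomainHit(
        protein_id=pid, start=0, end=10, bit_score=50.0, p_value=0.0,
        alignment=DomainAlignment(pairs=[]),
    )


class TestLoadKspTable:
    def test_header_only_file_gives_no_records(self, tmp_path):
        p = tmp_path / "ksp.tsv"
        p.write_text("kinase_id\tsubstrate_id\tposition\tacceptor\n")
        assert load_ksp_table(p) == []

    def test_well_formed_rows_are_loaded_with_zero_based_positions(self, tmp_path):
        p = tmp_path / "ksp.tsv"
        p.write_text(
            "kinase_id\tsubstrate_id\tposition\tacceptor\n"
            "K1\tS1\t10\tS\nK1\tS2\t3\tT\nK2\tS1\t7\tY\n"
        )
        recs = load_ksp_table(p)
        assert len(recs) == 3
        assert recs[0].site_pos == 9

    def test_malformed_rows_are_rejected_not_fatal(self, tmp_path, caplog):
        p = tmp_path / "ksp.tsv"
        p.write_text(
            "kinase_id\tsubstrate_id\tposition\tacceptor\n"
            "K1\tS1\tten\tS\nK1\tS2\t3\tQ\nK1\tS3\t5\tS\n"
        )
        recs = load_ksp_table(p)
        assert [r.substrate_id for r in recs] == ["S3"]

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "ksp.tsv"
        p.write_text("kinase_id\tposition\tacceptor\nK1\t3\tS\n")
        with pytest.raises(ValueError, match="substrate_id"):
            load_ksp_table(p)


class TestMapSites:
    def _proteome(self):
        rng = np.random.default_rng(42)
        seq = "".join(np.random.default_rng(42).choice(list("ACDEFGHIKLMNPQRVW"), size=60))
        seq = seq[:30] + "S" + seq[31:]
        return {"P1": seq}, seq

    def test_exact_window_match_is_remapped(self):
        proteome, seq = self._proteome()
        window = seq[23:38]
        rec = KsPInteraction("K1", "P1", 5, "S", window=window)
        (mapped,) = map_sites([rec], proteome)
        assert mapped.site_pos == 30

    def test_record_without_counterpart_is_dropped(self):
        proteome, _ = self._proteome()
        rec = KsPInteraction("K1", "P1", 5, "S", window="AAAAAAASAAAAAAA")
        assert map_sites([rec], proteome) == []

    def test_single_substitution_is_rescued_by_local_alignment(self):
        proteome, seq = self._proteome()
        window = list(seq[23:38])
        window[2] = "W" if window[2] != "W" else "Y"  # one planted mutation
        rec = KsPInteraction("K1", "P1", 5, "S", window="".join(window))
        (mapped,) = map_sites([rec], proteome)
        assert mapped.site_pos == 30

    def test_coordinate_only_records_are_validated_against_the_proteome(self):
        proteome, seq = self._proteome()
        ok = KsPInteraction("K1", "P1", 30, "S")
        bad = KsPInteraction("K1", "P1", 12, "S")  # residue there is not S
        mapped = map_sites([ok, bad], proteome)
        assert [m.site_pos for m in mapped] == [30]


class TestExcludeMultidomain:
    def test_only_single_domain_kinases_survive(self):
        recs = [
            KsPInteraction("K1", "S1", 3, "S"),
            KsPInteraction("K2", "S1", 3, "S"),
            KsPInteraction("K3", "S1", 3, "S"),
        ]
        hits = [_hit("K1"), _hit("K2"), _hit("K2")]
        kept = exclude_multidomain(recs, hits)
        assert [r.kinase_id for r in kept] == ["K1"]


class TestCluster70:
    def test_identical_sequences_share_a_cluster(self):
        clusters = cluster_70({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL"})
        assert len(clusters) == 1
        assert set(clusters[0].member_ids) == {"a", "b"}

    def test_unrelated_sequences_split(self):
        clusters = cluster_70({"a": "AAAAAAAAAA", "b": "WWWWWWWWWW"})
        assert len(clusters) == 2

    def test_toy_set_matches_brute_force_identity_oracle(self):
        seqs = {
            "s1": "ACDEFG",
            "s2": "ACDEFW",  # 5/6 vs s1
            "s3": "AGGGFG",  # 3/6 vs s1
            "s4": "WWYYPP",
            "s5": "WWYYPG",  # 5/6 vs s4
        }
        clusters = cluster_70(seqs)
        # oracle: replay the same greedy order with enumerated identities
        order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
        reps, members = [], {}
        for sid in order:
            for rep in reps:
                if brute_identity(seqs[sid], seqs[rep]) >= 0.70:
                    members[rep].append(sid)
                    break
            else:
                reps.append(sid)
                members[sid] = [sid]
        got = {c.representative_id: set(c.member_ids) for c in clusters}
        assert got == {r: set(m) for r, m in members.items()}

    def test_clusters_partition_the_input_and_respect_the_threshold(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVY"), size=7))
        seqs = {}
        for i in range(6):
            s = list(base)
            for _ in range(rng.integers(0, 4)):
                s[rng.integers(7)] = "W"
            seqs[f"s{i}"] = "".join(s)
        clusters = cluster_70(seqs)
        all_members = [m for c in clusters for m in c.member_ids]
        assert sorted(all_members) == sorted(seqs)
        for c in clusters:
            for m in c.member_ids:
                assert brute_identity(seqs[m], seqs[c.representative_id]) >= 0.70

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cluster_70({})


def _pool(n, seed=0):
    rng = np.random.default_rng(seed)
    peps = []
    for i in range(n):
        window = "".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=15))
        window = window[:7] + "STY"[i % 3] + window[8:]
        peps.append(PhosphoPeptide(f"bg{i}", 7, "STY"[i % 3], window))
    return peps


class TestMakeNegatives:
    def test_equal_number_of_negatives(self):
        positives = [KsPInteraction(f"K{i}", f"S{i}", 3, "S") for i in range(5)]
        negs = make_negatives(positives, _pool(50), "annotated-phospho", seed=1)
        assert len(negs) == len(positives)
        assert all(n.label == "negative" for n in negs)

    def test_same_seed_reproduces_the_same_set(self):
        positives = [KsPInteraction(f"K{i}", f"S{i}", 3, "S") for i in range(5)]
        a = make_negatives(positives, _pool(50), "random-STY", seed=9)
        b = make_negatives(positives, _pool(50), "random-STY", seed=9)
        assert a == b

    def test_negatives_never_hit_known_positives(self):
        pool = _pool(30)
        positives = [
            KsPInteraction("K1", p.protein_id, p.site_pos, p.acceptor) for p in pool[:10]
        ]
        negs = make_negatives(positives, pool, "annotated-phospho", seed=2)
        pos_keys = {p.key for p in positives}
        assert all(n.key not in pos_keys for n in negs)

    def test_exhausted_pool_raises(self):
        pool = _pool(3)
        positives = [
            KsPInteraction("K1", p.protein_id, p.site_pos, p.acceptor) for p in pool
        ]
        with pytest.raises(ValueError, match="exhausted"):
            make_negatives(positives, pool, "annotated-phospho", seed=0)


class TestDeduplicate:
    def _rec(self, window):
        return KsPInteraction("K1", "S1", 7, "S", window=window)

    def test_identity_boundaries(self):
        train = ["AAAAAAASAAAAAAA"]
        same = self._rec("AAAAAAASAAAAAAA")  # 15/15
        seven = self._rec("AAAAAAASWWWWWWW")  # 8/15 (53.3%) -> removed
        six = self._rec("AAAAAAWSWWWWWWW")  # 7/15 (46.7%) -> kept
        kept = deduplicate_vs_training([same, seven, six], train)
        assert kept == [six]

    def test_window_identity_counts_positions(self):
        assert window_identity("AAAAAAASAAAAAAA", "AAAAAAWSWWWWWWW") == pytest.approx(7 / 15)


def test_manifest_counts_labels_and_acceptors():
    recs = [
        KsPInteraction("K1", "S1", 3, "S"),
        KsPInteraction("K1", "S2", 3, "T", label="negative", source="random-STY-background"),
    ]
    m = dataset_manifest(recs)
    assert m["n_total"] == 2
    assert m["n_label_positive"] == 1
    assert m["n_acceptor_T"] == 1
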