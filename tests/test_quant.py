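"""Quantification: demultiplexing, feature extraction, pair counting,
UMI deduplication, molecule classification."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from castling import assembly as A
from castling import quant as Q
from castling import simulate as S
from castling import targets as T
from castling._seq import revcomp

BARCODES = {"s1": "ACGTAC", "s2": "TTGCAA", "s3": "CAATGG"}


@pytest.fixture(scope="module")
def quant_setup(small_genome, cassette):
    selected, _ = T.select_candidates(small_genome)
    designs, _ = A.design_pool(small_genome, selected, cassette)
    refs = Q.build_junction_references(designs, cassette, small_genome)
    adapter = S.AdapterSpec(r1_anchor=cassette.sequence[-30:][:12])
    return small_genome, cassette, designs, refs, adapter


class TestDemux:
    def test_exact_and_one_substitution_assigned(self):
        assert Q.demux_barcodes("ACGTAC", BARCODES) == "s1"
        assert Q.demux_barcodes("ACGTAA", BARCODES) == "s1"

    def test_two_substitutions_unassigned(self):
        assert Q.demux_barcodes("ACGAAA", BARCODES) is None

    def test_ambiguous_unassigned_by_exhaustive_oracle(self):
        """Every 6-mer within distance 1 of two barcodes must be rejected."""
        close = {"a": "AAAAAA", "b": "AAAACC"}  # distance 2: invalid set
        with pytest.raises(ValueError, match="Levenshtein"):
            Q.demux_barcodes("AAAAAC", close)
        # with a valid set, scan random queries against a brute-force oracle
        rng = np.random.default_rng(0)
        for _ in range(300):
            query = "".join(rng.choice(list("ACGT"), size=6))
            expected_hits = [
                s for s, bc in BARCODES.items() if Q.levenshtein(query, bc) <= 1
            ]
            expected = expected_hits[0] if len(expected_hits) == 1 else None
            assert Q.demux_barcodes(query, BARCODES) == expected


class TestExtractFeatures:
    def _pair(self, adapter, umi="ACGTACGT", bc="ACGTAC", genomic="G" * 60):
        r1 = adapter.r1_anchor + "A" * 80
        r2 = bc + umi + adapter.r2_anchor + genomic
        return r1, r2

    def test_perfect_pair_recovered(self, quant_setup):
        *_, adapter = quant_setup
        r1, r2 = self._pair(adapter)
        feats = Q.extract_features(r1, r2, adapter)
        assert feats["ok"]
        assert feats["umi"] == "ACGTACGT"
        assert feats["barcode"] == "ACGTAC"
        assert feats["junction2"] == "G" * 60

    def test_one_mismatch_in_anchor_tolerated(self, quant_setup):
        *_, adapter = quant_setup
        r1, r2 = self._pair(adapter)
        a = adapter.r1_anchor
        for i in range(len(a)):  # every single-mismatch placement
            sub = a[:i] + ("A" if a[i] != "A" else "C") + a[i + 1 :]
            feats = Q.extract_features(sub + r1[len(a) :], r2, adapter)
            assert feats["ok"]

    def test_missing_adapter_rejected_with_reason(self, quant_setup):
        *_, adapter = quant_setup
        r1, r2 = self._pair(adapter)
        feats = Q.extract_features("T" * len(r1), r2, adapter)
        assert not feats["ok"] and feats["reason"] == "r1_anchor_missing"
        feats = Q.extract_features(r1, "T" * len(r2), adapter)
        assert not feats["ok"] and feats["reason"] == "r2_anchor_missing"


class TestCountInsertions:
    def _pairs_df(self, rows):
        return pd.DataFrame(rows)

    def test_insert_within_homology_not_counted(self, quant_setup):
        _, _, designs, refs, adapter = quant_setup
        rid, ref = next(iter(refs.items()))
        short = ref.homology_len - 5
        frag = ref.sequence[:short]
        pairs = self._pairs_df(
            [{"pair_id": "p0", "read1": frag[:60], "read2": revcomp(frag)[:60], "umi": "AAAA", "sample": "s1"}]
        )
        counts, assign = Q.count_insertions(pairs, refs)
        assert not assign.counted.iloc[0]
        assert assign.reason.iloc[0] == "insert_within_homology"

    def test_forward_mate_offset_not_counted(self, quant_setup):
        _, _, designs, refs, adapter = quant_setup
        rid, ref = next(iter(refs.items()))
        frag = ref.sequence[:300]
        pairs = self._pairs_df(
            [
                {
                    "pair_id": "p0",
                    "read1": ref.sequence[5:155],  # starts 5 bp into the constant region
                    "read2": revcomp(frag)[:100],
                    "umi": "AAAA",
                    "sample": "s1",
                }
            ]
        )
        counts, assign = Q.count_insertions(pairs, refs)
        assert not assign.counted.iloc[0]
        assert assign.reason.iloc[0] == "forward_not_at_constant_region"

    def test_seeded_simulation_recovers_ground_truth_exactly(self, quant_setup):
        g, cassette, designs, refs, adapter = quant_setup
        spec = S.LibrarySpec(
            off_target_rate=0.0, contaminant_rate=0.0, dark_clone_rate=0.0, seed=20
        )
        clones = S.simulate_library(designs, g, spec, n_clones=60)
        reads, truth = S.simulate_anchorseq_reads(
            clones, refs, adapter, BARCODES, pcr_duplication=5, seed=21, genome=g
        )
        counts, assign = Q.count_insertions(reads, refs, adapter=adapter)
        dedup = Q.dedup_count_matrix(assign)
        merged = dedup.merge(
            truth,
            left_on=["sample", "genotype"],
            right_on=["sample", "design_id"],
            how="outer",
        ).fillna(-1)
        assert (merged.molecules_x == merged.molecules_y).all()
        # pre-dedup counts are exactly the duplication factor times molecules
        pre = counts.set_index(["sample", "genotype"]).reads
        post = dedup.set_index(["sample", "genotype"]).molecules
        assert ((pre / post) == 5.0).all()


class TestDedupUmis:
    def test_directional_merge_examples(self):
        assert Q.dedup_umis(Counter({"AAAA": 10, "AAAT": 1})) == 1
        assert Q.dedup_umis(Counter({"AAAA": 5, "TTTT": 5})) == 2
        assert Q.dedup_umis(["ACGT"] * 50) == 1
        assert Q.dedup_umis([]) == 0

    def test_count_ratio_rule_boundary(self):
        # merge requires count(u) >= 2*count(v) - 1
        assert Q.dedup_umis(Counter({"AAAA": 5, "AAAT": 3})) == 1  # 5 >= 5
        assert Q.dedup_umis(Counter({"AAAA": 4, "AAAT": 3})) == 2  # 4 < 5

    def test_mixed_lengths_raise(self):
        with pytest.raises(ValueError, match="equal length"):
            Q.dedup_umis(["AAA", "AAAA"])

    def test_agrees_with_rule_oracle_on_random_multisets(self):
        def oracle(counts):
            reps = []
            for u, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
                for ru, rc in reps:
                    if sum(a != b for a, b in zip(ru, u)) == 1 and rc >= 2 * c - 1:
                        break
                else:
                    reps.append((u, c))
            return len(reps)

        rng = np.random.default_rng(1)
        space = ["".join(p) for p in itertools.product("AC", repeat=4)]
        for _ in range(200):
            k = int(rng.integers(1, 8))
            chosen = rng.choice(space, size=k, replace=False)
            counts = Counter({u: int(rng.integers(1, 20)) for u in chosen})
            assert Q.dedup_umis(counts) == oracle(counts)


class TestClassification:
    def test_on_off_target_calls(self):
        assert Q.classify_on_off_target("d1", "d1") == "on_target"
        assert Q.classify_on_off_target("d1", "d2") == "off_target"
        assert Q.classify_on_off_target("d1", None) == "off_target"
        assert (
            Q.classify_on_off_target("dX", "dX", experiment_designs={"d1"})
            == "on_target_foreign_design"
        )

    def test_simulated_off_target_recall(self, quant_setup):
        g, cassette, designs, refs, adapter = quant_setup
        spec = S.LibrarySpec(
            off_target_rate=0.3, contaminant_rate=0.0, dark_clone_rate=0.0, seed=22
        )
        clones = S.simulate_library(designs, g, spec, n_clones=100)
        reads, _ = S.simulate_anchorseq_reads(
            clones, refs, adapter, BARCODES, pcr_duplication=1, seed=23, genome=g
        )
        counts, assign = Q.count_insertions(reads, refs, adapter=adapter)
        m = assign.merge(reads[["pair_id", "clone_id"]], on="pair_id").merge(
            clones[["clone_id", "clone_class"]], on="clone_id"
        )
        off = m[m.clone_class == "off_target"]
        assert len(off) > 0
        assert not off.counted.any()  # off-target junctions never count on-target

    def test_classify_molecules_against_edit_distance_oracle(self):
        rng = np.random.default_rng(2)
        designs = {
            f"d{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(12)
        }

        def dp_distance(a, b):
            # textbook Levenshtein DP, independent of edlib
            m, n = len(a), len(b)
            prev = list(range(n + 1))
            for i in range(1, m + 1):
                cur = [i] + [0] * n
                for j in range(1, n + 1):
                    cur[j] = min(
                        prev[j] + 1,
                        cur[j - 1] + 1,
                        prev[j - 1] + (a[i - 1] != b[j - 1]),
                    )
                prev = cur
            return prev[n]

        molecules = []
        for d, seq in list(designs.items())[:6]:
            molecules.append(seq)  # exact
            molecules.append(seq[:10] + seq[11:])  # one deletion
        result = Q.classify_molecules(molecules, designs)
        for seq in molecules:
            dists = {d: dp_distance(seq, s) for d, s in designs.items()}
            best = min(dists.values())
            winners = [d for d, v in dists.items() if v == best]
            if len(winners) == 1:
                row = result[result.design_id == winners[0]].iloc[0]
                assert row.error_free + row.erroneous > 0

    def test_exact_sequence_is_error_free(self):
        designs = {"d1": "ACGT" * 10, "d2": "TGCA" * 10}
        res = Q.classify_molecules([designs["d1"]], designs)
        row = res.set_index("design_id").loc["d1"]
        assert row.error_free == 1 and row.erroneous == 0
        assert res.set_index("design_id").loc["d2"].status == "absent"

    def test_equidistant_molecule_unassigned(self):
        designs = {"d1": "AAAAAAAA", "d2": "AAAACCCC"}
        # query at distance 2 from both
        res = Q.classify_molecules(["AAAAAACC"], designs)
        assert res.attrs["unassigned"] == 1
        assert (res.error_free == 0).all() and (res.erroneous == 0).all()
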