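"""Read assignment: scoring, ties, oracle equivalence, QC, count export."""

import numpy as np
import pandas as pd
import pytest

from wobbleseq.assign import (
    AMBIGUOUS,
    FRACTIONAL,
    UNASSIGNED,
    UNIQUE,
    AssignParams,
    assign_reads,
    qc_metrics,
    write_counts,
)
from wobbleseq.simulate import SimulationConfig, demo_reference, simulate_counts, simulate_reads


# --- independent brute-force oracle ----------------------------------------

def oracle_assign_one(read, refset, max_mismatch=3, mod_site_free=True):
    """Loop-based re-statement of the scoring contract: 3'-anchored
    comparison, exemptions at mod sites and ANN wobble, terminal-indel rescue
    at cost 1, family-aware tie handling."""

    def score(read_seq, rec, trim_ref=False):
        seq = rec.sequence[:-1] if trim_ref else rec.sequence
        if len(read_seq) > len(seq):
            return None
        exempt = set()
        if mod_site_free:
            exempt = {p for p, _ in rec.mod_sites}
            if rec.is_ann:
                exempt.add(rec.wobble_index)
        off = len(seq) - len(read_seq)
        mm = 0
        for i, base in enumerate(read_seq):
            pos = off + i
            if seq[pos] != base and pos not in exempt:
                mm += 1
        return mm

    scored = {}
    for rec in refset:
        s = score(read, rec)
        if s is not None:
            scored[rec.id] = s
    best = min(scored.values()) if scored else None
    if best is None or best > max_mismatch:
        # terminal indel rescue, cost 1
        rescued = {}
        for rec in refset:
            cands = []
            if len(read) > 1:
                s = score(read[:-1], rec)
                if s is not None:
                    cands.append(s + 1)
            s = score(read, rec, trim_ref=True)
            if s is not None:
                cands.append(s + 1)
            if cands:
                rescued[rec.id] = min(cands)
        best = min(rescued.values()) if rescued else None
        if best is None or best > max_mismatch:
            return (UNASSIGNED, ())
        scored = rescued
    tied = sorted(i for i, s in scored.items() if s == best)
    fams = {refset.records[i].family_key for i in tied}
    if len(fams) > 1:
        return (AMBIGUOUS, tuple(tied))
    w = 1.0 / len(tied)
    payload = tuple((i, w) for i in tied)
    return (UNIQUE if len(tied) == 1 else FRACTIONAL, payload)


class TestScoring:
    def test_exact_suffix_is_unique(self, small_refset):
        read = small_refset.records["Gly-GCC-1"].sequence[-50:]
        res, _ = assign_reads([("r1", read)], small_refset)
        cat, payload = res.outcomes[0]
        assert cat == UNIQUE and payload[0][0] == "Gly-GCC-1"

    def test_same_family_tie_splits_weight(self, small_refset):
        # Ala-AGC-1 and Ala-AGC-2 differ only at position 5
        read = small_refset.records["Ala-AGC-1"].sequence[-50:]
        res, _ = assign_reads([("r1", read)], small_refset)
        cat, payload = res.outcomes[0]
        assert cat == FRACTIONAL
        assert dict(payload) == {"Ala-AGC-1": 0.5, "Ala-AGC-2": 0.5}
        assert res.anticodon_counts["Ala-AGC"] == pytest.approx(1.0)

    def test_wobble_g_mismatch_unpenalized(self, small_refset):
        rec = small_refset.records["Val-AAC-1"]
        read = list(rec.sequence[-50:])
        read[rec.wobble_index - (len(rec.sequence) - 50)] = "G"  # inosine read as G
        res, _ = assign_reads(
            [("r1", "".join(read))], small_refset, AssignParams(max_mismatch=0)
        )
        cat, payload = res.outcomes[0]
        assert cat == UNIQUE and payload[0][0] == "Val-AAC-1"

    def test_too_many_mismatches_unassigned(self, small_refset):
        read = "T" * 40
        res, _ = assign_reads([("r1", read)], small_refset)
        assert res.outcomes[0][0] == UNASSIGNED

    def test_empty_reference_rejected(self):
        from wobbleseq.reference import ReferenceSet

        with pytest.raises(ValueError):
            assign_reads([("r1", "ACGT")], ReferenceSet(records={}))

    def test_missing_fastq_named(self, small_refset):
        with pytest.raises(FileNotFoundError, match="nope.fastq"):
            assign_reads("nope.fastq", small_refset)


class TestOracleEquivalence:
    def test_simulated_reads_match_brute_force(self, tmp_path):
        # 30-isodecoder reference, ~1000 reads
        from wobbleseq.reference import packaged_anticodon_table

        table = packaged_anticodon_table().iloc[:15]
        refset = demo_reference(seed=4, isodecoders_per_family=2,
                                anticodon_table=table)
        assert len(refset) == 30
        cfg = SimulationConfig(seed=8, n_replicates=1, reads_per_replicate=1000,
                               seq_error_rate=0.01)
        counts, _ = simulate_counts(refset, cfg)
        paths = simulate_reads(refset, counts[["control_1"]], cfg, tmp_path)
        from wobbleseq.assign import read_fastq

        reads = list(read_fastq(paths["control_1"]))
        res, _ = assign_reads(reads, refset)
        assert res.n_reads >= 900
        for (name, seq), got in zip(reads, res.outcomes):
            expected = oracle_assign_one(seq, refset)
            assert got == expected, name

    def test_count_conservation(self, small_refset, tmp_path):
        cfg = SimulationConfig(seed=9, n_replicates=1, reads_per_replicate=800,
                               seq_error_rate=0.02)
        counts, _ = simulate_counts(small_refset, cfg)
        paths = simulate_reads(small_refset, counts[["control_1"]], cfg, tmp_path)
        res, _ = assign_reads(paths["control_1"], small_refset)
        total = res.counts.sum() + res.n_ambiguous + res.n_unassigned
        assert total == pytest.approx(res.n_reads)
        # anticodon counts are sums of member counts
        for fam in small_refset.families.values():
            expected = sum(res.counts[m] for m in fam.members)
            assert res.anticodon_counts.get(fam.label, 0.0) == pytest.approx(expected)


class TestQC:
    def test_all_full_length_with_cca(self, small_refset):
        reads = [
            (f"r{i}", rec.sequence)
            for i, rec in enumerate(small_refset.nuclear_records())
        ]
        res, _ = assign_reads(reads, small_refset)
        qc = qc_metrics(res)
        assert qc.full_length_fraction == 1.0
        assert qc.cca_fraction == 1.0
        # full-length reads cover the position where the near-duplicate
        # Ala-AGC isodecoders differ, so every read is unique
        assert qc.unique_fraction == 1.0

    def test_half_truncated(self, small_refset):
        rec = small_refset.records["Gly-GCC-1"]
        reads = [("full", rec.sequence), ("trunc", rec.sequence[58:])]
        res, _ = assign_reads(reads, small_refset)
        assert qc_metrics(res).full_length_fraction == 0.5

    def test_truncation_rate_recovered(self, small_refset, tmp_path):
        cfg = SimulationConfig(seed=10, n_replicates=1, reads_per_replicate=4000,
                               trunc_prob=0.3, seq_error_rate=0.0)
        counts, _ = simulate_counts(small_refset, cfg)
        paths = simulate_reads(small_refset, counts[["control_1"]], cfg, tmp_path)
        res, _ = assign_reads(paths["control_1"], small_refset)
        qc = qc_metrics(res)
        # two mod sites at trunc_prob=0.3 -> P(full) = 0.49
        assert qc.full_length_fraction == pytest.approx(0.49, abs=0.04)


class TestWriteCounts:
    def test_matrices_written_with_headers(self, small_refset, tmp_path):
        iso = pd.DataFrame(
            {"rep_1": [1.0, 0.5], "rep_2": [2.0, 0.5]},
            index=["Ala-AGC-1", "Ala-AGC-2"],
        )
        fam = pd.DataFrame({"rep_1": [1.5], "rep_2": [2.5]}, index=["Ala-AGC"])
        p1, p2 = write_counts(iso, fam, tmp_path)
        back = pd.read_csv(p1, sep="\t", index_col=0)
        assert list(back.columns) == ["rep_1", "rep_2"]
        assert back.loc["Ala-AGC-2"].sum() == pytest.approx(1.0)
        assert pd.read_csv(p2, sep="\t", index_col=0).shape == (1, 2)

    def test_empty_assignment_header_only(self, tmp_path):
        p1, _ = write_counts(pd.DataFrame(columns=["rep_1"]),
                             pd.DataFrame(columns=["rep_1"]), tmp_path)
        assert pd.read_csv(p1, sep="\t").shape[0] == 0
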