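"""Anchor scanning, QC cascade, UMI consensus and cell→clone resolution."""

import numpy as np
import pytest

from merlin.barcode_design import DEFAULT_ANCHOR
from merlin.extract import (
    DEFAULT_EMPTY_VECTOR_SIGNATURE,
    ExtractionHit,
    TaggedRead,
    dedup_and_resolve,
    extract_all,
    extract_clone_id,
    locate_anchor,
    read_fastq_tagged,
    read_sam_tagged,
    reverse_complement,
)
from merlin import synthetic

VALID_SUFFIX = "GTTGAACGACCACAA"  # conforms to the SNW repeat at phase 0


def _read(seq, cell="CELL1", umi="AAAAAAAAAA", rid="r1"):
    return TaggedRead(rid, seq, cell, umi)


class TestLocateAnchor:
    def test_forward_hit(self):
        assert locate_anchor("ACG" + DEFAULT_ANCHOR + "TTT") == (3, "+")

    def test_reverse_hit(self):
        seq = reverse_complement(VALID_SUFFIX + DEFAULT_ANCHOR)
        off, strand = locate_anchor(seq)
        assert strand == "-" and off == 15

    def test_absent(self):
        assert locate_anchor("ACGT" * 30) is None

    def test_mismatch_tolerance(self):
        corrupted = "G" + DEFAULT_ANCHOR[1:]
        assert locate_anchor("AA" + corrupted, max_mismatch=0) is None
        assert locate_anchor("AA" + corrupted, max_mismatch=1) == (2, "+")

    def test_rejects_mismatch_budget_as_large_as_anchor(self):
        with pytest.raises(ValueError):
            locate_anchor("ACGT", "ACG", max_mismatch=3)


class TestExtractCloneId:
    def test_ok_reports_suffix_adjacent_to_anchor(self):
        hit = extract_clone_id(_read("CACGT" + VALID_SUFFIX + DEFAULT_ANCHOR + "TT"))
        assert hit.status == "ok"
        assert hit.clone_id == VALID_SUFFIX

    def test_strand_invariance(self):
        seq = "CACGT" + VALID_SUFFIX + DEFAULT_ANCHOR + "TT"
        fwd = extract_clone_id(_read(seq))
        rev = extract_clone_id(_read(reverse_complement(seq)))
        assert fwd == rev

    def test_no_anchor(self):
        assert extract_clone_id(_read("ACGT" * 20)).status == "no_anchor"

    def test_short(self):
        hit = extract_clone_id(_read("ACGACCACAA" + DEFAULT_ANCHOR))
        assert hit.status == "short" and hit.clone_id is None

    def test_pattern_fail(self):
        # A at every SNW 'S' position violates the repeat unit
        hit = extract_clone_id(_read("A" * 15 + DEFAULT_ANCHOR))
        assert hit.status == "pattern_fail"

    def test_empty_vector(self):
        seq = "ACGT" + DEFAULT_EMPTY_VECTOR_SIGNATURE + DEFAULT_ANCHOR
        assert extract_clone_id(_read(seq)).status == "empty_vector"


class TestDedupAndResolve:
    def test_single_clone_umi_support(self):
        hits = [
            ExtractionHit("c1", f"umi{i}", "ok", VALID_SUFFIX) for i in range(5)
        ]
        table = dedup_and_resolve(hits)
        assert table.assignments.iloc[0].tolist() == ["c1", VALID_SUFFIX, 5]

    def test_duplicate_triples_counted_once(self):
        hits = [ExtractionHit("c1", "u1", "ok", VALID_SUFFIX)] * 3
        table = dedup_and_resolve(hits)
        assert table.assignments.iloc[0]["umi_support"] == 1

    def test_multi_clone_cell_removed(self):
        other = "GTTGAACGACCACGA"  # also SNW-valid, distinct
        hits = [
            ExtractionHit("c1", "u1", "ok", VALID_SUFFIX),
            ExtractionHit("c1", "u2", "ok", other),
        ]
        table = dedup_and_resolve(hits)
        assert len(table.assignments) == 0
        assert table.qc["cells_multi_barcode"] == 1
        assert table.qc["fraction_assigned"] == 0.0

    def test_min_umi_support_filters_minority_clone(self):
        other = "GTTGAACGACCACGA"
        hits = [ExtractionHit("c1", f"u{i}", "ok", VALID_SUFFIX) for i in range(4)]
        hits.append(ExtractionHit("c1", "u9", "ok", other))
        table = dedup_and_resolve(hits, min_umi_support=2)
        assert table.assignments.iloc[0]["clone_id"] == VALID_SUFFIX

    def test_umi_consensus_outvotes_errors(self):
        other = "GTTGAACGACCACGA"
        hits = [
            ExtractionHit("c1", "u1", "ok", VALID_SUFFIX),
            ExtractionHit("c1", "u1", "ok", VALID_SUFFIX),
            ExtractionHit("c1", "u1", "ok", other),
        ]
        table = dedup_and_resolve(hits)
        assert table.assignments.iloc[0].tolist() == ["c1", VALID_SUFFIX, 1]


class TestPipelineOnSyntheticReads:
    def test_noise_free_recovery_is_exact(self, blueprint):
        props, _, truth = synthetic.simulate_trajectories(
            synthetic.SimScenario(n_clones=40, seed=11), blueprint
        )
        cells = synthetic.assign_cells(list(props.index), 120, seed=12)
        reads, _ = synthetic.simulate_tagged_reads(cells, blueprint, seed=13)
        table = extract_all(reads, blueprint)
        recovered = dict(zip(table.assignments.cell_tag, table.assignments.clone_id))
        assert recovered == cells
        assert (table.assignments["clone_id"].str.len() == 15).all()

    def test_status_counts_partition_reads(self, blueprint):
        cells = {f"c{i}": "GTTGAACGACCACAA" for i in range(30)}
        reads, _ = synthetic.simulate_tagged_reads(
            cells, blueprint, depth=4, no_anchor_rate=0.2,
            empty_vector_rate=0.2, seed=5,
        )
        table = extract_all(reads, blueprint)
        counts = table.qc["status_counts"]
        assert sum(counts.values()) == table.qc["n_reads"] == len(reads)
        assert counts["no_anchor"] > 0 and counts["empty_vector"] > 0

    def test_all_empty_vector_assigns_nothing(self, blueprint):
        cells = {f"c{i}": "GTTGAACGACCACAA" for i in range(10)}
        reads, _ = synthetic.simulate_tagged_reads(
            cells, blueprint, depth=3, empty_vector_rate=1.0, seed=5
        )
        table = extract_all(reads, blueprint)
        assert table.qc["status_counts"]["empty_vector"] == len(reads)
        assert table.qc["cells_assigned"] == 0

    def test_umi_consensus_accuracy_under_sequencing_errors(self, blueprint):
        props, _, _ = synthetic.simulate_trajectories(
            synthetic.SimScenario(n_clones=30, seed=21), blueprint
        )
        cells = synthetic.assign_cells(list(props.index), 150, seed=22)
        reads, _ = synthetic.simulate_tagged_reads(
            cells, blueprint, depth=7, reads_per_umi=3, error_rate=0.01, seed=23
        )
        table = extract_all(reads, blueprint, min_umi_support=1)
        assigned = dict(zip(table.assignments.cell_tag, table.assignments.clone_id))
        correct = sum(assigned[c] == cells[c] for c in assigned)
        assert len(assigned) > 0
        assert correct / len(assigned) >= 0.99

    def test_multi_clone_cells_are_flagged(self, blueprint):
        props, _, _ = synthetic.simulate_trajectories(
            synthetic.SimScenario(n_clones=20, seed=31), blueprint
        )
        cells = synthetic.assign_cells(list(props.index), 60, seed=32)
        reads, truth = synthetic.simulate_tagged_reads(
            cells, blueprint, depth=6, multi_clone_cell_rate=0.5, seed=33
        )
        planted = {k.split(":", 1)[1] for k, v in truth.decoy_reads.items()
                   if v == "multi_clone_cell"}
        table = extract_all(reads, blueprint)
        assert table.qc["cells_multi_barcode"] == len(planted)
        assert not planted & set(table.assignments.cell_tag)


class TestReaders:
    def test_fastq_sam_round_trip_agree(self, tmp_path, blueprint):
        cells = {f"c{i}": "GTTGAACGACCACAA" for i in range(5)}
        reads, _ = synthetic.simulate_tagged_reads(cells, blueprint, depth=2, seed=3)
        fq = tmp_path / "r.fastq"
        sam = tmp_path / "r.sam"
        synthetic.write_fastq(reads, str(fq))
        synthetic.write_sam(reads, str(sam))
        from_fq = sorted((r.read_id, r.seq, r.cell_tag, r.umi) for r in read_fastq_tagged(str(fq)))
        from_sam = sorted((r.read_id, r.seq, r.cell_tag, r.umi) for r in read_sam_tagged(str(sam)))
        assert from_fq == from_sam == sorted(
            (r.read_id, r.seq, r.cell_tag, r.umi) for r in reads
        )
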