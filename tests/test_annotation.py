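import numpy as np
import pytest

from conftest import iv, ps, tr

from utrx import (
    AnnotationTable,
    GenomicInterval,
    PipelineParameters,
    ValidationError,
    find_downstream_candidate,
    find_primary_probeset,
    remove_multimapping,
    select_representative_transcripts,
)


class TestRemoveMultimapping:
    def test_keeps_only_single_alignment_probesets_in_order(self):
        a = ps("A", iv("chr1", 0, 25))
        b = ps("B", iv("chr1", 0, 25), iv("chr2", 0, 25))
        c = ps("C", iv("chr2", 50, 75))
        assert remove_multimapping([a, b, c]) == [a, c]
        assert remove_multimapping([a, c]) == [a, c]
        assert remove_multimapping([b]) == []

    def test_idempotent(self):
        sets = [ps("A", iv("chr1", 0, 25)),
                ps("B", iv("chr1", 0, 25), iv("chr2", 0, 25))]
        once = remove_multimapping(sets)
        assert remove_multimapping(once) == once


class TestRepresentativeTranscripts:
    def test_plus_strand_takes_max_end(self):
        t1 = tr("T1", "geneG", "chr1", 0, 500)
        t2 = tr("T2", "geneG", "chr1", 0, 800)
        assert select_representative_transcripts([t1, t2]) == {"geneG": t2}

    def test_minus_strand_takes_min_start(self):
        t3 = tr("T3", "geneH", "chr1", 300, 900, "-")
        t4 = tr("T4", "geneH", "chr1", 100, 900, "-")
        assert select_representative_transcripts([t3, t4]) == {"geneH": t4}

    def test_tie_broken_by_smallest_id(self):
        t1 = tr("T2", "geneG", "chr1", 0, 500)
        t2 = tr("T1", "geneG", "chr1", 0, 500)
        assert select_representative_transcripts([t1, t2])["geneG"].id == "T1"

    def test_mixed_strand_symbol_rejected_with_diagnostic(self, caplog):
        t1 = tr("T1", "geneG", "chr1", 0, 500, "+")
        t2 = tr("T2", "geneG", "chr1", 0, 800, "-")
        with caplog.at_level("WARNING", logger="utrx"):
            out = select_representative_transcripts([t1, t2])
        assert out == {}
        assert "geneG" in caplog.text


class TestFindPrimary:
    def _setup(self, strand):
        t = tr("T1", "g", "chr1", 0, 1000, strand)
        near = ps("psA", iv("chr1", 100, 125, strand))
        far = ps("psB", iv("chr1", 400, 425, strand))
        ann = AnnotationTable({"psA": {"T1"}, "psB": {"T1"}})
        return t, near, far, ann

    def test_plus_strand_most_three_prime(self):
        t, near, far, ann = self._setup("+")
        assert find_primary_probeset(t, ann, [near, far]) is far

    def test_minus_strand_most_three_prime(self):
        t, near, far, ann = self._setup("-")
        assert find_primary_probeset(t, ann, [near, far]) is near

    def test_no_annotated_probeset_gives_none(self):
        t = tr("T1", "g", "chr1", 0, 1000)
        unrelated = ps("psA", iv("chr1", 100, 125))
        assert find_primary_probeset(t, AnnotationTable({}), [unrelated]) is None

    def test_tie_broken_by_id(self):
        t = tr("T1", "g", "chr1", 0, 1000)
        a = ps("psB", iv("chr1", 400, 425))
        b = ps("psA", iv("chr1", 400, 425))
        ann = AnnotationTable({"psA": {"T1"}, "psB": {"T1"}})
        assert find_primary_probeset(t, ann, [a, b]).id == "psA"


class TestDownstreamCandidate:
    def test_nearest_unannotated_on_plus(self):
        t = tr("T1", "g", "chr1", 0, 1030)
        primary = ps("p", iv("chr1", 1000, 1025))
        near = ps("x", iv("chr1", 1200, 1225))
        far = ps("y", iv("chr1", 5000, 5025))
        ann = AnnotationTable({"p": {"T1"}})
        assert find_downstream_candidate(t, primary, [primary, near, far], ann) is near

    def test_annotated_nearest_blocks_the_pair(self):
        t = tr("T1", "g", "chr1", 0, 1030)
        primary = ps("p", iv("chr1", 1000, 1025))
        near = ps("x", iv("chr1", 1200, 1225))
        far = ps("y", iv("chr1", 5000, 5025))
        ann = AnnotationTable({"p": {"T1"}, "x": {"T99"}})
        assert find_downstream_candidate(t, primary, [primary, near, far], ann) is None

    def test_minus_strand_downstream_is_lower_coordinates(self):
        t = tr("T1", "g", "chr1", 900, 2000, "-")
        primary = ps("p", iv("chr1", 1000, 1025, "-"))
        cand = ps("x", iv("chr1", 800, 825, "-"))
        ann = AnnotationTable({"p": {"T1"}})
        assert find_downstream_candidate(t, primary, [primary, cand], ann) is cand

    def test_abutting_or_overlapping_target_is_not_downstream(self):
        t = tr("T1", "g", "chr1", 0, 1030)
        primary = ps("p", iv("chr1", 1000, 1025))
        abutting = ps("x", iv("chr1", 1025, 1050))
        overlapping = ps("y", iv("chr1", 1010, 1040))
        ann = AnnotationTable({"p": {"T1"}})
        assert find_downstream_candidate(
            t, primary, [primary, abutting, overlapping], ann) is None

    def test_wrong_strand_ignored(self):
        t = tr("T1", "g", "chr1", 0, 1030)
        primary = ps("p", iv("chr1", 1000, 1025))
        anti = ps("x", iv("chr1", 1200, 1225, "-"))
        ann = AnnotationTable({"p": {"T1"}})
        assert find_downstream_candidate(t, primary, [primary, anti], ann) is None

    def test_overlap_mode_marks_transcript_covered_probesets_annotated(self):
        t = tr("T1", "g", "chr1", 0, 1030)
        t2 = tr("T2", "h", "chr1", 1100, 1400)
        primary = ps("p", iv("chr1", 1000, 1025))
        inside_t2 = ps("x", iv("chr1", 1200, 1225))
        ann = AnnotationTable({"p": {"T1"}})  # x has no table entry at all
        assert find_downstream_candidate(t, primary, [primary, inside_t2], ann) is inside_t2
        assert find_downstream_candidate(
            t, primary, [primary, inside_t2], ann,
            annotate_by_overlap=True, transcripts=[t, t2],
        ) is None


def test_pairing_is_strand_mirror_symmetric():
    """Reflecting all coordinates and flipping strands preserves pair triples."""
    rng = np.random.default_rng(11)
    c = 10**6

    def mirror_iv(i):
        return GenomicInterval(i.chrom, c - i.end, c - i.start,
                               "-" if i.strand == "+" else "+")

    for _ in range(20):
        t_start = int(rng.integers(0, 5000))
        t = tr("T1", "g", "chr1", t_start, t_start + 2000, "+")
        probes = [ps("p0", iv("chr1", t_start + 1500, t_start + 1525))]
        for k in range(5):
            s = int(rng.integers(0, 20000))
            probes.append(ps(f"q{k}", iv("chr1", s, s + 25)))
        ann = AnnotationTable({"p0": {"T1"}})

        t_m = tr("T1", "g", "chr1", *(lambda m: (m.start, m.end))(mirror_iv(t.span)), "-")
        probes_m = [type(p)(p.id, (mirror_iv(p.alignments[0]),)) for p in probes]

        def triple(transcript, probe_list):
            primary = find_primary_probeset(transcript, ann, probe_list)
            if primary is None:
                return None
            cand = find_downstream_candidate(transcript, primary, probe_list, ann)
            return (primary.id, cand.id if cand else None)

        assert triple(t, probes) == triple(t_m, probes_m)


def test_pipeline_parameters_validation():
    with pytest.raises(ValidationError):
        PipelineParameters(correlation_cutoff=1.5)
    with pytest.raises(ValidationError):
        PipelineParameters(n_random_sets=0)
    with pytest.raises(ValidationError):
        PipelineParameters(expression_threshold=float("nan"))
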