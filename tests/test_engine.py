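"""Submission validation, minting, instantiation, processing and QC."""

import random

import pytest

from termforge import engine as eng
from termforge import fixtures as fx
from termforge import ontology as onto
from termforge import patterns as pat
from termforge import templates as tpl
from termforge.errors import (
    AmbiguousLabelError, MintingError, UnknownEntityError,
)


class TestMinting:
    def test_incremental_format_and_advance(self):
        m = eng.IncrementalMinter("http://example.org/EX_", width=7, start=41)
        assert m.mint("x", set()) == "http://example.org/EX_0000041"
        assert m.counter == 42

    def test_random_mints_are_distinct_under_base_namespace(self):
        m = eng.RandomMinter("http://example.org/R_", random.Random(0))
        known = set()
        a = eng.mint_uri(m, known)
        b = eng.mint_uri(m, known)
        assert a != b
        assert a.startswith("http://example.org/R_")
        assert b.startswith("http://example.org/R_")

    def test_hundred_incremental_mints_strictly_increase(self):
        m = eng.IncrementalMinter("http://example.org/EX_", width=7, start=1)
        known = set()
        iris = [eng.mint_uri(m, known) for _ in range(100)]
        ids = [int(iri.rsplit("_", 1)[1]) for iri in iris]
        assert ids == list(range(1, 101))
        assert len(set(iris)) == 100

    def test_incremental_skips_existing_iris(self):
        known = {"http://example.org/EX_0000001"}
        m = eng.IncrementalMinter("http://example.org/EX_", width=7, start=1)
        assert m.mint("x", known) == "http://example.org/EX_0000002"

    def test_incremental_exhaustion_raises(self):
        m = eng.IncrementalMinter("http://example.org/EX_", width=1, start=9)
        m.mint("x", set())
        with pytest.raises(MintingError):
            m.mint("y", set())

    def test_state_file_persists_counter_across_runs(self, tmp_path):
        state = tmp_path / "uri-state.json"
        m1 = eng.IncrementalMinter("http://x/E_", width=5, start=1,
                                   state_file=state)
        first = [m1.mint(str(i), set()) for i in range(3)]
        m1.persist()
        m2 = eng.IncrementalMinter("http://x/E_", width=5, start=1,
                                   state_file=state)
        second = [m2.mint(str(i), set()) for i in range(3)]
        ids = [int(i.rsplit("_", 1)[1]) for i in first + second]
        assert ids == sorted(ids) and len(set(ids)) == 6

    def test_external_minter_is_pluggable_and_checked(self):
        m = eng.ExternalMinter(lambda label: f"http://x/{label}")
        assert m.mint("a", set()) == "http://x/a"
        with pytest.raises(MintingError):
            m.mint("a", {"http://x/a"})


class TestValidation:
    def test_missing_mandatory_cell_names_field_and_row(self, worked_example):
        we = worked_example
        sub = eng.Submission(we.submission.header, [
            {"New term": "", "parent": "blood cell", "definition": "d"}])
        issues = eng.validate_submission(we.template, sub, we.index)
        assert len(issues) == 1
        assert issues[0].row == 1 and issues[0].field == "New term"

    def test_known_parent_label_passes(self, worked_example):
        we = worked_example
        sub = eng.Submission(we.submission.header, [
            {"New term": "x cell", "parent": "blood cell",
             "definition": ""}])
        assert eng.validate_submission(we.template, sub, we.index) == []

    def test_out_of_list_restricted_value_is_error(self, worked_example):
        we = worked_example
        sub = eng.Submission(we.submission.header, [
            {"New term": "x cell", "parent": "unicorn cell",
             "definition": ""}])
        issues = eng.validate_submission(we.template, sub, we.index)
        assert len(issues) == 1
        assert issues[0].field == "parent" and "unicorn" in issues[0].message

    def test_empty_submission_has_no_errors(self, worked_example):
        we = worked_example
        sub = eng.Submission(we.submission.header, [])
        assert eng.validate_submission(we.template, sub, we.index) == []

    def test_header_mismatch_aborts(self, worked_example):
        we = worked_example
        sub = eng.Submission(("wrong", "columns"), [])
        with pytest.raises(eng.SubmissionError):
            eng.validate_submission(we.template, sub, we.index)


class TestResolveCell:
    def _setup(self, we):
        axset = onto.AxiomSet()
        minter = eng.make_minter(we.template.uri_policy)
        return axset, minter, {}, set(we.index.all_entities())

    def test_existing_label_reused_without_minting(self, worked_example):
        we = worked_example
        axset, minter, cache, known = self._setup(we)
        f = we.template.fields[0]
        bv = eng.resolve_cell("anucleate", f, we.index, minter, cache, known,
                              axset, we.template, pat.VariableType.CLASS)
        assert not bv.is_new
        assert bv.iri == we.class_iri("anucleate")
        assert len(axset) == 0 and not axset.new_terms

    def test_unknown_label_minted_with_label_annotation(self, worked_example):
        we = worked_example
        axset, minter, cache, known = self._setup(we)
        f = we.template.fields[0]
        bv = eng.resolve_cell("novel cell line X", f, we.index, minter,
                              cache, known, axset, we.template,
                              pat.VariableType.CLASS)
        assert bv.is_new and bv.iri.startswith(fx.WE_BASE)
        assert onto.Declaration(bv.iri, onto.EntityKind.CLASS) in axset
        assert onto.AnnotationAssertion(
            bv.iri, onto.RDFS_LABEL,
            onto.OwlLiteral("novel cell line X")) in axset
        assert axset.new_terms == [(bv.iri, "novel cell line X")]

    def test_same_label_in_two_rows_shares_one_iri(self, worked_example):
        we = worked_example
        axset, minter, cache, known = self._setup(we)
        f = we.template.fields[0]
        a = eng.resolve_cell("dup cell", f, we.index, minter, cache, known,
                             axset, we.template, pat.VariableType.CLASS, 3)
        b = eng.resolve_cell(" DUP  cell ", f, we.index, minter, cache,
                             known, axset, we.template,
                             pat.VariableType.CLASS, 7)
        assert a.iri == b.iri
        assert len(axset.new_terms) == 1

    def test_unknown_value_on_noncreating_field_is_error(self, worked_example):
        we = worked_example
        axset, minter, cache, known = self._setup(we)
        f = we.template.fields[1]  # parent: restricted, non-creating
        with pytest.raises(UnknownEntityError):
            eng.resolve_cell("unicorn", f, we.index, minter, cache, known,
                             axset, we.template, pat.VariableType.CLASS)

    def test_ambiguous_label_is_error(self, worked_example):
        we = worked_example
        idx = we.index
        idx2 = tpl.merge_indices([idx])
        idx2.label_collisions["ambiguous"] = ("http://x/a", "http://x/b")
        axset, minter, cache, known = self._setup(we)
        with pytest.raises(AmbiguousLabelError):
            eng.resolve_cell("ambiguous", we.template.fields[0], idx2,
                             minter, cache, known, axset, we.template,
                             pat.VariableType.CLASS)


class TestInstantiate:
    def test_cell_nucleation_with_blood_cell_and_anucleate(
            self, worked_example):
        we = worked_example
        p = fx.cell_nucleation_pattern()
        binding = eng.Binding(1)
        binding.bind("cell", eng.BoundValue(we.class_iri("blood cell")))
        binding.bind("nucleation", eng.BoundValue(we.class_iri("anucleate")))
        axioms = eng.instantiate(p, binding, we.template, we.index)
        assert axioms == [onto.SubClassOf(
            onto.Named(we.class_iri("blood cell")),
            onto.SomeValues(f"{fx.TOY_NS}hasNucleation",
                            onto.Named(we.class_iri("anucleate"))))]

    def test_annotation_pattern_with_constant(self, worked_example):
        we = worked_example
        p = we.template.patterns[1]  # ?newTerm.IRI definition ?definition
        binding = eng.Binding(1)
        minted = f"{fx.WE_BASE}0000100"
        binding.bind("newTerm", eng.BoundValue(minted, is_new=True))
        binding.bind("definition", "a made-up definition")
        axioms = eng.instantiate(p, binding, we.template, we.index)
        assert axioms == [onto.AnnotationAssertion(
            minted, onto.IAO_DEFINITION,
            onto.OwlLiteral("a made-up definition"))]

    def test_unbound_variable_is_error(self, worked_example):
        we = worked_example
        binding = eng.Binding(1)
        with pytest.raises(eng.ProcessingError):
            eng.instantiate(we.template.patterns[0], binding, we.template,
                            we.index)


class TestProcessSubmission:
    def test_worked_example_single_row_exact_axioms(self, tmp_path):
        we = fx.generate_worked_example(tmp_path, n_rows=1)
        axset, report = eng.process_submission(we.template, we.submission,
                                               we.index)
        assert axset == we.expected_axioms
        assert len(axset) == 4
        assert report.rows_ok == 1
        assert report.new_terms_minted == 1

    def test_worked_example_three_rows(self, worked_example):
        we = worked_example
        axset, report = eng.process_submission(we.template, we.submission,
                                               we.index)
        assert axset == we.expected_axioms
        assert axset.new_terms == we.expected_new_terms
        assert report.rows_ok == 3 and report.rows_error == 0
        # third row leaves the optional definition empty -> pattern skipped
        assert report.rows[2].patterns_skipped == ["definition"]

    def test_zero_rows_yield_empty_set(self, worked_example):
        we = worked_example
        sub = eng.Submission(we.submission.header, [])
        axset, report = eng.process_submission(we.template, sub, we.index)
        assert len(axset) == 0
        assert report.rows_processed == 0
        assert report.new_terms_minted == 0

    def test_axiom_count_formula_for_distinct_new_labels(self, worked_example):
        we = worked_example
        n = 7
        rows = [{"New term": f"counted cell {i}", "parent": "cell",
                 "definition": f"definition number {i}"} for i in range(n)]
        sub = eng.Submission(we.submission.header, rows)
        axset, report = eng.process_submission(we.template, sub, we.index)
        # n subclass + n definition (pattern axioms) + 2n bookkeeping
        assert len(axset) == 4 * n
        assert report.new_terms_minted == n

    def test_fail_fast_aborts_and_produces_nothing(self, worked_example):
        we = worked_example
        rows = [dict(we.submission.rows[0]),
                {"New term": "", "parent": "cell", "definition": ""}]
        sub = eng.Submission(we.submission.header, rows)
        axset, report = eng.process_submission(we.template, sub, we.index,
                                               mode="fail-fast")
        assert report.aborted
        assert len(axset) == 0 and report.axioms_generated == 0

    def test_partial_mode_processes_valid_rows_only(self, worked_example):
        we = worked_example
        rows = [dict(we.submission.rows[0]),
                {"New term": "", "parent": "cell", "definition": ""}]
        sub = eng.Submission(we.submission.header, rows)
        axset, report = eng.process_submission(we.template, sub, we.index,
                                               mode="partial")
        assert not report.aborted
        assert report.rows_error == 1 and report.rows_ok == 1
        assert len(axset) == 4
        # conservation: every axiom's provenance points at an ok row
        ok_rows = {r.row for r in report.rows if r.status == "ok"}
        for ax in axset:
            assert {row for row, _ in axset.provenance(ax)} <= ok_rows

    def test_incremental_runs_are_byte_identical(self, worked_example,
                                                 tmp_path):
        we = worked_example
        outs = []
        for name in ("a.ofn", "b.ofn"):
            axset, _ = eng.process_submission(we.template, we.submission,
                                              we.index)
            onto.serialize_axioms(axset, tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]

    def test_random_minting_is_isomorphic_up_to_renaming(self, worked_example):
        we = worked_example
        t = tpl.Template(
            name=we.template.name, fields=we.template.fields,
            patterns=we.template.patterns,
            uri_policy=tpl.UriPolicy("random", fx.WE_BASE),
            prefixes=dict(we.template.prefixes))
        a, _ = eng.process_submission(t, we.submission, we.index,
                                      rng=random.Random(1))
        b, _ = eng.process_submission(t, we.submission, we.index,
                                      rng=random.Random(2))
        rename = {ai: bi for (ai, _), (bi, _) in zip(a.new_terms, b.new_terms)}

        def apply(ax):
            if isinstance(ax, onto.Declaration):
                return onto.Declaration(rename.get(ax.iri, ax.iri), ax.kind)
            if isinstance(ax, onto.AnnotationAssertion):
                return onto.AnnotationAssertion(
                    rename.get(ax.subject, ax.subject), ax.prop, ax.value)
            if isinstance(ax, onto.SubClassOf):
                assert isinstance(ax.sub, onto.Named)
                return onto.SubClassOf(
                    onto.Named(rename.get(ax.sub.iri, ax.sub.iri)), ax.sup)
            raise AssertionError(ax)

        assert {apply(ax) for ax in a} == set(b.axioms)

    def test_reprocessing_against_updated_index_mints_nothing(
            self, worked_example):
        we = worked_example
        axset, _ = eng.process_submission(we.template, we.submission,
                                          we.index)
        updated = tpl.merge_indices([we.index])
        for iri, label in axset.new_terms:
            updated.classes.add(iri)
            updated.label_of[iri] = label
            updated.iri_of_label[onto.normalize_label(label)] = iri
        again, report = eng.process_submission(we.template, we.submission,
                                               updated)
        assert report.new_terms_minted == 0
        assert not again.new_terms

    def test_output_is_referentially_closed(self, worked_example):
        we = worked_example
        axset, _ = eng.process_submission(we.template, we.submission,
                                          we.index)
        assert axset.check_closure(we.index) == []
        declared = {ax.iri for ax in axset if isinstance(ax, onto.Declaration)}
        assert declared == {iri for iri, _ in axset.new_terms}


class TestQC:
    def test_duplicate_definitions_flagged(self, worked_example):
        we = worked_example
        rows = [{"New term": "qc cell 1", "parent": "cell",
                 "definition": "the same words"},
                {"New term": "qc cell 2", "parent": "cell",
                 "definition": "the same words"}]
        sub = eng.Submission(we.submission.header, rows)
        axset, report = eng.process_submission(we.template, sub, we.index)
        codes = [q.code for q in report.qc_issues]
        assert "duplicate-definition" in codes

    def test_minted_label_matching_source_label_flagged(self, worked_example):
        we = worked_example
        axset = onto.AxiomSet()
        axset.record_new_term("http://x/new", "blood cell")
        issues = eng.qc_axiomset(axset, we.index)
        assert any(q.code == "duplicate-label" for q in issues)

    def test_self_subclass_flagged(self, worked_example):
        axset = onto.AxiomSet()
        axset.add(onto.SubClassOf(onto.Named("http://x/a"),
                                  onto.Named("http://x/a")))
        issues = eng.qc_axiomset(axset, worked_example.index)
        assert any(q.code == "self-subclass" for q in issues)

    def test_clean_output_has_no_issues(self, worked_example):
        we = worked_example
        axset, report = eng.process_submission(we.template, we.submission,
                                               we.index)
        assert report.qc_issues == []
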