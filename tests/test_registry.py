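import datetime as dt
import itertools

import numpy as np
import pytest

from seqcode import (
    EntryStatus,
    ExternalName,
    Rank,
    Registry,
    TypeDesignation,
    TypeKind,
    attach_doi,
    export_json,
    import_json,
    parse_name,
    qc_report,
    register_draft,
    render_protologue,
    resolve_priority,
    validate_path2,
)
from seqcode.qc import GenomeCategory, QualityMetrics
from seqcode.registry import (
    RegistryError,
    SchemaError,
    StateError,
    reject_entry,
)
from seqcode.synthetic import generate_registry_fixture, passing_metrics


@pytest.fixture
def qc_pass():
    return qc_report(None, passing_metrics())


@pytest.fixture
def qc_fail():
    return qc_report(
        None, QualityMetrics(category=GenomeCategory.MAG, completeness_pct=85.0,
                             contamination_pct=7.0)
    )


def species_entry(reg, qc, name="Abcde fghij", path=1):
    return register_draft(
        reg,
        parse_name(name, Rank.SPECIES),
        TypeDesignation(kind=TypeKind.GENOME_ASSEMBLY, accession="GCA_000000001.1"),
        created_date=dt.date(2023, 5, 1),
        path=path,
        qc=qc,
    )


class TestRegisterDraft:
    def test_happy_path_promotes_to_provisionally_accepted(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)
        assert entry.status is EntryStatus.PROVISIONALLY_ACCEPTED

    def test_homonym_of_registered_name_rejected(self, qc_pass):
        reg = Registry()
        species_entry(reg, qc_pass)
        with pytest.raises(RegistryError, match="homonym"):
            species_entry(reg, qc_pass)

    def test_homonym_of_icnp_name_rejected(self, qc_pass):
        reg = Registry(external_names=[
            ExternalName(name_key="abcde fghij", priority_date=dt.date(2000, 1, 1))
        ])
        with pytest.raises(RegistryError, match="ICNP"):
            species_entry(reg, qc_pass)

    def test_rejected_entry_frees_its_homonym_key(self, qc_pass):
        reg = Registry()
        first = species_entry(reg, qc_pass)
        reject_entry(reg, first.entry_id, "curator decision")
        second = species_entry(reg, qc_pass)
        assert second.status is EntryStatus.PROVISIONALLY_ACCEPTED

    def test_ineligible_type_genome_rejected(self, qc_fail):
        reg = Registry()
        with pytest.raises(RegistryError, match="eligible"):
            species_entry(reg, qc_fail)

    def test_species_without_qc_rejected(self):
        reg = Registry()
        with pytest.raises(RegistryError, match="QC"):
            species_entry(reg, None)

    def test_rank_type_mismatch_rejected(self, qc_pass):
        reg = Registry()
        sp = species_entry(reg, qc_pass)
        with pytest.raises(RegistryError, match="typified"):
            register_draft(
                reg,
                parse_name("Klmno", Rank.GENUS),
                TypeDesignation(kind=TypeKind.GENOME_ASSEMBLY, accession="GCA_1.1"),
                created_date=dt.date(2023, 5, 1),
            )
        # and a dangling reference
        with pytest.raises(RegistryError, match="does not exist"):
            register_draft(
                reg,
                parse_name("Klmno", Rank.GENUS),
                TypeDesignation(kind=TypeKind.SPECIES_REF, ref_entry_id="nope"),
                created_date=dt.date(2023, 5, 1),
            )

    def test_name_with_error_findings_rejected(self, qc_pass):
        reg = Registry()
        with pytest.raises(RegistryError, match="nomenclature"):
            register_draft(
                reg,
                parse_name("abcde fghij", Rank.SPECIES),  # uncapitalized genus
                TypeDesignation(kind=TypeKind.GENOME_ASSEMBLY, accession="GCA_1.1"),
                created_date=dt.date(2023, 5, 1),
                qc=qc_pass,
            )


class TestPath1:
    def test_attach_doi_sets_priority_date(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)
        done = attach_doi(reg, entry.entry_id, "10.1038/s41564-022-01214-9",
                          dt.date(2022, 9, 19))
        assert done.status is EntryStatus.VALID
        assert done.priority_date == dt.date(2022, 9, 19)

    def test_malformed_doi_rejected(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)
        with pytest.raises(RegistryError, match="DOI"):
            attach_doi(reg, entry.entry_id, "doi:11.1234", dt.date(2023, 1, 1))

    def test_attach_doi_wrong_path(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass, path=2)
        with pytest.raises(StateError):
            attach_doi(reg, entry.entry_id, "10.1/x", dt.date(2023, 1, 1))


class TestPath2:
    def test_candidatus_name_validates_without_designation(self, qc_pass):
        reg = Registry()
        entry = register_draft(
            reg,
            parse_name("Candidatus Abcde fghij", Rank.SPECIES),
            TypeDesignation(kind=TypeKind.GENOME_ASSEMBLY, accession="GCA_2.1"),
            created_date=dt.date(2023, 2, 1),
            path=2,
            qc=qc_pass,
        )
        done = validate_path2(reg, entry.entry_id, dt.date(2023, 3, 1))
        assert done.status is EntryStatus.VALID
        assert done.priority_date == dt.date(2023, 3, 1)
        assert done.name.was_candidatus
        assert "Candidatus" not in done.name.full_name

    def test_candidatus_with_failing_genome_rejected(self, qc_fail):
        reg = Registry()
        with pytest.raises(RegistryError, match="eligible"):
            register_draft(
                reg,
                parse_name("Candidatus Abcde fghij", Rank.SPECIES),
                TypeDesignation(kind=TypeKind.GENOME_ASSEMBLY, accession="GCA_2.1"),
                created_date=dt.date(2023, 2, 1),
                path=2,
                qc=qc_fail,
            )


# --- explicit transition-table oracle -----------------------------------

ACTIONS = ("attach_doi", "validate_path2", "reject")


def oracle_step(state: str, action: str, path: int):
    """Returns the next state, or None when the action must raise."""
    if action == "reject":
        return "rejected" if state in ("draft", "provisionally_accepted") else None
    if action == "attach_doi":
        return (
            "valid"
            if state == "provisionally_accepted" and path == 1
            else None
        )
    if action == "validate_path2":
        return (
            "valid"
            if state == "provisionally_accepted" and path == 2
            else None
        )
    raise AssertionError(action)


def apply_action(reg, entry_id, action):
    if action == "attach_doi":
        attach_doi(reg, entry_id, "10.1234/x", dt.date(2024, 1, 1))
    elif action == "validate_path2":
        validate_path2(reg, entry_id, dt.date(2024, 1, 1))
    else:
        reject_entry(reg, entry_id, "test")


class TestStateMachine:
    @pytest.mark.parametrize("n_sequences", [300])
    def test_random_event_logs_match_transition_oracle(self, n_sequences, qc_pass):
        rng = np.random.default_rng(11)
        for i in range(n_sequences):
            path = int(rng.choice([1, 2]))
            reg = Registry()
            entry = species_entry(reg, qc_pass, path=path)
            state = entry.status.value  # provisionally_accepted
            for action in rng.choice(ACTIONS, size=rng.integers(1, 6)):
                expected = oracle_step(state, str(action), path)
                if expected is None:
                    with pytest.raises(StateError):
                        apply_action(reg, entry.entry_id, str(action))
                else:
                    apply_action(reg, entry.entry_id, str(action))
                    state = expected
                assert reg.get(entry.entry_id).status.value == state

    def test_no_exit_from_terminal_states(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)
        attach_doi(reg, entry.entry_id, "10.1/x", dt.date(2024, 1, 1))
        for action in ACTIONS:
            with pytest.raises(StateError):
                apply_action(reg, entry.entry_id, action)


class TestPriority:
    def records(self):
        return [
            ExternalName("aaa", dt.date(2024, 1, 1), source="ICNP"),
            ExternalName("bbb", dt.date(2023, 6, 1), source="ICNP"),
            ExternalName("ccc", dt.date(2025, 2, 2), source="ICNP"),
        ]

    def test_single_record_is_itself(self):
        recs = self.records()[:1]
        assert resolve_priority(recs)[0].label == "aaa"

    def test_earliest_date_wins(self):
        ordered = resolve_priority(self.records())
        assert [r.label for r in ordered] == ["bbb", "aaa", "ccc"]

    def test_invariant_under_permutation(self):
        base = resolve_priority(self.records())
        for perm in itertools.permutations(self.records()):
            assert resolve_priority(list(perm)) == base

    def test_seqcode_name_not_displaced_by_later_icnp_name(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)
        entry = attach_doi(reg, entry.entry_id, "10.1/x", dt.date(2023, 1, 1))
        icnp = ExternalName("later name", dt.date(2023, 5, 1), source="ICNP")
        ordered = resolve_priority([icnp, entry])
        assert ordered[0].source == "SeqCode"

    def test_date_tie_keeps_seqcode_first(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)
        entry = attach_doi(reg, entry.entry_id, "10.1/x", dt.date(2023, 5, 1))
        icnp = ExternalName("aaa", dt.date(2023, 5, 1), source="ICNP")
        ordered = resolve_priority([icnp, entry])
        assert [r.source for r in ordered] == ["SeqCode", "ICNP"]

    def test_missing_priority_date_rejected(self, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)  # provisionally accepted, no date
        with pytest.raises(RegistryError, match="priority date"):
            resolve_priority([entry])


class TestProtologue:
    def test_species_type_sentence_names_accession_with_ts(self, wolfra_registry):
        reg, species, genus, family = wolfra_registry
        text = render_protologue(reg, species.entry_id)
        assert "GCA_021323375.2^Ts" in text

    def test_genus_protologue_names_type_species(self, wolfra_registry):
        reg, species, genus, family = wolfra_registry
        text = render_protologue(reg, genus.entry_id)
        assert "Wolframiiraptor gerlachensis^Ts" in text

    def test_entry_without_description_has_two_blocks(self, wolfra_registry):
        reg, species, genus, family = wolfra_registry
        assert len(render_protologue(reg, species.entry_id).split("\n\n")) == 2

    GOLDEN = {
        "species": (
            "Wolframiiraptor gerlachensis^Ts (ger.lach.en'sis N.L. masc. adj. "
            "gerlachensis, of Gerlach, the town where Great Boiling Spring is "
            "located in Nevada)\n\n"
            "The genome available under the assembly accession number "
            "(GCA_021323375.2^Ts) is the designated nomenclatural type for the "
            "species."
        ),
        "genus": (
            "Wolframiiraptor (Wolf.ra.mi.i.rap'tor N.L. neut. n. wolframium, "
            "tungsten; L. masc. n. raptor, snatcher or thief)\n\n"
            "The nomenclatural type of the genus is "
            "Wolframiiraptor gerlachensis^Ts."
        ),
        "family": (
            "Wolframiiraptoraceae\n\n"
            "The nomenclatural type of the family is the genus Wolframiiraptor."
        ),
    }

    def test_golden_renders_for_three_ranks(self, wolfra_registry):
        reg, species, genus, family = wolfra_registry
        assert render_protologue(reg, species.entry_id) == self.GOLDEN["species"]
        assert render_protologue(reg, genus.entry_id) == self.GOLDEN["genus"]
        assert render_protologue(reg, family.entry_id) == self.GOLDEN["family"]


class TestJson:
    def test_empty_registry_round_trip(self, tmp_path):
        reg = Registry()
        export_json(reg, tmp_path / "reg.json")
        assert import_json(tmp_path / "reg.json") == reg

    def test_fixture_round_trip_deep_equality(self, tmp_path):
        reg, _ = generate_registry_fixture(100, seed=5)
        export_json(reg, tmp_path / "reg.json")
        again = import_json(tmp_path / "reg.json")
        assert again == reg
        # a second export is byte-identical
        export_json(again, tmp_path / "reg2.json")
        assert (tmp_path / "reg.json").read_text() == (tmp_path / "reg2.json").read_text()

    def test_unknown_status_value_is_schema_error(self, tmp_path, qc_pass):
        reg = Registry()
        species_entry(reg, qc_pass)
        export_json(reg, tmp_path / "reg.json")
        text = (tmp_path / "reg.json").read_text()
        (tmp_path / "bad.json").write_text(
            text.replace("provisionally_accepted", "pending_review")
        )
        with pytest.raises(SchemaError, match="status"):
            import_json(tmp_path / "bad.json")

    def test_at_most_one_active_entry_per_key_enforced_on_load(self, tmp_path, qc_pass):
        reg = Registry()
        entry = species_entry(reg, qc_pass)
        export_json(reg, tmp_path / "reg.json")
        import json as _json

        payload = _json.loads((tmp_path / "reg.json").read_text())
        clone = dict(payload["entries"][0])
        clone["entry_id"] = "other-id"
        payload["entries"].append(clone)
        (tmp_path / "dup.json").write_text(_json.dumps(payload))
        with pytest.raises(RegistryError, match="homonym"):
            import_json(tmp_path / "dup.json")
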