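"""Container round trips, protection flags, filenames, PED export."""

import json
from datetime import datetime

import pytest

from ftree.builder import build_pedigree
from ftree.docio import (
    PedigreeDocument,
    ReadOnlyError,
    UnknownVersionError,
    WrongPasswordError,
    default_filename,
    document_to_json,
    export_ped,
    read_document,
    save_document,
)
from ftree.fixtures import random_questionnaire, scenario_questionnaire
from ftree.model import KeyTable, LifeStage, Sex


@pytest.fixture
def doc(d_questionnaire, d_pedigree):
    return PedigreeDocument(pedigree=d_pedigree,
                            questionnaire=d_questionnaire)


class TestRoundTrip:
    def test_plain_save_read_identity(self, doc, tmp_path):
        path = save_document(doc, tmp_path / "fam.ftgc.json")
        again = read_document(path)
        assert document_to_json(again) == document_to_json(doc)

    def test_password_save_read_identity(self, doc, tmp_path):
        path = save_document(doc, tmp_path / "fam.ftgc.enc", password="pkU!7")
        again = read_document(path, password="pkU!7")
        assert document_to_json(again)["pedigree"] == \
            document_to_json(doc)["pedigree"]
        # ciphertext must not leak the payload
        raw = path.read_text()
        assert "questionnaire" not in raw
        assert "Hanako" not in raw

    def test_random_documents_round_trip(self, tmp_path):
        for seed in range(20):
            q = random_questionnaire(seed, consanguinity_rate=0.0)
            d = PedigreeDocument(pedigree=build_pedigree(q), questionnaire=q)
            path = save_document(d, tmp_path / f"r{seed}.ftgc.json")
            assert document_to_json(read_document(path)) == \
                document_to_json(d)

    def test_wrong_password_detected(self, doc, tmp_path):
        path = save_document(doc, tmp_path / "x.ftgc.enc", password="right")
        with pytest.raises(WrongPasswordError):
            read_document(path, password="wrong")
        with pytest.raises(WrongPasswordError):
            read_document(path)

    def test_tampering_detected(self, doc, tmp_path):
        path = save_document(doc, tmp_path / "x.ftgc.enc", password="pw")
        env = json.loads(path.read_text())
        ct = env["ciphertext"]
        env["ciphertext"] = ct[:-4] + ("AAAA" if ct[-4:] != "AAAA" else "BBBB")
        path.write_text(json.dumps(env))
        with pytest.raises(WrongPasswordError):
            read_document(path, password="pw")

    def test_unknown_version_rejected_with_clear_error(self, doc, tmp_path):
        path = save_document(doc, tmp_path / "v.ftgc.json")
        data = json.loads(path.read_text())
        data["format_version"] = "7.2"
        path.write_text(json.dumps(data))
        with pytest.raises(UnknownVersionError, match="7.2"):
            read_document(path)


class TestProtectionFlags:
    def test_read_only_blocks_resave(self, doc, tmp_path):
        path = save_document(doc, tmp_path / "ro.ftgc.json", read_only=True)
        assert read_document(path).read_only
        with pytest.raises(ReadOnlyError):
            save_document(doc, path)
        # explicit clear allows the overwrite
        save_document(doc, path, clear_read_only=True, read_only=False)
        assert not read_document(path).read_only

    def test_timestamp_override_recorded(self, doc, tmp_path):
        t = datetime(2017, 7, 14, 12, 0, 0)
        path = save_document(doc, tmp_path / "t.ftgc.json",
                             override_times=(t, t))
        again = read_document(path)
        assert again.created_at == t and again.modified_at == t
        assert again.times_overridden

    def test_normal_save_stamps_modified_after_created(self, doc, tmp_path):
        path = save_document(doc, tmp_path / "n.ftgc.json")
        again = read_document(path)
        assert again.created_at is not None
        assert again.modified_at >= again.created_at
        assert not again.times_overridden


class TestDefaultFilename:
    TS = datetime(2017, 7, 14)

    def make_doc(self, labels, d_pedigree, d_questionnaire):
        kt = KeyTable()
        for slot, label in enumerate(labels, start=1):
            kt.entry(slot).label = label
            kt.entry(slot).checked = True
        d_pedigree.key_table = kt
        return PedigreeDocument(pedigree=d_pedigree,
                                questionnaire=d_questionnaire)

    def test_first_ten_characters_of_each_checked_key(self, d_pedigree,
                                                      d_questionnaire):
        doc = self.make_doc(["Duchenne muscular dystrophy"], d_pedigree,
                            d_questionnaire)
        assert default_filename(doc, self.TS) == \
            "20170714_Duchenne m.ftgc.json"

    def test_short_labels_pass_unmodified(self, d_pedigree, d_questionnaire):
        doc = self.make_doc(["cancer", "stroke"], d_pedigree, d_questionnaire)
        assert default_filename(doc, self.TS) == \
            "20170714_cancer_stroke.ftgc.json"

    def test_no_checked_keys_datestamp_only(self, d_pedigree,
                                            d_questionnaire):
        doc = self.make_doc([], d_pedigree, d_questionnaire)
        assert default_filename(doc, self.TS) == "20170714.ftgc.json"

    def test_contributions_never_exceed_ten_characters(self, d_pedigree,
                                                       d_questionnaire):
        labels = ["a" * 40, "gastrointestinal disorder", "x"]
        doc = self.make_doc(labels, d_pedigree, d_questionnaire)
        name = default_filename(doc, self.TS)
        for part in name.removesuffix(".ftgc.json").split("_")[1:]:
            assert len(part) <= 10


def parse_ped(text):
    """Independent minimal PED reader used as the re-parse oracle."""
    rows = {}
    for line in text.strip().splitlines():
        fam, iid, father, mother, sex, aff = line.split("\t")
        rows[iid] = {"father": father, "mother": mother, "sex": sex,
                     "aff": aff, "fam": fam}
    return rows


class TestPedExport:
    def test_affected_boy_row(self, d_pedigree):
        rows = parse_ped(export_ped(d_pedigree, affection_key=1))
        boy = next(i for i in d_pedigree.individuals.values()
                   if i.is_proband)
        assert rows[boy.id]["sex"] == "1"
        assert rows[boy.id]["aff"] == "2"

    def test_founders_have_zero_parents(self, d_pedigree):
        rows = parse_ped(export_ped(d_pedigree))
        founders = [iid for iid in rows
                    if not d_pedigree.parents_of(iid)]
        assert founders
        for iid in founders:
            assert rows[iid]["father"] == "0"
            assert rows[iid]["mother"] == "0"

    def test_parent_references_resolve_in_file(self, ultimate_pedigree):
        rows = parse_ped(export_ped(ultimate_pedigree))
        for row in rows.values():
            for ref in (row["father"], row["mother"]):
                assert ref == "0" or ref in rows

    def test_losses_and_multiples_skipped(self, ultimate_pedigree, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ftree.docio"):
            rows = parse_ped(export_ped(ultimate_pedigree))
        skipped = [i for i in ultimate_pedigree.individuals.values()
                   if i.multiple_count != 1 or
                   i.life_stage in (LifeStage.SAB, LifeStage.TOP,
                                    LifeStage.ECTOPIC)]
        assert skipped
        for i in skipped:
            assert i.id not in rows
        assert len(caplog.records) == len(skipped)

    def test_reparse_isomorphic_to_exported_subgraph(self, ultimate_pedigree):
        p = ultimate_pedigree
        rows = parse_ped(export_ped(p, affection_key=1))
        sex_map = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
        for iid, row in rows.items():
            ind = p.individuals[iid]
            assert row["sex"] == sex_map[ind.sex]
            parents = {q for q in p.parents_of(iid) if q in rows}
            assert {row["father"], row["mother"]} - {"0"} == parents
            if 1 in ind.condition_keys:
                assert row["aff"] == "2"
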