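"""Document container: save/read pedigree documents, protection, PED export.

The container is versioned JSON holding the questionnaire (the source of
truth), the built pedigree, comments, timestamps and protection flags.  When
password-protected, the JSON payload is wrapped in an authenticated
encryption envelope: a PBKDF2-SHA256-derived key pair drives an
HMAC-SHA256-in-counter-mode keystream (encrypt) and an HMAC-SHA256 tag over
header and ciphertext (then-MAC), so a wrong password or a tampered file is
detected instead of yielding garbage.  Read-only is advisory metadata
enforced by this toolkit: saving over a read-only document fails unless the
flag is explicitly cleared.

Timestamps may be overridden (cohort intake often backfills paper sheets),
but an override is recorded in a ``times_overridden`` marker for provenance.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import logging
import os
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional

from .model import (
    Adoption,
    Comment,
    GameteRole,
    Individual,
    KeyTable,
    LifeStage,
    N_UNKNOWN,
    Pedigree,
    PREGNANCY_LOSS_STAGES,
    Sex,
    Sibship,
    TwinGroup,
    Union,
    UnionStatus,
    Custody,
    Zygosity,
)
from .questionnaire import (
    Questionnaire,
    questionnaire_from_json,
    questionnaire_to_json,
    _age_to_json,
    _age_from_json,
    _gest_to_json,
    _gest_from_json,
    _metadata_to_json,
    _metadata_from_json,
)

log = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"
CONTAINER_EXT = ".ftgc.json"
ENCRYPTED_EXT = ".ftgc.enc"
KDF_ITERATIONS = 120_000


class DocumentError(ValueError):
    pass


class WrongPasswordError(DocumentError):
    pass


class ReadOnlyError(DocumentError):
    pass


class UnknownVersionError(DocumentError):
    pass


@dataclass
class PedigreeDocument:
    pedigree: Pedigree
    questionnaire: Questionnaire
    created_at: Optional[datetime] = None
    modified_at: Optional[datetime] = None
    read_only: bool = False
    protection: str = "none"  # none | password
    times_overridden: bool = False
    format_version: str = FORMAT_VERSION


# ---------------------------------------------------------------------------
# pedigree (de)serialization


def _individual_to_json(i: Individual) -> dict:
    return {
        "id": i.id, "sex": i.sex.value, "name": i.name,
        "age": _age_to_json(i.age), "generation": i.generation,
        "life_stage": i.life_stage.value, "affected": i.affected,
        "condition_keys": list(i.condition_keys), "carrier": i.carrier,
        "presymptomatic_carrier": i.presymptomatic_carrier,
        "is_proband": i.is_proband, "is_consultand": i.is_consultand,
        "multiple_count": i.multiple_count, "adoption": i.adoption.value,
        "gamete_role": i.gamete_role.value,
        "history_unknown": i.history_unknown,
        "gestational_age": _gest_to_json(i.gestational_age),
        "annotations": list(i.annotations), "show_below": i.show_below,
        "order_key": i.order_key, "gen_label": i.gen_label,
        "number": i.number,
    }


def _individual_from_json(d: dict) -> Individual:
    mc = d.get("multiple_count", 1)
    return Individual(
        id=d["id"], sex=Sex(d.get("sex", "unknown")), name=d.get("name", ""),
        age=_age_from_json(d.get("age"), d["id"]),
        generation=int(d.get("generation", 3)),
        life_stage=LifeStage(d.get("life_stage", "living")),
        affected=bool(d.get("affected", False)),
        condition_keys=[int(k) for k in d.get("condition_keys", [])],
        carrier=bool(d.get("carrier", False)),
        presymptomatic_carrier=bool(d.get("presymptomatic_carrier", False)),
        is_proband=bool(d.get("is_proband", False)),
        is_consultand=bool(d.get("is_consultand", False)),
        multiple_count=mc if mc == N_UNKNOWN else int(mc),
        adoption=Adoption(d.get("adoption", "none")),
        gamete_role=GameteRole(d.get("gamete_role", "none")),
        history_unknown=bool(d.get("history_unknown", False)),
        gestational_age=_gest_from_json(d.get("gestational_age"), d["id"]),
        annotations=[str(a) for a in d.get("annotations", [])],
        show_below=str(d.get("show_below", "")),
        order_key=int(d.get("order_key", 0)),
        gen_label=str(d.get("gen_label", "")),
        number=int(d.get("number", 0)),
    )


def pedigree_to_json(p: Pedigree) -> dict:
    return {
        "individuals": [_individual_to_json(i) for i in p.individuals.values()],
        "unions": [{
            "id": u.id, "partner_a": u.partner_a, "partner_b": u.partner_b,
            "status": u.status.value, "consanguineous": u.consanguineous,
            "custody": u.custody.value,
            "no_children_by_choice": u.no_children_by_choice,
            "infertility": u.infertility,
        } for u in p.unions.values()],
        "sibships": [{
            "id": s.id, "union_id": s.union_id, "children": list(s.children),
            "twin_groups": [{"members": list(t.members),
                             "zygosity": t.zygosity.value}
                            for t in s.twin_groups],
        } for s in p.sibships.values()],
        "proband_id": p.proband_id,
        "consultand_ids": list(p.consultand_ids),
        "metadata": _metadata_to_json(p.metadata),
        "key_table": [{"label": e.label, "checked": e.checked,
                       "show_below_symbol": e.show_below_symbol,
                       "shade_index": e.shade_index}
                      for e in p.key_table.entries],
        "comments": [{"id": c.id, "text": c.text,
                      "anchor": c.anchor if isinstance(c.anchor, str)
                      else list(c.anchor)}
                     for c in p.comments],
    }


def pedigree_from_json(d: dict) -> Pedigree:
    from .model import KeyEntry

    p = Pedigree()
    for od in d.get("individuals", []):
        p.add(_individual_from_json(od))
    for od in d.get("unions", []):
        p.add(Union(id=od["id"], partner_a=od["partner_a"],
                    partner_b=od["partner_b"],
                    status=UnionStatus(od.get("status", "partnered")),
                    consanguineous=bool(od.get("consanguineous", False)),
                    custody=Custody(od.get("custody", "none")),
                    no_children_by_choice=bool(
                        od.get("no_children_by_choice", False)),
                    infertility=bool(od.get("infertility", False))))
    for od in d.get("sibships", []):
        p.add(Sibship(id=od["id"], union_id=od.get("union_id"),
                      children=list(od.get("children", [])),
                      twin_groups=[TwinGroup(members=list(t["members"]),
                                             zygosity=Zygosity(t["zygosity"]))
                                   for t in od.get("twin_groups", [])]))
    p.proband_id = d.get("proband_id")
    p.consultand_ids = list(d.get("consultand_ids", []))
    p.metadata = _metadata_from_json(d.get("metadata", {}))
    kt = d.get("key_table")
    if kt:
        p.key_table = KeyTable(entries=[
            KeyEntry(label=e.get("label", ""),
                     checked=bool(e.get("checked", False)),
                     show_below_symbol=bool(e.get("show_below_symbol", False)),
                     shade_index=int(e.get("shade_index", 0)))
            for e in kt])
    p.comments = [Comment(id=c["id"], text=c["text"],
                          anchor=c["anchor"] if isinstance(c["anchor"], str)
                          else tuple(c["anchor"]))
                  for c in d.get("comments", [])]
    return p


def document_to_json(d: PedigreeDocument) -> dict:
    return {
        "container": "ftgc",
        "format_version": d.format_version,
        "created_at": d.created_at.isoformat() if d.created_at else None,
        "modified_at": d.modified_at.isoformat() if d.modified_at else None,
        "read_only": d.read_only,
        "times_overridden": d.times_overridden,
        "questionnaire": questionnaire_to_json(d.questionnaire),
        "pedigree": pedigree_to_json(d.pedigree),
    }


def document_from_json(data: dict) -> PedigreeDocument:
    if data.get("container") != "ftgc":
        raise DocumentError("not a pedigree document container")
    version = data.get("format_version")
    if version != FORMAT_VERSION:
        raise UnknownVersionError(
            f"container version {version!r} is not supported by this release "
            f"(expected {FORMAT_VERSION}); upgrade the toolkit to read it")
    return PedigreeDocument(
        pedigree=pedigree_from_json(data.get("pedigree", {})),
        questionnaire=questionnaire_from_json(data["questionnaire"]),
        created_at=datetime.fromisoformat(data["created_at"])
        if data.get("created_at") else None,
        modified_at=datetime.fromisoformat(data["modified_at"])
        if data.get("modified_at") else None,
        read_only=bool(data.get("read_only", False)),
        protection="none",
        times_overridden=bool(data.get("times_overridden", False)),
        format_version=version,
    )


# ---------------------------------------------------------------------------
# authenticated password envelope


def _derive_keys(password: str, salt: bytes,
                 iterations: int) -> tuple[bytes, bytes]:
    km = hashlib.pbkdf2_hmac("sha256", password.encode("utf-8"), salt,
                             iterations, dklen=64)
    return km[:32], km[32:]


def _keystream_xor(key: bytes, nonce: bytes, data: bytes) -> bytes:
    out = bytearray(len(data))
    block = 32
    for i in range(0, len(data), block):
        ks = hmac.new(key, nonce + (i // block).to_bytes(8, "big"),
                      hashlib.sha256).digest()
        chunk = data[i:i + block]
        out[i:i + len(chunk)] = bytes(a ^ b for a, b in zip(chunk, ks))
    return bytes(out)


def _encrypt(payload: bytes, password: str, rng=None) -> dict:
    rand = rng.randbytes if rng is not None else os.urandom
    salt, nonce = rand(16), rand(16)
    enc_key, mac_key = _derive_keys(password, salt, KDF_ITERATIONS)
    ct = _keystream_xor(enc_key, nonce, payload)
    header = salt + nonce + KDF_ITERATIONS.to_bytes(4, "big")
    tag = hmac.new(mac_key, header + ct, hashlib.sha256).hexdigest()
    b64 = lambda b: base64.b64encode(b).decode("ascii")  # noqa: E731
    return {
        "container": "ftgc-enc",
        "format_version": FORMAT_VERSION,
        "kdf": {"algorithm": "pbkdf2-sha256", "salt": b64(salt),
                "iterations": KDF_ITERATIONS},
        "cipher": "hmac-sha256-ctr",
        "nonce": b64(nonce),
        "ciphertext": b64(ct),
        "mac": tag,
    }


def _decrypt(env: dict, password: Optional[str]) -> bytes:
    if password is None:
        raise WrongPasswordError("document is password-protected")
    version = env.get("format_version")
    if version != FORMAT_VERSION:
        raise UnknownVersionError(f"envelope version {version!r} not supported")
    try:
        salt = base64.b64decode(env["kdf"]["salt"])
        iterations = int(env["kdf"]["iterations"])
        nonce = base64.b64decode(env["nonce"])
        ct = base64.b64decode(env["ciphertext"])
        tag = env["mac"]
    except (KeyError, ValueError) as e:
        raise DocumentError(f"corrupt envelope: {e}") from None
    enc_key, mac_key = _derive_keys(password, salt, iterations)
    header = salt + nonce + iterations.to_bytes(4, "big")
    expect = hmac.new(mac_key, header + ct, hashlib.sha256).hexdigest()
    if not hmac.compare_digest(expect, tag):
        raise WrongPasswordError("wrong password or tampered document")
    return _keystream_xor(enc_key, nonce, ct)


# ---------------------------------------------------------------------------
# save / read


def save_document(d: PedigreeDocument, path, password: Optional[str] = None,
                  read_only: Optional[bool] = None,
                  override_times: Optional[tuple[datetime, datetime]] = None,
                  clear_read_only: bool = False, _rng=None) -> Path:
    """Write the container; refuses to overwrite a read-only document unless
    ``clear_read_only`` is set."""
    path = Path(path)
    if path.exists() and not clear_read_only:
        try:
            existing = json.loads(path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError):
            existing = {}
        if existing.get("read_only") or existing.get("container") == "ftgc-enc":
            # an encrypted container cannot prove it is writable; require an
            # explicit clear_read_only only when the plain flag is set
            if existing.get("read_only"):
                raise ReadOnlyError(
                    f"{path} is saved read-only; pass clear_read_only=True "
                    "to replace it")
    now = datetime.now().replace(microsecond=0)
    if override_times is not None:
        d.created_at, d.modified_at = override_times
        d.times_overridden = True
    else:
        d.created_at = d.created_at or now
        d.modified_at = now
    if read_only is not None:
        d.read_only = read_only
    d.protection = "password" if password else "none"
    payload = json.dumps(document_to_json(d), indent=2,
                         ensure_ascii=False).encode("utf-8")
    if password:
        env = _encrypt(payload, password, rng=_rng)
        path.write_text(json.dumps(env, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_bytes(payload + b"\n")
    return path


def read_document(path, password: Optional[str] = None) -> PedigreeDocument:
    """Inverse of :func:`save_document`; authenticates protected containers."""
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise DocumentError(f"corrupt container {path}: {e}") from None
    if data.get("container") == "ftgc-enc":
        payload = _decrypt(data, password)
        try:
            data = json.loads(payload.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as e:
            raise DocumentError(f"corrupt encrypted payload: {e}") from None
        doc = document_from_json(data)
        doc.protection = "password"
        return doc
    return document_from_json(data)


# ---------------------------------------------------------------------------
# filenames


FILENAME_KEY_CHARS = 10


def default_filename(d: PedigreeDocument, timestamp: datetime) -> str:
    """Datestamp plus the first ten characters of every checked key label, in
    key-slot order, joined by underscores — so saved files sort and search by
    the conditions they document."""
    parts = [timestamp.strftime("%Y%m%d")]
    parts += [e.label[:FILENAME_KEY_CHARS]
              for e in d.pedigree.key_table.entries if e.checked and e.label]
    return "_".join(parts) + CONTAINER_EXT


# ---------------------------------------------------------------------------
# PED / LINKAGE export


def _ped_clean(s: str) -> str:
    return "".join(c if not c.isspace() else "_" for c in s) or "FAM1"


def export_ped(p: Pedigree, affection_key: int = 1) -> str:
    """Six-column PED text: family, individual, father, mother, sex,
    affection.

    Multiple-individual nodes and pregnancy losses cannot carry genotype rows
    and are skipped with a logged warning; parent references always resolve
    within the file (a skipped parent exports as founder 0).
    """
    fam = _ped_clean(p.metadata.family_names)
    skipped: set[str] = set()
    for i in p.individuals.values():
        if i.multiple_count != 1:
            log.warning("PED export: skipping multiple-individuals node %s",
                        i.id)
            skipped.add(i.id)
        elif i.life_stage in PREGNANCY_LOSS_STAGES:
            log.warning("PED export: skipping pregnancy-loss node %s", i.id)
            skipped.add(i.id)
    rows = []
    for i in p.individuals.values():
        if i.id in skipped:
            continue
        father = mother = "0"
        parents = [p.individuals[q] for q in p.parents_of(i.id)
                   if q not in skipped]
        males = [x for x in parents if x.sex == Sex.MALE]
        females = [x for x in parents if x.sex == Sex.FEMALE]
        rest = [x for x in parents if x not in males and x not in females]
        f = males[0] if males else (rest[0] if rest else None)
        m = females[0] if females else (
            rest[-1] if rest and rest[-1] is not f else None)
        if f is not None:
            father = f.id
        if m is not None:
            mother = m.id
        sex = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[i.sex]
        born = i.life_stage in (LifeStage.LIVING, LifeStage.DECEASED,
                                LifeStage.STILLBIRTH)
        if affection_key in i.condition_keys:
            aff = "2"
        elif born and not i.affected:
            aff = "1"
        else:
            aff = "0"
        rows.append("\t".join([fam, i.id, father, mother, sex, aff]))
    return "\n".join(rows) + ("\n" if rows else "")
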