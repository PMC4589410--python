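"""FASTA input/output and the FSD text file format.

The FSD file is a deliberately plain, auditable text format (version 1):

.. code-block:: text

    #FSD 1
    #PARAMS key=value ...
    #REF <id> <name> <length> <sha1>      one per manifest entry
    #FREF <id> <name>                     factorized-reference section
    <ref_id>\t<start>\t<length>\t<mismatch>
    ...
    #SEQ <name>                           sequence section
    <ref_id>\t<start>\t<length>\t<mismatch>
    ...

Manifest ids are dense from 0 with raw references first; an id is
"factorized" exactly when a ``#FREF`` section carries it.  The SHA-1 of
every unfolded sequence is stored so that unfolding against the wrong
reference file fails fast with a checksum error rather than producing
garbage.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (FSD, RME, Factorization, ManifestEntry, ReferenceSet,
                    sha1_of, unfold, validate_sequence, _ALPHABET_SET)

FSD_VERSION = 1

_SANITIZE_RE = re.compile(r"[^ACGTN]")


class FSDError(Exception):
    """Base class for FSD file errors."""


class FSDFormatError(FSDError):
    """Malformed or wrong-version FSD file, or a dangling reference id."""


class ChecksumError(FSDError):
    """Unfolded sequence does not match its manifest checksum."""


def read_fasta(path, sanitize: bool = False) -> list[tuple[str, str]]:
    """Read a FASTA file to ``(name, sequence)`` pairs.

    Names are the first whitespace-delimited header token; sequences are
    folded to uppercase.  Characters outside {A,C,G,T,N} raise unless
    ``sanitize`` maps them to N.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if sanitize:
            seq = _SANITIZE_RE.sub("N", seq)
        validate_sequence(seq, f"record {rec.id!r}")
        out.append((rec.id, seq))
    return out


def write_fasta(items: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def _rme_lines(f: Factorization) -> list[str]:
    return [f"{r.ref_id}\t{r.start}\t{r.length}\t{r.mismatch}" for r in f.rmes]


def write_fsd(fsd: FSD, path) -> None:
    lines = [f"#FSD {FSD_VERSION}"]
    if fsd.params:
        kv = " ".join(f"{k}={v}" for k, v in fsd.params.items())
        lines.append(f"#PARAMS {kv}")
    for e in fsd.manifest:
        lines.append(f"#REF {e.ref_id} {e.name} {e.length} {e.sha1}")
    n_raw = fsd.n_raw
    for r, f in enumerate(fsd.factorized_refs):
        lines.append(f"#FREF {n_raw + r} {f.seq_name}")
        lines.extend(_rme_lines(f))
    for f in fsd.factorizations:
        lines.append(f"#SEQ {f.seq_name}")
        lines.extend(_rme_lines(f))
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_fsd(path) -> FSD:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#FSD"):
        raise FSDFormatError(f"{path}: missing #FSD header")
    version = lines[0].split()[1:]
    if version != [str(FSD_VERSION)]:
        raise FSDFormatError(f"{path}: unsupported FSD version {version}")
    params: dict = {}
    manifest: list[ManifestEntry] = []
    factorized_refs: list[Factorization] = []
    factorizations: list[Factorization] = []
    fref_ids: list[int] = []
    current: list[RME] | None = None
    for ln in lines[1:]:
        if ln.startswith("#PARAMS"):
            for kv in ln.split()[1:]:
                k, _, v = kv.partition("=")
                params[k] = _coerce(v)
        elif ln.startswith("#REF "):
            parts = ln.split()
            if len(parts) != 5:
                raise FSDFormatError(f"malformed manifest line: {ln!r}")
            manifest.append(ManifestEntry("raw", int(parts[1]), parts[2],
                                          int(parts[3]), parts[4]))
        elif ln.startswith("#FREF "):
            parts = ln.split()
            if len(parts) != 3:
                raise FSDFormatError(f"malformed #FREF line: {ln!r}")
            if factorizations:
                raise FSDFormatError("#FREF section after #SEQ section")
            current = []
            fref_ids.append(int(parts[1]))
            factorized_refs.append(Factorization(parts[2], current))
        elif ln.startswith("#SEQ "):
            name = ln.split(maxsplit=1)[1]
            current = []
            factorizations.append(Factorization(name, current))
        elif ln.startswith("#"):
            raise FSDFormatError(f"unknown header line: {ln!r}")
        else:
            if current is None:
                raise FSDFormatError(f"RME line outside a section: {ln!r}")
            parts = ln.split("\t")
            if len(parts) != 4 or len(parts[3]) != 1 or parts[3] not in _ALPHABET_SET:
                raise FSDFormatError(f"malformed RME line: {ln!r}")
            current.append(RME(int(parts[0]), int(parts[1]), int(parts[2]), parts[3]))

    ids = [e.ref_id for e in manifest]
    if ids != list(range(len(ids))):
        raise FSDFormatError("manifest ids are not dense from 0")
    for i in fref_ids:
        if i not in ids:
            raise FSDFormatError(f"#FREF id {i} not in manifest")
        manifest[i].kind = "factorized"
    n_raw = sum(1 for e in manifest if e.kind == "raw")
    if sorted(fref_ids) != list(range(n_raw, n_raw + len(fref_ids))):
        raise FSDFormatError("factorized ids must follow the raw ids densely")
    n_total = len(manifest)
    for f in factorized_refs:
        for rme in f.rmes:
            if not 0 <= rme.ref_id < n_raw:
                raise FSDFormatError(
                    f"dangling id {rme.ref_id} in factorized reference {f.seq_name!r}")
    for f in factorizations:
        for rme in f.rmes:
            if not 0 <= rme.ref_id < n_total:
                raise FSDFormatError(
                    f"dangling id {rme.ref_id} in factorization {f.seq_name!r}")
    return FSD(manifest, factorized_refs, factorizations, params=params)


def unfold_file(fsd_path, refs_path, out_path, sanitize: bool = False) -> int:
    """Unfold an FSD file against a reference FASTA; write a FASTA.

    Raw manifest entries are matched by name in the reference file and
    verified against the manifest SHA-1 (a mismatch signals the wrong
    reference file); factorized references are unfolded and verified the
    same way.  Returns the number of sequences written.
    """
    fsd = read_fsd(fsd_path)
    available = dict(read_fasta(refs_path, sanitize=sanitize))
    raw_items: list[tuple[str, str]] = []
    for e in fsd.manifest:
        if e.kind != "raw":
            continue
        seq = available.get(e.name)
        if seq is None:
            raise ChecksumError(f"reference {e.name!r} not found in {refs_path}")
        if sha1_of(seq) != e.sha1:
            raise ChecksumError(
                f"reference {e.name!r} does not match the manifest checksum")
        raw_items.append((e.name, seq))
    refs = ReferenceSet(raw_items)
    n_raw = len(raw_items)
    for r, f in enumerate(fsd.factorized_refs):
        uf = fsd.unfolded_reference(r, refs)
        entry = fsd.manifest[n_raw + r]
        if sha1_of(uf) != entry.sha1:
            raise ChecksumError(
                f"factorized reference {entry.name!r} fails its checksum")
    out = [(f.seq_name, unfold(f, refs, fsd)) for f in fsd.factorizations]
    write_fasta(out, out_path)
    return len(out)
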