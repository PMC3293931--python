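"""FASTA input/output and RNA sequence records.

Mature miRNAs and query transcripts are held as immutable, U-normalized
records (uppercase, T converted to U).  Ambiguity codes are rejected rather
than masked: downstream dinucleotide densities and duplex scoring have no
defined semantics for N, so we fail loudly at parse time.

Coordinates are 0-based half-open everywhere inside the package; only
user-facing writers convert to 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Literal, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FastaParseError, InvariantError

RNA_ALPHABET = frozenset("ACGU")
_ALLOWED_INPUT = frozenset("ACGUTacgut")

MIRNA_MIN_LEN = 15
MIRNA_MAX_LEN = 30


def normalize_rna(s: str) -> str:
    """Uppercase and convert T to U; reject anything outside A/C/G/U/T.

    Ambiguity codes (N, R, Y, ...) raise :class:`AlphabetError` naming the
    1-based offending position.  Idempotent on already-normalized input.
    """
    for i, ch in enumerate(s):
        if ch not in _ALLOWED_INPUT:
            raise AlphabetError(
                f"illegal character {ch!r} at position {i + 1} "
                "(only A/C/G/U/T accepted; ambiguity codes are rejected)"
            )
    return s.upper().replace("T", "U")


def _check_id(identifier: str) -> None:
    if not identifier or re.search(r"\s", identifier):
        raise InvariantError(f"record id must be non-empty without whitespace: {identifier!r}")


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA sequence, 5'->3', 15-30 nt."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        _check_id(self.id)
        if not (MIRNA_MIN_LEN <= len(self.seq) <= MIRNA_MAX_LEN):
            raise InvariantError(
                f"miRNA {self.id!r}: length {len(self.seq)} outside "
                f"[{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}]"
            )
        if not set(self.seq) <= RNA_ALPHABET:
            raise AlphabetError(f"miRNA {self.id!r}: non-RNA characters in sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptRecord:
    """A query mRNA/transcript sequence, 5'->3'."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        _check_id(self.id)
        if len(self.seq) < 1:
            raise InvariantError(f"transcript {self.id!r}: empty sequence")
        if not set(self.seq) <= RNA_ALPHABET:
            raise AlphabetError(f"transcript {self.id!r}: non-RNA characters in sequence")

    def __len__(self) -> int:
        return len(self.seq)


Record = Union[MiRNARecord, TranscriptRecord]


def read_fasta(path: Union[str, Path], kind: Literal["mirna", "transcript"]) -> List[Record]:
    """Read a multi-record FASTA file into validated, normalized records.

    File order is preserved; duplicate IDs are rejected.  ``kind`` selects
    the record type and hence which invariants (e.g. miRNA length) apply.
    """
    if kind not in ("mirna", "transcript"):
        raise ValueError(f"kind must be 'mirna' or 'transcript', got {kind!r}")
    path = Path(path)
    text = path.read_text()
    stripped = text.strip()
    if not stripped:
        raise FastaParseError(f"{path}: empty FASTA input")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header starting with '>'"
                )
            break

    records: List[Record] = []
    seen = set()
    cls = MiRNARecord if kind == "mirna" else TranscriptRecord
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            seq = normalize_rna(str(rec.seq))
        except AlphabetError as exc:
            raise AlphabetError(f"record {rec.id!r}: {exc}") from exc
        records.append(cls(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[Record], path: Union[str, Path], width: int = 70) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
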