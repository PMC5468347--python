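"""Sequence input, N-terminal window extraction and redundancy reduction.

Secretory preproteins carry a cleavable N-terminal signal peptide; the
polypeptide left after signal-peptidase cleavage is the mature domain.
Everything downstream in this package operates on fixed-length N-terminal
windows of one of two kinds:

``preprotein``
    residues 1..W of the unprocessed chain (signal peptide included).
``mature``
    residues (cleavage_pos + 3)..(cleavage_pos + 2 + W).  The first two
    mature-domain positions are skipped deliberately: they carry conserved
    cleavage-site motifs (e.g. the lipoprotein +1 Cys) rather than bulk
    mature-domain information.

Coordinates are 1-based and inclusive throughout; ``cleavage_pos`` is the
index of the *last* signal-peptide residue.

Redundancy reduction follows Hobohm's algorithm 2: build a neighbour graph
over pairs whose percent identity (within the first 100 residues) exceeds a
cutoff, then repeatedly drop the sequence with the most neighbours until no
edge remains.  Secretory and cytoplasmic sequences are reduced separately.
Identity is computed from a deterministic global alignment (match=1,
mismatch=0, linear gap penalty -1) of the truncated pair.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)
GAP = "-"
#: rare non-standard one-letter codes that may appear in proteome FASTA files
NONSTANDARD = frozenset("XBZUOJ")

VALID_LABELS = ("secretory", "cytoplasmic", "unknown", "non_secretory")


class FastaParseError(ValueError):
    pass


class LabelError(ValueError):
    pass


@dataclass
class SequenceRecord:
    """One protein: identifier, sequence, class label, optional cleavage site.

    ``cleavage_pos`` is the 1-based index of the last signal-peptide residue
    and must be absent for cytoplasmic proteins.
    """

    id: str
    seq: str
    label: str = "unknown"
    cleavage_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label not in VALID_LABELS:
            raise LabelError(f"record {self.id!r}: unknown label token {self.label!r}")
        if self.cleavage_pos is not None:
            if not (1 <= self.cleavage_pos < len(self.seq)):
                raise ValueError(
                    f"record {self.id!r}: cleavage_pos {self.cleavage_pos} outside "
                    f"1..{len(self.seq) - 1}"
                )
            if self.label == "cytoplasmic":
                raise ValueError(
                    f"record {self.id!r}: cytoplasmic protein cannot carry a "
                    "cleavage position"
                )


@dataclass
class Window:
    """A fixed-length N-terminal sequence window, right-padded with '-'."""

    source_id: str
    kind: str  # "preprotein" | "mature"
    residues: str
    start_pos: int
    short: bool = field(default=False)  # fewer non-gap residues than useful

    def __post_init__(self) -> None:
        if self.kind not in ("preprotein", "mature"):
            raise ValueError(f"unknown window kind {self.kind!r}")
        stripped = self.residues.rstrip(GAP)
        if GAP in stripped:
            raise ValueError("window padding must be a contiguous suffix")

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into records with unknown labels.

    Sequences are upper-cased and trailing '*' stop symbols stripped.
    Raises :class:`FastaParseError` naming the offending line on malformed
    input and on empty files.
    """
    with open(path) as fh:
        lines = fh.readlines()
    seen_header = False
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise FastaParseError(
                f"{path}: line {i}: sequence data before any '>' header: {line.strip()!r}"
            )
    if not seen_header:
        raise FastaParseError(f"{path}: no FASTA records found")

    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise FastaParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        records.append(SequenceRecord(id=entry.id, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_labels(path, records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Attach labels/cleavage positions from a TSV (id, label, cleavage_pos).

    A header line starting with ``id`` is permitted and skipped.  Ids present
    in the TSV but absent from ``records`` trigger a warning.  Duplicate ids
    and unknown label tokens are errors.  A secretory row may leave
    cleavage_pos empty; requesting a mature window for it fails later.
    """
    table: dict[str, tuple[str, Optional[int]]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row_no, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row_no == 1 and row[0].strip().lower() == "id":
                continue
            if len(row) < 2:
                raise LabelError(f"{path}: row {row_no}: expected id<TAB>label[<TAB>cleavage]")
            rid, label = row[0].strip(), row[1].strip().lower().replace("-", "_")
            if label not in VALID_LABELS:
                raise LabelError(f"{path}: row {row_no}: unknown label token {row[1]!r}")
            cleavage: Optional[int] = None
            if len(row) > 2 and row[2].strip():
                cleavage = int(row[2])
            if rid in table:
                raise LabelError(f"{path}: duplicate id {rid!r}")
            table[rid] = (label, cleavage)

    by_id = {rec.id for rec in records}
    missing = [rid for rid in table if rid not in by_id]
    if missing:
        warnings.warn(
            f"{path}: {len(missing)} labelled id(s) absent from FASTA: "
            + ", ".join(missing[:5]),
            stacklevel=2,
        )
    out = []
    for rec in records:
        if rec.id in table:
            label, cleavage = table[rec.id]
            out.append(SequenceRecord(rec.id, rec.seq, label, cleavage))
        else:
            out.append(rec)
    return out


def write_labels(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\tcleavage_pos\n")
        for rec in records:
            cp = "" if rec.cleavage_pos is None else str(rec.cleavage_pos)
            fh.write(f"{rec.id}\t{rec.label}\t{cp}\n")


#: mature windows start this many residues past the cleavage position
MATURE_OFFSET = 3
DEFAULT_W_PRE = 84
DEFAULT_W_MAT = 80


def extract_window(
    record: SequenceRecord,
    kind: str,
    W: int,
    min_useful: int = 20,
) -> Window:
    """Extract the N-terminal window of the requested kind.

    Preprotein windows start at position 1; mature windows at
    ``cleavage_pos + 3``.  Residues beyond the sequence end are padded with
    '-'; windows with fewer than ``min_useful`` real residues get the
    ``short`` flag.
    """
    if W < 1:
        raise ValueError("window length must be positive")
    if kind == "preprotein":
        start = 1
    elif kind == "mature":
        if record.cleavage_pos is None:
            raise ValueError(
                f"record {record.id!r}: mature window requested but no cleavage "
                "position is annotated"
            )
        start = record.cleavage_pos + MATURE_OFFSET
    else:
        raise ValueError(f"unknown window kind {kind!r}")
    body = record.seq[start - 1 : start - 1 + W]
    residues = body + GAP * (W - len(body))
    return Window(
        source_id=record.id,
        kind=kind,
        residues=residues,
        start_pos=start,
        short=len(body) < min_useful,
    )


def window_from_position(record: SequenceRecord, kind: str, W: int, start: int) -> Window:
    """Window of ``kind`` beginning at an arbitrary 1-based position.

    Used when scanning candidate cleavage sites and when scoring unannotated
    sequences in the mature view (start=1).
    """
    body = record.seq[start - 1 : start - 1 + W]
    residues = body + GAP * (W - len(body))
    return Window(record.id, kind, residues, start, short=len(body) < 20)


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = 0
    al.open_gap_score = -1
    al.extend_gap_score = -1
    return al


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str, span: int = 100) -> float:
    """Percent identity over a global alignment of the first ``span`` residues.

    identity = 100 * identical aligned positions / alignment length.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    # canonical argument order: the traceback picks one of possibly many
    # co-optimal alignments, so symmetry must hold by construction
    if b < a:
        a, b = b, a
    aln = _ALIGNER.align(a[:span], b[:span])[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def _reduce_indices(seqs: list[str], cutoff: float, span: int) -> list[int]:
    n = len(seqs)
    if n <= 1:
        return list(range(n))
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(seqs[i], seqs[j], span) > cutoff:
                adj[i, j] = adj[j, i] = True
    alive = np.ones(n, dtype=bool)
    while True:
        deg = (adj & alive[None, :]).sum(axis=1)
        deg[~alive] = -1
        top = deg.max()
        if top <= 0:
            break
        # tie-break: among max-degree members drop the latest input index,
        # which deterministically keeps earliest occurrences
        drop = np.flatnonzero((deg == top) & alive)[-1]
        alive[drop] = False
    return [i for i in range(n) if alive[i]]


def hobohm2_reduce(
    records: Sequence[SequenceRecord], cutoff: float = 40.0, span: int = 100
) -> list[SequenceRecord]:
    """Hobohm algorithm 2 redundancy reduction, per class.

    Secretory and cytoplasmic proteins are reduced separately; records with
    other labels form their own group.  Output preserves input order and no
    retained pair exceeds the identity cutoff.
    """
    if not records:
        raise ValueError("no records to reduce")
    groups: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        groups.setdefault(rec.label, []).append(idx)
    keep: set[int] = set()
    for indices in groups.values():
        seqs = [records[i].seq for i in indices]
        for local in _reduce_indices(seqs, cutoff, span):
            keep.add(indices[local])
    return [rec for i, rec in enumerate(records) if i in keep]
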