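"""Scaffold-guided alignment merging and Nudix-box / X-loop localization.

Divide-and-conquer alignment of a huge homology clan produces one alignment
per subgroup, each containing the same core (scaffold) sequences. Because the
scaffold rows are aligned identically in every subgroup, their columns give a
correspondence that lets the subgroup alignments be stitched into one: columns
homologous to the scaffold are merged across subgroups, while each subgroup's
insertions are kept as private column blocks padded with gaps in every other
subgroup (insertions are deliberately *not* aligned between subgroups).

The module also locates the hallmark Nudix-box motif — the 23-residue
loop-helix-loop signature GX5EX7REUXEEXGU of the pyrophosphohydrolases, where
U is a bulky aliphatic residue (L/I/V by default) and X is any amino acid —
and the downstream "X-loop" window, a substrate-specificity loop about 17
residues after the motif end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_U_SET = "LIV"
#: the canonical Nudix-box pattern: G X5 E X7 R E U X E E X G U (23 positions)
NUDIX_BOX_TEMPLATE = "G" + "X" * 5 + "E" + "X" * 7 + "RE" + "UX" + "EE" + "XG" + "U"
NUDIX_BOX_LENGTH = len(NUDIX_BOX_TEMPLATE)  # == 23


@dataclass
class Alignment:
    """An ordered multiple sequence alignment over amino acids plus '-'."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids within one alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def row(self, sid: str) -> str:
        for rid, seq in self.records:
            if rid == sid:
                return seq
        raise KeyError(sid)

    @classmethod
    def read_fasta(cls, path: str) -> "Alignment":
        msa = AlignIO.read(path, "fasta")
        return cls([(rec.id, str(rec.seq).upper()) for rec in msa])

    def write_fasta(self, path: str) -> None:
        msa = MultipleSeqAlignment(
            SeqRecord(Seq(seq), id=sid, description="") for sid, seq in self.records
        )
        AlignIO.write(msa, path, "fasta")


def degap(seq: str) -> str:
    return seq.replace(GAP, "")


def merge_on_scaffold(scaffold: Alignment,
                      subgroups: Sequence[Alignment]) -> Alignment:
    """Merge subgroup alignments sharing a common scaffold into one alignment.

    Every subgroup must contain all scaffold rows, with ungapped sequences
    identical to the scaffold's and mutual alignment preserved. Output columns
    are, per scaffold position: each subgroup's insert block (in subgroup
    input order), then the merged scaffold column; a trailing block run
    follows the last scaffold column. Every row's ungapped sequence is
    preserved exactly; non-scaffold ids must be unique across subgroups.
    """
    scaffold_ids = set(scaffold.ids)
    extra_rows: list[tuple[str, int]] = []  # (sequence_id, subgroup index)
    seen_extra: set[str] = set()
    for k, sub in enumerate(subgroups):
        missing = scaffold_ids - set(sub.ids)
        if missing:
            raise ValueError(
                f"subgroup {k} is missing scaffold sequences: {sorted(missing)[:5]}")
        for sid in sub.ids:
            if sid in scaffold_ids:
                if degap(sub.row(sid)) != degap(scaffold.row(sid)):
                    raise ValueError(
                        f"scaffold sequence mismatch (ungapped) for {sid!r} "
                        f"in subgroup {k}")
            else:
                if sid in seen_extra:
                    raise ValueError(f"duplicate non-scaffold id across subgroups: "
                                     f"{sid!r}")
                seen_extra.add(sid)
                extra_rows.append((sid, k))

    n_scols = scaffold.n_columns
    # Per subgroup: which of its columns match scaffold columns (>=1 scaffold
    # row non-gap) and which are inserts (all scaffold rows gapped), and the
    # insert-block run preceding each scaffold column (index n_scols = trailing).
    match_cols: list[list[int]] = []
    insert_blocks: list[dict[int, list[int]]] = []
    for k, sub in enumerate(subgroups):
        rows = {sid: sub.row(sid) for sid in scaffold.ids}
        matches: list[int] = []
        blocks: dict[int, list[int]] = {}
        pending: list[int] = []
        for col in range(sub.n_columns):
            if any(rows[sid][col] != GAP for sid in scaffold.ids):
                blocks[len(matches)] = pending
                pending = []
                matches.append(col)
            else:
                pending.append(col)
        blocks[len(matches)] = pending
        if len(matches) != n_scols:
            raise ValueError(
                f"subgroup {k} has {len(matches)} scaffold-matching columns, "
                f"expected {n_scols}")
        for j, col in enumerate(matches):
            for sid in scaffold.ids:
                if sub.row(sid)[col] != scaffold.row(sid)[j]:
                    raise ValueError(
                        f"subgroup {k} realigns scaffold row {sid!r} at scaffold "
                        f"column {j + 1}")
        match_cols.append(matches)
        # normalize missing runs to empty
        insert_blocks.append({j: blocks.get(j, []) for j in range(n_scols + 1)})

    out_ids = scaffold.ids + [sid for sid, _ in extra_rows]
    out: dict[str, list[str]] = {sid: [] for sid in out_ids}
    sub_rows = [{sid: sub.row(sid) for sid in sub.ids} for sub in subgroups]

    def emit_insert_blocks(j: int) -> None:
        for k, sub in enumerate(subgroups):
            for col in insert_blocks[k][j]:
                for sid in out_ids:
                    if sid in sub_rows[k] and sid not in scaffold_ids:
                        out[sid].append(sub_rows[k][sid][col])
                    else:
                        out[sid].append(GAP)

    for j in range(n_scols):
        emit_insert_blocks(j)
        for sid in out_ids:
            if sid in scaffold_ids:
                out[sid].append(scaffold.row(sid)[j])
            else:
                k = next(kk for ss, kk in extra_rows if ss == sid)
                out[sid].append(sub_rows[k][sid][match_cols[k][j]])
    emit_insert_blocks(n_scols)

    return Alignment([(sid, "".join(out[sid])) for sid in out_ids])


@dataclass(frozen=True)
class MotifHit:
    """A motif match in 1-based inclusive ungapped residue coordinates."""

    sequence_id: str
    start: int
    end: int
    matched: str
    pattern_name: str = "nudix_box_canonical"


@dataclass(frozen=True)
class XLoopWindow:
    """The X-loop residue window downstream of a Nudix-box hit."""

    sequence_id: str
    offset_from_motif_end: int
    start: int
    end: int
    truncated: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _compile_motif(pattern: str, u_set: str) -> re.Pattern:
    regex = []
    for ch in pattern:
        if ch == "X":
            regex.append(f"[{AMINO_ACIDS}]")
        elif ch == "U":
            regex.append(f"[{u_set}]")
        elif ch in AMINO_ACIDS:
            regex.append(ch)
        else:
            raise ValueError(f"bad motif template character {ch!r}")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(regex)}))")


def scan_nudix_box(sequence: str, sequence_id: str = "",
                   pattern: str = NUDIX_BOX_TEMPLATE,
                   u_set: str = DEFAULT_U_SET) -> list[MotifHit]:
    """All (possibly overlapping) Nudix-box matches in an ungapped sequence.

    The template uses X for any residue and U for the hydrophobic set
    (default {L, I, V}). Gap characters are stripped before scanning; other
    non-residue characters are an error. Coordinates are 1-based inclusive
    in ungapped residue space.
    """
    seq = degap(sequence.upper())
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-residue characters in sequence: {sorted(bad)}")
    name = "nudix_box_canonical" if pattern == NUDIX_BOX_TEMPLATE else "custom"
    hits = []
    for m in _compile_motif(pattern, u_set).finditer(seq):
        matched = m.group(1)
        start = m.start() + 1
        hits.append(MotifHit(sequence_id, start, start + len(matched) - 1,
                             matched, name))
    return hits


def locate_xloop(sequence: str, motif_hit: MotifHit, offset: int = 17,
                 length: int = 10,
                 length_bounds: tuple[int, int] = (2, 19)) -> XLoopWindow | None:
    """The X-loop window ``offset`` residues after a Nudix-box hit.

    Returns the window of the requested length (clamped to ``length_bounds``
    and truncated at the sequence end), or None when fewer residues than the
    lower bound remain — a sequence too short to harbour the loop, which is
    distinct from an error.
    """
    seq = degap(sequence.upper())
    lo, hi = length_bounds
    if not lo <= length <= hi:
        raise ValueError(f"requested length {length} outside bounds {length_bounds}")
    if motif_hit.end > len(seq):
        raise ValueError("motif hit extends past the sequence end")
    start = motif_hit.end + offset + 1
    end = min(start + length - 1, len(seq))
    if end - start + 1 < lo:
        return None
    return XLoopWindow(motif_hit.sequence_id, offset, start, end,
                       truncated=end < start + length - 1)
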