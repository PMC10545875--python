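"""Transcript-level splice-effect verification.

An observed (patient) transcript is globally aligned against the
reference coding sequence with unit mismatch/gap costs; a single
contiguous gap in the observed sequence is called as a deletion in
1-based HGVS c. coordinates, normalized 3'-most when the junction
falls inside a repeat, and classified as in-frame or frameshift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO

_DNA = set("ACGT")


class TranscriptError(ValueError):
    pass


@dataclass
class TranscriptDiff:
    kind: str                       # identical / deletion / other
    interval: tuple[int, int] | None = None   # 1-based inclusive c. coords
    length: int = 0
    frame: str | None = None        # in_frame / frameshift
    deleted_sequence: str = ""
    # all placements of the same edit (repeat-junction ambiguity)
    equivalent_intervals: list[tuple[int, int]] = field(default_factory=list)
    # for kind == "other": list of (ref_pos, ref_base, obs_base) style notes
    diffs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in vars(self).items()}
        obj["equivalent_intervals"] = [list(t) for t in self.equivalent_intervals]
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 0
    a.mismatch_score = -1
    # unit per-base gap cost with a tiny opening surcharge: among
    # equal-cost alignments this breaks ties toward one contiguous gap
    a.open_gap_score = -1.01
    a.extend_gap_score = -1
    return a


def _check_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise TranscriptError(f"{name} sequence is empty")
    bad = set(seq) - _DNA
    if bad:
        raise TranscriptError(f"{name} contains non-DNA characters {sorted(bad)}")
    return seq


def _shift_3prime(ref: str, start0: int, length: int) -> list[tuple[int, int]]:
    """All equivalent placements of deleting ref[start0:start0+length].

    Deleting at i and at i+1 are equivalent iff ref[i] == ref[i+length];
    walking both directions enumerates the repeat equivalence class,
    ordered 5' to 3'.
    """
    placements = [start0]
    i = start0
    while i > 0 and ref[i - 1] == ref[i - 1 + length]:
        i -= 1
        placements.insert(0, i)
    i = start0
    while i + length < len(ref) and ref[i] == ref[i + length]:
        i += 1
        placements.append(i)
    return [(p + 1, p + length) for p in placements]


def align_and_diff(ref_cds: str, observed: str) -> TranscriptDiff:
    """Call the difference between an observed transcript and its reference.

    Identical sequences give kind 'identical'; a single contiguous
    stretch missing from the observed sequence gives kind 'deletion'
    with the HGVS-normalized (3'-most) interval; anything else —
    substitutions, insertions, multiple gaps — gives kind 'other' with
    a human-readable diff list.
    """
    ref_cds = _check_dna(ref_cds, "reference")
    observed = _check_dna(observed, "observed")
    if ref_cds == observed:
        return TranscriptDiff(kind="identical")

    aln = _aligner().align(ref_cds, observed)[0]
    ref_gapped, obs_gapped = str(aln[0]), str(aln[1])

    deletions: list[tuple[int, int]] = []  # 0-based [start, end) in ref
    notes: list[str] = []
    ref_pos = 0
    open_del: int | None = None
    for rc, oc in zip(ref_gapped, obs_gapped):
        if rc != "-" and oc == "-":
            if open_del is None:
                open_del = ref_pos
        else:
            if open_del is not None:
                deletions.append((open_del, ref_pos))
                open_del = None
            if rc == "-":
                notes.append(f"insertion of {oc!r} after c.{ref_pos}")
            elif rc != oc:
                notes.append(f"substitution c.{ref_pos + 1} {rc}>{oc}")
        if rc != "-":
            ref_pos += 1
    if open_del is not None:
        deletions.append((open_del, ref_pos))

    if len(deletions) == 1 and not notes:
        start0, end0 = deletions[0]
        length = end0 - start0
        placements = _shift_3prime(ref_cds, start0, length)
        c_start, c_end = placements[-1]   # HGVS: 3'-most representative
        return TranscriptDiff(
            kind="deletion", interval=(c_start, c_end), length=length,
            frame="in_frame" if length % 3 == 0 else "frameshift",
            deleted_sequence=ref_cds[c_start - 1:c_end],
            equivalent_intervals=placements)

    for start0, end0 in deletions:
        notes.append(f"deletion c.{start0 + 1}_{end0} "
                     f"({ref_cds[start0:end0]})")
    return TranscriptDiff(kind="other", diffs=notes)


def diff_to_hgvs(diff: TranscriptDiff) -> str:
    """HGVS coding-DNA description of a deletion diff."""
    if diff.kind != "deletion" or diff.interval is None:
        raise TranscriptError("HGVS rendering requires a deletion diff")
    start, end = diff.interval
    return f"c.{start}del" if start == end else f"c.{start}_{end}del"


def read_fasta_pair(path: str | Path) -> tuple[str, str]:
    """Read (reference, observed) as the first two records of a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise TranscriptError("FASTA must hold two records: reference, observed")
    return str(records[0].seq), str(records[1].seq)
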