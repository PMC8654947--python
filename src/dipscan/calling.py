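"""Junction-based insertion calling from sequencing reads.

Locates the motif/recipient junction in each read by exact seed-and-extend
matching against the recipient reference (CDS plus optional flanking
context), identifies the inserted motif, and reports the insertion
position, direction, and reading frame. Paired calls are deduplicated;
retained in-frame calls aggregate to a gated count table.

Coordinate convention: insertions are reported 1-based as "after residue
i"; ``junction_nt`` is the 0-based CDS offset of the first inserted
nucleotide, ``aa_position = junction_nt // 3``, and a call is in frame iff
``junction_nt % 3 == 0`` (junctions inside a codon are reported at the
preceding residue, out of frame).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import reverse_complement

__all__ = [
    "InsertionCall", "ReferenceSet", "CallStats", "call_insertion",
    "dedup_pair", "call_read_pairs", "aggregate_counts", "missingness_qc",
    "read_fastq_pairs",
]

UNKNOWN_MOTIF = "unknown"


@dataclass(frozen=True)
class InsertionCall:
    read_id: str
    aa_position: int
    direction: str          # 'forward' | 'reverse'
    in_frame: bool
    motif_id: str


@dataclass(frozen=True)
class ReferenceSet:
    """Recipient CDS, motif sequences, and optional vector context."""
    recipient_cds: str
    motif_seqs: dict[str, str]
    context5: str = ""
    context3: str = ""

    def __post_init__(self):
        if len(self.recipient_cds) % 3 != 0:
            raise ValueError("recipient CDS length must be divisible by 3")
        for seq in (self.recipient_cds, self.context5, self.context3,
                    *self.motif_seqs.values()):
            if set(seq) - set("ACGT"):
                raise ValueError("sequences must be over {A,C,G,T}")

    @property
    def genome(self) -> str:
        return self.context5 + self.recipient_cds + self.context3

    @classmethod
    def from_design(cls, design) -> "ReferenceSet":
        return cls(recipient_cds=design.recipient_cds,
                   motif_seqs=dict(design.motif_nt),
                   context5=design.context5, context3=design.context3)


@dataclass
class CallStats:
    ambiguous: int = 0
    discordant_pairs: int = 0
    no_call: int = 0


def _find_all(haystack: str, needle: str):
    out, start = [], haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def _extend(a: str, b: str) -> int:
    """Length of the common prefix of two strings."""
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


_MAX_BACKOFF = 12  # nt of junction microhomology tolerated


def _motif_at_prefix_junction(insert: str, genome: str, j: int,
                              refs: ReferenceSet, min_flank: int,
                              strong_only: bool = False) -> str | None:
    """Unique motif explaining an insert that follows a recipient prefix
    ending at genome offset ``j``; None when no motif fits.

    With ``strong_only`` (used when the anchoring flank is short because
    of junction microhomology) only a full motif match followed by at
    least ``min_flank`` nt of matching recipient counts.
    """
    hits = []
    for mid, seq in refs.motif_seqs.items():
        if insert.startswith(seq):
            rest = insert[len(seq):]
            if genome[j:j + len(rest)] == rest and \
                    (not strong_only or len(rest) >= min_flank):
                hits.append(mid)
        elif not strong_only and seq.startswith(insert):
            hits.append(mid)
    return hits[0] if len(hits) == 1 else None


def _motif_at_suffix_junction(insert: str, genome: str, j: int,
                              refs: ReferenceSet, min_flank: int,
                              strong_only: bool = False) -> str | None:
    """Unique motif explaining an insert that precedes a recipient suffix
    resuming at genome offset ``j``."""
    hits = []
    for mid, seq in refs.motif_seqs.items():
        if insert.endswith(seq):
            pre = insert[:len(insert) - len(seq)]
            if genome[j - len(pre):j] == pre and \
                    (not strong_only or len(pre) >= min_flank):
                hits.append(mid)
        elif not strong_only and seq.endswith(insert):
            hits.append(mid)
    return hits[0] if len(hits) == 1 else None


def _call_oriented(read: str, refs: ReferenceSet, min_flank: int,
                   stats: CallStats | None):
    genome = refs.genome
    off5 = len(refs.context5)
    cds_len = len(refs.recipient_cds)

    def valid_junction(j_genome: int) -> bool:
        j = j_genome - off5
        return 3 <= j <= cds_len  # after residue 1 .. after residue L

    # --- prefix-anchored: read starts in recipient --------------------------
    seed = read[:min_flank]
    starts = _find_all(genome, seed)
    candidates = []
    best_p = 0
    for s in starts:
        p = min_flank + _extend(read[min_flank:], genome[s + min_flank:])
        if p > best_p:
            best_p, candidates = p, [s]
        elif p == best_p:
            candidates.append(s)
    if candidates and best_p == len(read):
        return None, "identity"  # read is pure recipient: no junction
    if candidates and best_p >= min_flank:
        if len({s + best_p for s in candidates}) > 1:
            if stats:
                stats.ambiguous += 1
            return None, "ambiguous"
        s = candidates[0]
        # back off over junction microhomology: prefer the placement that
        # identifies a known motif
        for back in range(0, _MAX_BACKOFF + 1):
            p2 = best_p - back
            if p2 < 1:
                break
            j = s + p2
            if not valid_junction(j):
                continue
            insert = read[p2:]
            motif = _motif_at_prefix_junction(
                insert, genome, j, refs, min_flank,
                strong_only=(p2 < min_flank))
            if motif is not None:
                return (j - off5, motif), "ok"
        j = s + best_p
        insert = read[best_p:]
        if valid_junction(j) and len(insert) >= min_flank:
            return (j - off5, UNKNOWN_MOTIF), "ok"

    # --- suffix-anchored: read ends in recipient ----------------------------
    seed = read[-min_flank:]
    ends = _find_all(genome, seed)
    candidates, best_s = [], 0
    rread = read[::-1]
    rgenome = genome[::-1]
    for e in ends:
        # e is the genome offset where the seed begins; extend leftwards
        end_in_genome = e + min_flank
        s_len = min_flank + _extend(rread[min_flank:],
                                    rgenome[len(genome) - end_in_genome
                                            + min_flank:])
        if s_len > best_s:
            best_s, candidates = s_len, [end_in_genome]
        elif s_len == best_s:
            candidates.append(end_in_genome)
    if candidates and min_flank <= best_s < len(read):
        if len({e - best_s for e in candidates}) > 1:
            if stats:
                stats.ambiguous += 1
            return None, "ambiguous"
        end = candidates[0]
        for back in range(0, _MAX_BACKOFF + 1):
            s2 = best_s - back
            if s2 < 1:
                break
            j = end - s2
            if not valid_junction(j):
                continue
            insert = read[:len(read) - s2]
            if len(insert) < min_flank:
                continue
            motif = _motif_at_suffix_junction(
                insert, genome, j, refs, min_flank,
                strong_only=(s2 < min_flank))
            if motif is not None:
                return (j - off5, motif), "ok"
        j = end - best_s
        insert = read[:len(read) - best_s]
        if valid_junction(j) and len(insert) >= min_flank:
            return (j - off5, UNKNOWN_MOTIF), "ok"
    return None, "none"


def call_insertion(read, refs: ReferenceSet, min_flank: int = 15,
                   stats: CallStats | None = None,
                   read_id: str = "") -> InsertionCall | None:
    """Call the insertion junction in a single read, or return None.

    Tries the forward orientation first, then the reverse complement.
    Reads matching the recipient end-to-end (no junction), ambiguous
    placements, and reads with insufficient flanks yield no call.
    """
    seq = str(read).upper()
    if len(seq) < 2 * min_flank:
        raise ValueError("read shorter than 2 * min_flank")
    for direction, oriented in (("forward", seq),
                                ("reverse", reverse_complement(seq))):
        result, status = _call_oriented(oriented, refs, min_flank, stats)
        if result is not None:
            junction_nt, motif = result
            return InsertionCall(
                read_id=read_id, aa_position=junction_nt // 3,
                direction=direction, in_frame=(junction_nt % 3 == 0),
                motif_id=motif)
        if status in ("identity", "ambiguous"):
            return None
    if stats:
        stats.no_call += 1
    return None


def dedup_pair(call_fwd: InsertionCall | None,
               call_rev: InsertionCall | None,
               stats: CallStats | None = None):
    """Merge the two mates' calls: concordant pairs count once, discordant
    pairs are dropped, single-mate calls pass through."""
    if call_fwd is None and call_rev is None:
        return []
    if call_fwd is None:
        return [call_rev]
    if call_rev is None:
        return [call_fwd]
    if (call_fwd.aa_position, call_fwd.motif_id) == \
            (call_rev.aa_position, call_rev.motif_id):
        merged = InsertionCall(
            read_id=call_fwd.read_id, aa_position=call_fwd.aa_position,
            direction=call_fwd.direction,
            in_frame=call_fwd.in_frame and call_rev.in_frame,
            motif_id=call_fwd.motif_id)
        return [merged]
    if stats:
        stats.discordant_pairs += 1
    return []


def call_read_pairs(pairs, refs: ReferenceSet, min_flank: int = 15):
    """Call and deduplicate a collection of ``(name, read1, read2)`` pairs.

    Returns ``(calls, stats)`` where calls is a list of InsertionCall.
    """
    stats = CallStats()
    calls = []
    for name, r1, r2 in pairs:
        c1 = call_insertion(r1, refs, min_flank, stats=stats, read_id=name)
        c2 = call_insertion(r2, refs, min_flank, stats=stats, read_id=name)
        calls.extend(dedup_pair(c1, c2, stats=stats))
    return calls, stats


def _sample_from_name(name: str) -> dict:
    """Recover gate/replicate/subpool/batch from a simulated read name."""
    parts = name.split("|")
    if len(parts) < 6:
        raise ValueError(f"read name {name!r} carries no sample metadata")
    return {"gate": parts[2], "replicate": int(parts[3].removeprefix("rep")),
            "subpool": parts[4], "batch": parts[5]}


def aggregate_counts(calls, sample_metadata=None) -> pd.DataFrame:
    """Aggregate retained in-frame calls to a gated count table.

    ``sample_metadata`` maps read_id -> dict(gate, replicate, subpool,
    batch); when omitted, metadata is parsed from simulated read names.
    Out-of-frame calls are tallied separately in the returned frame's
    ``attrs['out_of_frame']``.
    """
    rows, out_of_frame = [], Counter()
    for call in calls:
        if sample_metadata is not None:
            try:
                meta = sample_metadata[call.read_id]
            except KeyError:
                raise ValueError(
                    f"no sample metadata for read {call.read_id!r}") from None
        else:
            meta = _sample_from_name(call.read_id)
        key = (call.aa_position, call.motif_id, meta["gate"],
               meta["replicate"], meta["subpool"], meta["batch"])
        if call.in_frame:
            rows.append(key)
        else:
            out_of_frame[key] += 1
    counter = Counter(rows)
    table = pd.DataFrame(
        [k + (v,) for k, v in sorted(counter.items())],
        columns=["position", "motif_id", "gate", "replicate", "subpool",
                 "batch", "count"])
    table.attrs["out_of_frame"] = dict(out_of_frame)
    return table


def missingness_qc(matrix: pd.DataFrame) -> dict:
    """Percent-missing vectors of a fitness matrix (rows = positions)."""
    miss = matrix.isna()
    return {
        "per_position": (miss.mean(axis=1) * 100.0),
        "per_motif": (miss.mean(axis=0) * 100.0),
        "overall": float(miss.to_numpy().mean() * 100.0),
    }


def read_fastq_pairs(path_r1, path_r2):
    """Load a FASTQ pair back into ``(name, read1, read2)`` tuples."""
    from Bio import SeqIO
    r1 = SeqIO.parse(path_r1, "fastq")
    r2 = SeqIO.parse(path_r2, "fastq")
    return [(a.id, str(a.seq), str(b.seq)) for a, b in zip(r1, r2)]
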