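"""Masked references and a deterministic seed-and-extend read aligner.

Masking reproduces the two analysis modes of a pseudogene-aware panel:

* ``standard`` — the gene's 3' homologous region (exons 32-44) *and* the
  whole pseudogene are replaced by ``N``; variants there are invisible, which
  is exactly why the region confounds conventional short-read calling.
* ``modified`` — only the pseudogene is masked, *except* its exon-35/
  intron-35-homologous segment.  Reads spanning the 120-bp deletion junction
  cannot be placed on the gene without a 120-bp gap, but they match the
  pseudogene segment contiguously, so they align there and the deletion
  becomes visible as pseudogene-side coverage.

The aligner is an exact-k-mer seeded, ungapped-extension mapper with a
single-small-indel rescue (gap of 1-2 bp), sufficient for substitution-only
simulated reads plus the 1-2 bp indel variants the screen must genotype.
``N`` never matches any base and a mapped read may not overlap a masked
position at all.  Equal-best placements at distinct locations are reported
unmapped (ambiguous), mirroring the conservatism that motivates masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locus import Interval, ParalogLocus
from .simulate import Read

__all__ = [
    "MaskedReference",
    "AlignmentRecord",
    "build_masked_reference",
    "align_reads",
    "depth_profile",
    "brute_force_best",
    "alignments_to_sam",
]


@dataclass
class MaskedReference:
    """A locus sequence with N-masked intervals; same length as the locus."""

    sequence: str
    mode: str
    mask_intervals: tuple[Interval, ...]
    name: str = "locus"
    unmasked_pseudogene_window: Interval | None = None

    def __post_init__(self) -> None:
        self._arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        is_n = (self._arr == ord("N")).astype(np.int32)
        self._n_prefix = np.concatenate([[0], np.cumsum(is_n)])

    @property
    def array(self) -> np.ndarray:
        return self._arr

    def n_count(self, start0: int, end0: int) -> int:
        """Number of Ns in the 0-based half-open window [start0, end0)."""
        return int(self._n_prefix[end0] - self._n_prefix[start0])

    def to_fasta(self) -> str:
        lines = [f">{self.name} mode={self.mode}"]
        for i in range(0, len(self.sequence), 70):
            lines.append(self.sequence[i:i + 70])
        return "\n".join(lines) + "\n"


def pseudogene_unmask_window(locus: ParalogLocus) -> Interval:
    """Pseudogene segment homologous to exon 35 +/- flanks that the modified
    mode leaves unmasked (it contains the deletion junction)."""
    e35 = locus.exon_map.exon(35)
    a0 = locus.a_position(e35.g_start - 60)
    a1 = locus.a_position(e35.g_end + 58)
    return Interval(a0, a1)


def build_masked_reference(locus: ParalogLocus, mode: str) -> MaskedReference:
    if mode == "unmasked":
        return MaskedReference(locus.sequence, mode, ())
    if mode == "standard":
        intervals = (locus.homology_span, locus.pseudogene_a_span)
        window = None
    elif mode == "modified":
        win = pseudogene_unmask_window(locus)
        a = locus.pseudogene_a_span
        intervals = (Interval(a.start, win.start - 1), Interval(win.end + 1, a.end))
        window = win
    else:
        raise ValueError(f"unknown masking mode {mode!r} "
                         "(expected standard, modified or unmasked)")
    arr = np.frombuffer(locus.sequence.encode(), dtype=np.uint8).copy()
    for iv in intervals:
        arr[iv.start - 1:iv.end] = ord("N")
    return MaskedReference(arr.tobytes().decode("ascii"), mode, intervals,
                           unmasked_pseudogene_window=window)


@dataclass
class AlignmentRecord:
    """One read placement.  ``blocks`` are (ref_start_1based, read_start_0based,
    length) gapless segments; two blocks imply one small indel between them."""

    read_id: str
    position: int                 # 1-based leftmost reference position; 0 if unmapped
    mapped: bool
    n_mismatch: int = 0
    blocks: tuple[tuple[int, int, int], ...] = ()
    mismatch_positions: tuple[int, ...] = ()   # 1-based reference positions
    mismatch_bases: tuple[str, ...] = ()
    insertion: tuple[int, str] | None = None   # ref pos after which seq is inserted
    deletion: tuple[int, int] | None = None    # (first deleted ref pos, length)
    reason: str = ""
    read_length: int = 0

    def cigar(self) -> str:
        if not self.mapped:
            return "*"
        if len(self.blocks) == 1:
            return f"{self.blocks[0][2]}M"
        b1, b2 = self.blocks
        if self.insertion is not None:
            return f"{b1[2]}M{len(self.insertion[1])}I{b2[2]}M"
        return f"{b1[2]}M{self.deletion[1]}D{b2[2]}M"


def _build_index(ref_arr: np.ndarray, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    data = ref_arr.tobytes()
    n_byte = ord("N")
    # positions of Ns, to skip k-mers that touch them
    n_pos = np.flatnonzero(ref_arr == n_byte)
    n_block = np.zeros(len(ref_arr) + 1, dtype=np.int32)
    if len(n_pos):
        n_block[n_pos + 1] = 1
    n_cum = np.cumsum(n_block)
    for i in range(len(data) - k + 1):
        if n_cum[i + k] - n_cum[i]:
            continue
        index.setdefault(data[i:i + k], []).append(i)
    return index


class ReferenceIndex:
    """Cached k-mer index of a masked reference (reusable across read sets)."""

    def __init__(self, ref: MaskedReference, seed_k: int = 15):
        if seed_k < 11:
            raise ValueError("seed_k must be >= 11")
        if not len(ref.sequence):
            raise ValueError("empty reference")
        self.ref = ref
        self.k = seed_k
        self.kmers = _build_index(ref.array, seed_k)


_GAP_CONFIGS = ((1, 0), (2, 0), (0, 1), (0, 2))  # (ref gap, read gap)
_MIN_FLANK = 10


def _try_indel(ref_arr, read_arr, s: int, budget: int):
    """Best single-indel placement of read at candidate start s.

    Returns (total_mismatches, split_j, d_ref, d_read) or None.
    """
    L = len(read_arr)
    best = None
    pre = np.concatenate([[0], np.cumsum(ref_arr[s:s + L] != read_arr)]) \
        if s + L <= len(ref_arr) else None
    if pre is None:
        return None
    for d_ref, d_read in _GAP_CONFIGS:
        if d_read:
            m1 = ref_arr[s:s + L - d_read] != read_arr[d_read:]
        else:
            if s + L + d_ref > len(ref_arr):
                continue
            m1 = ref_arr[s + d_ref:s + L + d_ref] != read_arr
        c1 = np.concatenate([[0], np.cumsum(m1)])
        total1 = int(c1[-1])
        js = np.arange(_MIN_FLANK, L - d_read - _MIN_FLANK + 1)
        if len(js) == 0:
            continue
        totals = pre[js] + (total1 - c1[js])
        jbest = int(np.argmin(totals))
        t = int(totals[jbest])
        if t <= budget and (best is None or t < best[0]):
            best = (t, int(js[jbest]), d_ref, d_read)
    return best


def align_reads(reads: list[Read], ref: MaskedReference | ReferenceIndex,
                seed_k: int = 15, max_mismatch_frac: float = 0.05) -> list[AlignmentRecord]:
    """Map reads by exact k-mer seeding and ungapped extension.

    Seeds tile the read every k bases, so any placement with at most
    floor(max_mismatch_frac * L) mismatches is guaranteed a clean seed
    whenever the number of seeds exceeds the mismatch budget.  A read whose
    best placement ties across distinct locations, exceeds the mismatch
    budget, or overlaps a masked base is reported unmapped.  Reads failing
    the ungapped budget are rescued by a single 1-2 bp indel if that brings
    them within budget.
    """
    idx = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref, seed_k)
    mref = idx.ref
    ref_arr = mref.array
    k = idx.k
    ref_len = len(ref_arr)
    out: list[AlignmentRecord] = []

    for read in reads:
        seq = read.sequence
        L = len(seq)
        if L < k:
            out.append(AlignmentRecord(read.name, 0, False, reason="read shorter than seed",
                                       read_length=L))
            continue
        read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        data = seq.encode()
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        candidates: set[int] = set()
        for o in offsets:
            for p in idx.kmers.get(data[o:o + k], ()):
                s = p - o
                if 0 <= s <= ref_len - L:
                    candidates.add(s)
        if not candidates:
            out.append(AlignmentRecord(read.name, 0, False, reason="no seed",
                                       read_length=L))
            continue

        budget = int(max_mismatch_frac * L)
        scored: list[tuple[int, int]] = []
        for s in candidates:
            if mref.n_count(s, s + L):
                continue
            mm = int(np.count_nonzero(ref_arr[s:s + L] != read_arr))
            scored.append((mm, s))
        best_rec = None
        if scored:
            scored.sort()
            best_mm, best_s = scored[0]
            if best_mm <= budget:
                if len(scored) > 1 and scored[1][0] == best_mm:
                    out.append(AlignmentRecord(read.name, 0, False,
                                               reason="ambiguous", read_length=L))
                    continue
                diff = np.flatnonzero(ref_arr[best_s:best_s + L] != read_arr)
                best_rec = AlignmentRecord(
                    read.name, best_s + 1, True, best_mm,
                    blocks=((best_s + 1, 0, L),),
                    mismatch_positions=tuple(int(best_s + 1 + d) for d in diff),
                    mismatch_bases=tuple(chr(read_arr[d]) for d in diff),
                    read_length=L)
        if best_rec is None:
            # single-indel rescue
            indel_hits = []
            for s in candidates:
                hit = _try_indel(ref_arr, read_arr, s, budget)
                if hit is not None:
                    t, j, d_ref, d_read = hit
                    if mref.n_count(s, s + L - d_read + d_ref):
                        continue
                    indel_hits.append((t, s, j, d_ref, d_read))
            if not indel_hits:
                out.append(AlignmentRecord(read.name, 0, False,
                                           reason="no placement within budget",
                                           read_length=L))
                continue
            indel_hits.sort()
            t, s, j, d_ref, d_read = indel_hits[0]
            if len(indel_hits) > 1 and indel_hits[1][0] == t and indel_hits[1][1] != s:
                out.append(AlignmentRecord(read.name, 0, False, reason="ambiguous",
                                           read_length=L))
                continue
            b1 = (s + 1, 0, j)
            b2 = (s + j + d_ref + 1, j + d_read, L - j - d_read)
            mm_pos, mm_base = [], []
            d1 = np.flatnonzero(ref_arr[s:s + j] != read_arr[:j])
            for d in d1:
                mm_pos.append(int(s + 1 + d))
                mm_base.append(chr(read_arr[d]))
            seg = ref_arr[s + j + d_ref:s + j + d_ref + (L - j - d_read)]
            d2 = np.flatnonzero(seg != read_arr[j + d_read:])
            for d in d2:
                mm_pos.append(int(s + j + d_ref + 1 + d))
                mm_base.append(chr(read_arr[j + d_read + d]))
            insertion = (s + j, seq[j:j + d_read]) if d_read else None
            deletion = (s + j + 1, d_ref) if d_ref else None
            best_rec = AlignmentRecord(read.name, s + 1, True, t,
                                       blocks=(b1, b2),
                                       mismatch_positions=tuple(mm_pos),
                                       mismatch_bases=tuple(mm_base),
                                       insertion=insertion, deletion=deletion,
                                       read_length=L)
        out.append(best_rec)
    return out


def depth_profile(alignments: list[AlignmentRecord], ref: MaskedReference,
                  panel=None) -> tuple[np.ndarray, dict[str, float]]:
    """Per-position coverage vector (index 0 = position 1) and, when a panel
    is supplied, mean depth over each amplicon's insert interval."""
    diff = np.zeros(len(ref.sequence) + 1, dtype=np.int64)
    for rec in alignments:
        if not rec.mapped:
            continue
        for ref_start, _read_start, length in rec.blocks:
            diff[ref_start - 1] += 1
            diff[ref_start - 1 + length] -= 1
    cov = np.cumsum(diff[:-1])
    means: dict[str, float] = {}
    if panel is not None:
        for amp in panel.amplicons:
            iv = amp.interval
            means[amp.name] = float(cov[iv.start - 1:iv.end].mean())
    return cov, means


def brute_force_best(read_seq: str, ref: MaskedReference) -> tuple[int, int, bool]:
    """Exhaustive ungapped Hamming scan: (best_1based_pos, best_mm, unique).

    Windows containing any masked base are skipped, matching the aligner's
    mask contract.  Serves as the independent oracle for the seeded aligner.
    """
    ref_arr = ref.array
    L = len(read_seq)
    read_arr = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    mm = np.count_nonzero(windows != read_arr, axis=1).astype(np.int64)
    has_n = np.array([ref.n_count(s, s + L) > 0 for s in range(len(ref_arr) - L + 1)])
    mm[has_n] = np.iinfo(np.int64).max
    best = int(mm.min())
    hits = np.flatnonzero(mm == best)
    return int(hits[0]) + 1, best, len(hits) == 1


def alignments_to_sam(alignments: list[AlignmentRecord], ref: MaskedReference,
                      reads: list[Read] | None = None) -> str:
    """Minimal SAM: header plus the 11 mandatory fields per record."""
    seq_by_id = {r.name: r.sequence for r in reads} if reads else {}
    lines = ["@HD\tVN:1.6\tSO:unknown",
             f"@SQ\tSN:{ref.name}\tLN:{len(ref.sequence)}"]
    for rec in alignments:
        seq = seq_by_id.get(rec.read_id, "*")
        if rec.mapped:
            lines.append("\t".join([rec.read_id, "0", ref.name, str(rec.position),
                                    "60", rec.cigar(), "*", "0", "0", seq,
                                    "*"]))
        else:
            lines.append("\t".join([rec.read_id, "4", "*", "0", "0", "*", "*",
                                    "0", "0", seq, "*"]))
    return "\n".join(lines) + "\n"
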