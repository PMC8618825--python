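"""Pairwise whole-genome homology detection.

Seed-and-extend local alignment between a focal genome and a query
genome: exact k-mer seeds (repeat-soft-masked, occurrence-capped) are
merged along diagonals into gap-free blocks, extended under an x-drop
rule, chained colinearly with affine gap costs, and netted to a
reciprocal-best set. A deliberately small, reproducible stand-in for a
production genome aligner: no translated alignment, no rearrangement
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .model import AlignmentChain, Block, Interval, RepeatTrack

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, N/other=4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


@dataclass(frozen=True)
class AlignParams:
    k: int = 12
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0
    x_drop: float = 20.0
    min_chain_score: float = 100.0
    max_occ: int = 20
    merge_gap: int = 100          # same-diagonal anchor merge distance
    chain_max_gap: int = 2000     # max focal/query gap when chaining blocks
    band: int = 400               # max diagonal shift (indel) when chaining
    min_anchors: int = 2          # seeds per gap-free block (noise filter)
    max_extend: int = 64          # x-drop extension limit per side


#: Presets by query divergence, loosely mirroring aligner practice of
#: relaxing penalties for more distant genomes.
PRESETS: dict[str, AlignParams] = {
    "near": AlignParams(k=14, mismatch=-1.5, min_chain_score=150.0),
    "mid": AlignParams(),
    "far": AlignParams(k=12, mismatch=-0.5, merge_gap=150, min_chain_score=80.0),
}


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-mer start; invalid where the window has N."""
    n = arr.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    m = n - k + 1
    code = np.zeros(m, dtype=np.int64)
    safe = np.where(arr == 4, 0, arr).astype(np.int64)
    for j in range(k):
        code = (code << 2) | safe[j : j + m]
    isn = (arr == 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(isn)])
    valid = (cs[k:] - cs[:-k]) == 0
    return code, valid


class SeedIndex:
    """k-mer position index over a genome.

    k-mers containing N, k-mers starting inside soft-masked repeats, and
    k-mers above the occurrence ceiling are excluded.
    """

    def __init__(
        self,
        genome: dict[str, str],
        k: int,
        max_occ: int = 20,
        repeats: Optional[RepeatTrack] = None,
    ):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.chroms = list(genome)
        self.encoded = {c: encode(s) for c, s in genome.items()}
        offsets = {}
        off = 0
        for c in self.chroms:
            offsets[c] = off
            off += len(genome[c])
        self.offsets = offsets
        self._bounds = np.array(
            [offsets[c] for c in self.chroms] + [off], dtype=np.int64
        )
        codes_all, pos_all = [], []
        for c in self.chroms:
            arr = self.encoded[c]
            code, valid = _kmer_codes(arr, k)
            if repeats is not None and c in repeats.intervals:
                for iv in repeats.intervals[c]:
                    valid[iv.start : iv.end] = False
            idx = np.nonzero(valid)[0]
            codes_all.append(code[idx])
            pos_all.append(idx + offsets[c])
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        codes, pos = codes[order], pos[order]
        if codes.size and max_occ > 0:
            uniq, start, cnt = np.unique(codes, return_index=True, return_counts=True)
            keep = np.repeat(cnt <= max_occ, cnt)
            codes, pos = codes[keep], pos[keep]
        self.pos = pos
        if codes.size:
            self.uniq, ustart, ucnt = np.unique(
                codes, return_index=True, return_counts=True
            )
            self.uoff = np.concatenate([ustart, [codes.size]])
        else:
            self.uniq = np.empty(0, np.int64)
            self.uoff = np.zeros(1, np.int64)

    def global_to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(self._bounds, gpos, side="right") - 1
        return ci, gpos - self._bounds[ci]

    def lookup(self, query_codes: np.ndarray, query_valid: np.ndarray):
        """Anchors (focal global pos, query pos) for all exact k-mer matches."""
        qidx = np.nonzero(query_valid)[0]
        qc = query_codes[qidx]
        if self.uniq.size == 0 or qc.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        ui = np.searchsorted(self.uniq, qc, side="left")
        ui_c = np.minimum(ui, self.uniq.size - 1)
        hit = self.uniq[ui_c] == qc
        ui, qidx = ui_c[hit], qidx[hit]
        lo = self.uoff[ui]
        cnt = self.uoff[ui + 1] - lo
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos = np.repeat(qidx, cnt)
        starts = np.repeat(lo, cnt) + _ranges(cnt)
        return self.pos[starts], qpos


def build_seed_index(
    genome: dict[str, str],
    k: int,
    max_occ: int = 20,
    repeats: Optional[RepeatTrack] = None,
) -> SeedIndex:
    return SeedIndex(genome, k, max_occ=max_occ, repeats=repeats)


def _ranges(counts: np.ndarray) -> np.ndarray:
    """Concatenated arange(c) for each c in counts (zeros allowed)."""
    counts = counts[counts > 0]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    ends = np.cumsum(counts)
    out[0] = 0
    out[ends[:-1]] = 1 - counts[:-1]
    return np.cumsum(out)


def _score_and_extend(
    farr: np.ndarray,
    qarr: np.ndarray,
    fs: int,
    fe: int,
    qs: int,
    params: AlignParams,
) -> tuple[int, int, int, float]:
    """Score a same-diagonal segment and x-drop-extend it on both sides.

    Returns (f_start, f_end, q_start, score); q_end = q_start + length.
    N positions never match.
    """
    # left extension
    lmax = min(fs, qs, params.max_extend)
    if lmax > 0:
        a = farr[fs - lmax : fs][::-1]
        b = qarr[qs - lmax : qs][::-1]
        ext_l = _xdrop(a, b, params)
    else:
        ext_l = 0
    # right extension
    rmax = min(farr.shape[0] - fe, qarr.shape[0] - (qs + fe - fs), params.max_extend)
    if rmax > 0:
        a = farr[fe : fe + rmax]
        b = qarr[qs + (fe - fs) : qs + (fe - fs) + rmax]
        ext_r = _xdrop(a, b, params)
    else:
        ext_r = 0
    nfs, nfe = fs - ext_l, fe + ext_r
    nqs = qs - ext_l
    a = farr[nfs:nfe]
    b = qarr[nqs : nqs + (nfe - nfs)]
    matches = int(np.count_nonzero((a == b) & (a != 4)))
    score = matches * params.match + (a.shape[0] - matches) * params.mismatch
    return nfs, nfe, nqs, float(score)


def _xdrop(a: np.ndarray, b: np.ndarray, params: AlignParams) -> int:
    # extension always scores +1/-1: a preset's milder mismatch penalty is
    # for scoring anchored segments, not for licensing random walks
    n = a.shape[0]
    if a[0] != b[0] and (n < 2 or a[1] != b[1]):
        return 0  # immediate double mismatch: nothing to extend into
    sc = np.where((a == b) & (a != 4), 1.0, -1.0)
    cum = np.cumsum(sc)
    run_max = np.maximum.accumulate(cum)
    dropped = np.nonzero(run_max - cum > params.x_drop)[0]
    stop = dropped[0] if dropped.size else n
    if stop == 0:
        return 0
    best = int(np.argmax(cum[:stop]))
    return best + 1 if cum[best] > 0 else 0


def _merge_segments(fpos: np.ndarray, qpos: np.ndarray, k: int, merge_gap: int):
    """Merge anchors sharing a diagonal into (fs, fe, qs, n_anchors) runs."""
    diag = fpos - qpos
    order = np.lexsort((qpos, diag))
    d, f, q = diag[order], fpos[order], qpos[order]
    new_seg = np.empty(d.shape[0], dtype=bool)
    new_seg[0] = True
    new_seg[1:] = (d[1:] != d[:-1]) | (q[1:] - q[:-1] > merge_gap)
    seg_id = np.cumsum(new_seg) - 1
    nseg = int(seg_id[-1]) + 1
    fs = np.zeros(nseg, dtype=np.int64)
    fe = np.zeros(nseg, dtype=np.int64)
    qs = np.zeros(nseg, dtype=np.int64)
    cnt = np.bincount(seg_id, minlength=nseg)
    starts = np.nonzero(new_seg)[0]
    ends = np.append(starts[1:], d.shape[0]) - 1
    fs[:] = f[starts]
    fe[:] = f[ends] + k
    qs[:] = q[starts]
    return fs, fe, qs, cnt


def align_genomes(
    focal: dict[str, str],
    query: dict[str, str],
    params: AlignParams = AlignParams(),
    focal_repeats: Optional[RepeatTrack] = None,
    index: Optional[SeedIndex] = None,
) -> list[AlignmentChain]:
    """All colinear alignment chains of ``query`` against ``focal``.

    Both query strands are searched; chains are reported with focal
    strand + and the query strand recorded. Overlapping chains are
    allowed here — resolution happens in :func:`reciprocal_best_net`.
    """
    if not focal or not query:
        return []
    if index is None:
        index = build_seed_index(
            focal, params.k, max_occ=params.max_occ, repeats=focal_repeats
        )
    chains: list[AlignmentChain] = []
    for qname, qseq in query.items():
        qarr_fwd = encode(qseq)
        for strand in "+-":
            qarr = qarr_fwd if strand == "+" else revcomp_codes(qarr_fwd)
            codes, valid = _kmer_codes(qarr, params.k)
            if codes.size == 0:
                continue
            fpos_g, qpos = index.lookup(codes, valid)
            if fpos_g.size == 0:
                continue
            ci, fpos = index.global_to_local(fpos_g)
            for chrom_i in np.unique(ci):
                sel = ci == chrom_i
                chrom = index.chroms[chrom_i]
                farr = index.encoded[chrom]
                fs, fe, qs, cnt = _merge_segments(
                    fpos[sel], qpos[sel], params.k, params.merge_gap
                )
                keep = cnt >= params.min_anchors
                blocks = []
                for s, e, q0 in zip(fs[keep], fe[keep], qs[keep]):
                    nfs, nfe, nqs, sc = _score_and_extend(
                        farr, qarr, int(s), int(e), int(q0), params
                    )
                    if sc > 0:
                        blocks.append((nfs, nfe, nqs, nqs + (nfe - nfs), sc))
                chains.extend(
                    _chain_blocks(blocks, chrom, qname, strand, len(qseq), params)
                )
    chains.sort(key=lambda c: (c.f_chrom, c.f_start, c.q_seq, c.q_start))
    return chains


def _chain_blocks(
    blocks: list[tuple],
    chrom: str,
    qname: str,
    strand: str,
    qlen: int,
    params: AlignParams,
) -> list[AlignmentChain]:
    """Greedy colinear chaining of extended blocks with affine gap costs."""
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: (b[0], b[2]))
    open_chains: list[dict] = []
    done: list[dict] = []
    for b in blocks:
        bfs, bfe, bqs, bqe, bsc = b
        best = None
        best_pen = None
        still_open = []
        for ch in open_chains:
            if ch["fe"] < bfs - params.chain_max_gap:
                done.append(ch)
                continue
            still_open.append(ch)
            fgap = bfs - ch["fe"]
            qgap = bqs - ch["qe"]
            if fgap < -params.k or qgap < -params.k:
                continue  # overlapping beyond seed slack: not colinear
            dshift = abs(fgap - qgap)
            if qgap > params.chain_max_gap or dshift > params.band:
                continue
            pen = (params.gap_open + params.gap_extend * dshift) if dshift else 0.0
            if best is None or pen < best_pen:
                best, best_pen = ch, pen
        open_chains = still_open
        if best is not None:
            best["blocks"].append(b)
            best["score"] += bsc - best_pen
            best["fe"] = max(best["fe"], bfe)
            best["qe"] = max(best["qe"], bqe)
        else:
            open_chains.append(
                {"blocks": [b], "score": bsc, "fe": bfe, "qe": bqe}
            )
    done.extend(open_chains)
    out = []
    for ch in done:
        if ch["score"] < params.min_chain_score:
            continue
        blks = []
        for bfs, bfe, bqs, bqe, bsc in ch["blocks"]:
            if strand == "-":
                bqs, bqe = qlen - bqe, qlen - bqs
            blks.append(Block(int(bfs), int(bfe), int(bqs), int(bqe), float(bsc)))
        out.append(
            AlignmentChain(
                f_chrom=chrom,
                f_start=min(b.f_start for b in blks),
                f_end=max(b.f_end for b in blks),
                q_seq=qname,
                q_start=min(b.q_start for b in blks),
                q_end=max(b.q_end for b in blks),
                q_strand=strand,
                score=float(ch["score"]),
                blocks=sorted(blks, key=lambda b: b.f_start),
            )
        )
    return out


def _priority(c: AlignmentChain) -> tuple:
    """Deterministic tie-break: higher score, then focal, then query coord."""
    return (-c.score, c.f_chrom, c.f_start, c.q_seq, c.q_start)


class _ClaimedBases:
    """Sorted, disjoint claimed intervals with subtract-and-claim."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def free_pieces(self, s: int, e: int) -> list[tuple[int, int]]:
        """Sub-intervals of [s, e) not yet claimed."""
        import bisect

        pieces = []
        i = bisect.bisect_right(self.ends, s)
        cur = s
        while i < len(self.starts) and self.starts[i] < e:
            if self.starts[i] > cur:
                pieces.append((cur, self.starts[i]))
            cur = max(cur, self.ends[i])
            i += 1
        if cur < e:
            pieces.append((cur, e))
        return pieces

    def claim(self, s: int, e: int) -> None:
        import bisect

        i = bisect.bisect_right(self.ends, s)
        j = i
        ns, ne = s, e
        while j < len(self.starts) and self.starts[j] <= e:
            ns = min(ns, self.starts[j])
            ne = max(ne, self.ends[j])
            j += 1
        self.starts[i:j] = [ns]
        self.ends[i:j] = [ne]


def _select_winners(chains: list[AlignmentChain]) -> list[AlignmentChain]:
    """Greedy per-base best selection on the chains' focal side.

    Chains are taken in priority order; blocks of later chains are
    clipped to focal bases not yet claimed, so each focal base belongs
    to at most one winner. Chains left with no blocks are dropped.
    """
    winners = []
    taken: dict[str, _ClaimedBases] = {}
    for c in sorted(chains, key=_priority):
        kept = taken.setdefault(c.f_chrom, _ClaimedBases())
        new_blocks = []
        for b in c.blocks:
            for s, e in kept.free_pieces(b.f_start, b.f_end):
                loff, roff = s - b.f_start, b.f_end - e
                if c.q_strand == "+":
                    nqs, nqe = b.q_start + loff, b.q_end - roff
                else:
                    nqs, nqe = b.q_start + roff, b.q_end - loff
                frac = (e - s) / (b.f_end - b.f_start)
                new_blocks.append(Block(s, e, nqs, nqe, b.score * frac))
        if not new_blocks:
            continue
        w = replace(
            c,
            blocks=new_blocks,
            f_start=min(b.f_start for b in new_blocks),
            f_end=max(b.f_end for b in new_blocks),
            q_start=min(b.q_start for b in new_blocks),
            q_end=max(b.q_end for b in new_blocks),
            score=sum(b.score for b in new_blocks),
            reciprocal_best=False,
        )
        winners.append(w)
        for b in new_blocks:
            kept.claim(b.f_start, b.f_end)
    return winners


def _interval_overlap(blocks: list[tuple[int, int]], iv: Interval) -> int:
    """Total overlap of (merged) half-open tuples with one interval."""
    if not blocks:
        return 0
    blocks = sorted(blocks)
    total = 0
    cur_s, cur_e = blocks[0]
    merged = []
    for s, e in blocks[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append((cur_s, cur_e))
    for s, e in merged:
        total += max(0, min(e, iv.end) - max(s, iv.start))
    return total


def reciprocal_best_net(
    chains_f2q: list[AlignmentChain], chains_q2f: list[AlignmentChain]
) -> list[AlignmentChain]:
    """Flag reciprocal-best chains; each focal base gets <=1 flagged chain.

    Winners are first selected independently on each side (greedy
    per-base best by score, later chains clipped). A focal-side winner
    is reciprocal-best iff the query-side winners overlapping its query
    interval map back onto its focal interval with >=50% mutual
    coverage on both genomes — the same-locus check that separates a
    paralogous copy from the true ortholog.
    """
    f_winners = _select_winners(chains_f2q)
    q_winners = _select_winners(chains_q2f)
    # index query-side winners by their own focal chrom (= query sequence)
    q_by_seq: dict[str, list[AlignmentChain]] = {}
    for c in q_winners:
        q_by_seq.setdefault(c.f_chrom, []).append(c)

    out: list[AlignmentChain] = []
    for c in f_winners:
        back_f: list[tuple[int, int]] = []  # focal-genome coverage mapped back
        back_q: list[tuple[int, int]] = []  # query-genome coverage of c's span
        for qc in q_by_seq.get(c.q_seq, []):
            if qc.q_seq != c.f_chrom:
                continue
            if qc.f_interval().overlap(c.q_interval()) == 0:
                continue
            if qc.q_interval().overlap(c.f_interval()) == 0:
                continue
            for b in qc.blocks:
                back_q.append((b.f_start, b.f_end))
                back_f.append((b.q_start, b.q_end))
        cov_f = _interval_overlap(back_f, c.f_interval())
        cov_q = _interval_overlap(back_q, c.q_interval())
        ok = (
            cov_f >= 0.5 * len(c.f_interval())
            and cov_q >= 0.5 * len(c.q_interval())
        )
        out.append(replace(c, reciprocal_best=ok))
    out.sort(key=lambda c: (c.f_chrom, c.f_start, c.q_seq, c.q_start))
    return out


def coverage(
    intervals: dict[str, list[Interval]] | list[tuple[str, Interval]],
    chains: list[AlignmentChain],
    known_chroms: Optional[set[str]] = None,
) -> list[float]:
    """Fraction of each interval's bases covered by reciprocal-best blocks."""
    if isinstance(intervals, dict):
        items = [(c, iv) for c, ivs in intervals.items() for iv in ivs]
    else:
        items = list(intervals)
    blocks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in chains:
        if not c.reciprocal_best:
            continue
        bl = blocks_by_chrom.setdefault(c.f_chrom, [])
        bl.extend((b.f_start, b.f_end) for b in c.blocks)
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, bl in blocks_by_chrom.items():
        bl.sort()
        ms, me = [], []
        for s, e in bl:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))
    out = []
    for chrom, iv in items:
        if known_chroms is not None and chrom not in known_chroms:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        if chrom not in merged or len(iv) == 0:
            out.append(0.0)
            continue
        ms, me = merged[chrom]
        ov = np.minimum(me, iv.end) - np.maximum(ms, iv.start)
        out.append(float(np.clip(ov, 0, None).sum() / len(iv)))
    return out
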