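"""V/J assignment, CDR3 extraction and clonotype assembly for read 2 amplicons.

The amplicon layout is: partial read-2 tail, TRBV primer region, V 3' region,
CDR3 junction, J segment, constant-region start. V identity is therefore read
from the 5' window of read 2 (the primer anchors it); J is found 3' of the V
alignment. Alignment is ungapped (match +1 / mismatch -1) — the targeted
chemistry produces no structural indels, and sequencing indels are rare
enough on short amplicons to be dropped rather than rescued.

A clonotype is the exact triple (V gene, J gene, CDR3 nucleotide sequence);
no fuzzy clustering is applied. Nonproductive clonotypes are retained and
flagged, never dropped.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import io as sio
from .types import (
    Clonotype,
    ExtractionError,
    FormatError,
    PrimerPool,
    ReadRecord,
    SegmentReference,
    chain_of,
    translate_nt,
)

_V_WINDOW = 60  # 5' window of read 2 scanned for the V primer region
_V_MAX_OFFSET = 10
_MIN_READ_LEN = 40
_J_MIN_SPAN = 20


@dataclass(frozen=True)
class Alignment:
    """An ungapped hit of a reference segment on a read (0-based, half-open)."""

    segment_name: str
    score: int
    mismatches: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool


def _to_bytes(seq: str, pad_to: int, pad_byte: int) -> np.ndarray:
    arr = np.full(pad_to, pad_byte, dtype=np.uint8)
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    arr[: raw.size] = raw[:pad_to]
    return arr


@lru_cache(maxsize=8)
def _v_index(reference: SegmentReference, pool: PrimerPool):
    """Per-(reference, pool) matrix of padded V queries: tail + segment from
    the primer start, truncated to the scan window."""
    names, queries, tail_lens, primer_starts = [], [], [], []
    for p in pool.primers:
        try:
            v = reference.v(p.v_gene_name)
        except KeyError:
            continue
        start = v.sequence.find(p.primer_seq)
        if start < 0:
            continue  # primer does not anchor in this segment
        names.append(p.v_gene_name)
        queries.append(p.read2_tail + v.sequence[start:])
        tail_lens.append(len(p.read2_tail))
        primer_starts.append(start)
    qmat = np.stack([_to_bytes(q, _V_WINDOW, 0) for q in queries])
    qlens = np.minimum([len(q) for q in queries], _V_WINDOW)
    return names, qmat, np.asarray(qlens), tail_lens, primer_starts


@lru_cache(maxsize=8)
def _j_index(reference: SegmentReference):
    names = [j.name for j in reference.j_segments]
    seqs = [j.sequence for j in reference.j_segments]
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    return names, arrs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_v(
    read2: ReadRecord,
    reference: SegmentReference,
    primer_pool: PrimerPool,
    max_mismatch_frac: float = 0.1,
) -> Alignment | None:
    """Best ungapped V hit in the read's 5' window, or None.

    Each candidate query (read-2 tail + primer region + downstream segment,
    first 60 nt) is scanned at read offsets 0-10; the call is accepted when
    the best window's mismatch fraction is <= ``max_mismatch_frac``. Score
    ties break to the lexicographically smallest segment name. The returned
    alignment covers the V-segment portion only (tail excluded), with
    reference coordinates in the V segment.
    """
    seq = read2.sequence
    if len(seq) < _MIN_READ_LEN:
        return None
    names, qmat, qlens, tail_lens, primer_starts = _v_index(reference, primer_pool)
    if not names:
        return None
    # pad the read with a byte that mismatches both bases and query padding
    read_arr = _to_bytes(seq, _V_WINDOW + _V_MAX_OFFSET, 1)
    windows = sliding_window_view(read_arr, _V_WINDOW)[: _V_MAX_OFFSET + 1]
    mm_padded = (windows[None, :, :] != qmat[:, None, :]).sum(axis=2)
    offs = np.arange(windows.shape[0])
    spans = np.minimum(qlens[:, None], np.maximum(len(seq) - offs[None, :], 0))
    mm = mm_padded - (_V_WINDOW - spans)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(spans > 0, mm / np.maximum(spans, 1), 1.0)
    score = spans - 2 * mm
    ok = (spans >= _J_MIN_SPAN) & (frac <= max_mismatch_frac)
    if not ok.any():
        return None
    score_ok = np.where(ok, score, np.iinfo(np.int64).min)
    best = int(score_ok.max())
    cand = np.argwhere(score_ok == best)
    # tie-break on segment name, then offset
    _, qi, oi = min((names[int(q)], int(q), int(o)) for q, o in cand)
    span = int(spans[qi, oi])
    tail = tail_lens[qi]
    v_span = span - tail
    if v_span <= 0:
        return None
    v = reference.v(names[qi])
    start = primer_starts[qi]
    read_start = oi + tail
    read_end = oi + span
    mm_v = _hamming(seq[read_start:read_end], v.sequence[start : start + v_span])
    return Alignment(
        segment_name=names[qi],
        score=v_span - 2 * mm_v,
        mismatches=mm_v,
        read_start=read_start,
        read_end=read_end,
        ref_start=start,
        ref_end=start + v_span,
    )


def assign_j(
    read2: ReadRecord,
    reference: SegmentReference,
    max_mismatch: int = 2,
    min_offset: int = 0,
) -> Alignment | None:
    """Best ungapped J hit at offsets 3' of ``min_offset`` (the V end), or None.

    Accepted when mismatches <= ``max_mismatch`` over an aligned span of at
    least 20 nt (the span may be truncated by the read end). Score ties break
    to the smallest segment name, then the smallest offset.
    """
    seq = read2.sequence
    if len(seq) < _MIN_READ_LEN:
        return None
    names, arrs = _j_index(reference)
    n = len(seq)
    best: tuple[int, str, int, int] | None = None  # (-score, name, offset, span)
    read_raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    for name, jarr in sorted(zip(names, arrs)):
        lj = jarr.size
        max_off = n - _J_MIN_SPAN
        if max_off < min_offset:
            continue
        padded = np.full(n + lj, 1, dtype=np.uint8)
        padded[:n] = read_raw
        windows = sliding_window_view(padded, lj)[min_offset : max_off + 1]
        mm_padded = (windows != jarr[None, :]).sum(axis=1)
        offs = np.arange(min_offset, max_off + 1)
        spans = np.minimum(lj, n - offs)
        mm = mm_padded - (lj - spans)
        ok = (spans >= _J_MIN_SPAN) & (mm <= max_mismatch)
        if not ok.any():
            continue
        score = spans - 2 * mm
        score_ok = np.where(ok, score, np.iinfo(np.int64).min)
        oi = int(score_ok.argmax())  # argmax takes the first (smallest offset)
        cand = (-int(score_ok[oi]), name, int(offs[oi]), int(spans[oi]))
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    neg_score, name, off, span = best
    return Alignment(
        segment_name=name,
        score=-neg_score,
        mismatches=(span - (-neg_score)) // 2,
        read_start=off,
        read_end=off + span,
        ref_start=0,
        ref_end=span,
    )


def extract_cdr3(
    read2: ReadRecord,
    v_aln: Alignment,
    j_aln: Alignment,
    reference: SegmentReference,
) -> tuple[str, str, bool]:
    """CDR3 from the V Cys codon through the J Phe codon, inclusive.

    Returns (cdr3_nt, cdr3_aa, productive). cdr3_aa is empty when the length
    is not a multiple of three; productive requires in-frame translation with
    no stop, starting with C and ending with F. Raises ExtractionError when
    either anchor codon falls outside the read.
    """
    seq = read2.sequence
    cys = reference.v(v_aln.segment_name).cys_offset
    phe = reference.j(j_aln.segment_name).phe_offset
    cys_read = v_aln.read_start + (cys - v_aln.ref_start)
    phe_read = j_aln.read_start + (phe - j_aln.ref_start)
    if cys_read < 0 or phe_read + 3 > len(seq) or cys_read >= phe_read + 3:
        raise ExtractionError(
            f"read {read2.read_id}: CDR3 anchors outside read "
            f"(cys at {cys_read}, phe at {phe_read}, length {len(seq)})"
        )
    cdr3_nt = seq[cys_read : phe_read + 3]
    if len(cdr3_nt) % 3 != 0:
        return cdr3_nt, "", False
    aa = translate_nt(cdr3_nt)
    productive = bool(aa) and "*" not in aa and aa[0] == "C" and aa[-1] == "F"
    return cdr3_nt, aa, productive


def assemble_clones(
    assignments,
) -> tuple[list[Clonotype], dict[str, int]]:
    """Group per-read assignments into clonotypes.

    Clone key = exact (v_gene, j_gene, cdr3_nt). Clones are numbered 1..K by
    descending read support, ties by first-seen order.
    """
    order: list[tuple[str, str, str]] = []
    reads_by_key: dict[tuple[str, str, str], list[str]] = {}
    meta: dict[tuple[str, str, str], tuple[str, bool]] = {}
    for a in assignments:
        key = (a.v_gene, a.j_gene, a.cdr3_nt)
        if key not in reads_by_key:
            order.append(key)
            reads_by_key[key] = []
            meta[key] = (a.cdr3_aa, a.productive)
        reads_by_key[key].append(a.read_id)
    first_seen = {key: i for i, key in enumerate(order)}
    ranked = sorted(order, key=lambda k: (-len(reads_by_key[k]), first_seen[k]))
    clones: list[Clonotype] = []
    read_to_clone: dict[str, int] = {}
    for cid, key in enumerate(ranked, start=1):
        v_gene, j_gene, cdr3_nt = key
        aa, productive = meta[key]
        clones.append(
            Clonotype(
                clone_id=cid, v_gene=v_gene, j_gene=j_gene, cdr3_nt=cdr3_nt,
                cdr3_aa=aa, productive=productive, chain=chain_of(v_gene),
                read_support=len(reads_by_key[key]),
            )
        )
        for rid in reads_by_key[key]:
            read_to_clone[rid] = cid
    return clones, read_to_clone


def call_clones(
    path_r2: str | os.PathLike,
    reference: SegmentReference,
    primer_pool: PrimerPool,
    max_mismatch_frac: float = 0.1,
    j_max_mismatch: int = 2,
) -> tuple[list[Clonotype], dict[str, int], dict[str, int]]:
    """Run the native caller over a read 2 FASTQ.

    Returns (clones, read_id -> clone_id, drop log). The drop log counts
    reads by fate: total, no_v, no_j, cdr3_fail, assigned. Reads with a V but
    no J are logged, never assigned to a clone.
    """
    log = {"total": 0, "no_v": 0, "no_j": 0, "cdr3_fail": 0, "assigned": 0}
    assignments: list[ReadAssignment] = []
    for rec in sio.read_fastq(path_r2):
        log["total"] += 1
        v_aln = assign_v(rec, reference, primer_pool, max_mismatch_frac)
        if v_aln is None:
            log["no_v"] += 1
            continue
        j_aln = assign_j(rec, reference, j_max_mismatch, min_offset=v_aln.read_end)
        if j_aln is None:
            log["no_j"] += 1
            continue
        try:
            cdr3_nt, cdr3_aa, productive = extract_cdr3(rec, v_aln, j_aln, reference)
        except ExtractionError:
            log["cdr3_fail"] += 1
            continue
        log["assigned"] += 1
        assignments.append(
            ReadAssignment(
                rec.read_id, v_aln.segment_name, j_aln.segment_name,
                cdr3_nt, cdr3_aa, productive,
            )
        )
    clones, read_to_clone = assemble_clones(assignments)
    return clones, read_to_clone, log


def export_reads_for_clones(
    read_to_clone: dict[str, int],
    path_r2: str | os.PathLike,
    out_dir: str | os.PathLike,
) -> dict[int, Path]:
    """Write per-clone read 2 FASTQs: reads_cln<N>.fastq.gz, N = clone_id - 1.

    File numbering is 0-based (matching the common repertoire-caller export
    convention); clone ids in tables stay 1-based.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_clone: dict[int, list] = {}
    for rec in sio.read_fastq(path_r2):
        cid = read_to_clone.get(rec.read_id)
        if cid is not None:
            by_clone.setdefault(cid, []).append(rec)
    paths: dict[int, Path] = {}
    for cid in sorted(set(read_to_clone.values())):
        path = out_dir / f"reads_cln{cid - 1}.fastq.gz"
        sio.write_fastq(by_clone.get(cid, []), path)
        paths[cid] = path
    return paths


def _clean_hit(hit: str) -> str:
    """'TRBV9*00(1234.5)' -> 'TRBV9'; first hit of a comma-separated list."""
    first = hit.split(",")[0]
    for sep in ("*", "("):
        first = first.split(sep)[0]
    return first.strip()


_DEFAULT_COLUMNS = {
    "clone_id": "cloneId",
    "read_count": "readCount",
    "v_hit": "vGene",
    "j_hit": "jGene",
    "cdr3_nt": "nSeqCDR3",
    "cdr3_aa": "aaSeqCDR3",
}


def import_mixcr(
    clones_table: str | os.PathLike,
    reads_dir: str | os.PathLike,
    columns: dict[str, str] | None = None,
    id_base: int = 1,
) -> tuple[list[Clonotype], dict[str, int]]:
    """Import an external clone table plus per-clone read FASTQs.

    ``columns`` maps the semantic fields (clone_id, read_count, v_hit, j_hit,
    cdr3_nt, cdr3_aa) to the table's column names; defaults match this
    package's own export. For MiXCR tables pass e.g. ``{"read_count":
    "cloneCount", "v_hit": "allVHitsWithScore", ...}`` and ``id_base=0``
    (MiXCR numbers clones from 0). Per-clone files are looked up as
    reads_cln<raw_id - id_base>.fastq.gz; a clone with a missing file gets a
    warning and zero mapped reads. Chain is set from the V-hit prefix.
    """
    import csv

    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    reads_dir = Path(reads_dir)
    clones: list[Clonotype] = []
    read_to_clone: dict[str, int] = {}
    with open(clones_table, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{os.fspath(clones_table)}: empty clone table")
        for semantic in ("clone_id", "read_count", "v_hit", "j_hit", "cdr3_nt"):
            if cols[semantic] not in reader.fieldnames:
                raise FormatError(
                    f"{os.fspath(clones_table)}: missing column {cols[semantic]!r}"
                )
        for row in reader:
            try:
                raw_id = int(row[cols["clone_id"]])
                read_count = int(float(row[cols["read_count"]]))
            except ValueError as exc:
                raise FormatError(
                    f"{os.fspath(clones_table)}: unparseable numeric field: {exc}"
                ) from exc
            v_gene = _clean_hit(row[cols["v_hit"]])
            j_gene = _clean_hit(row[cols["j_hit"]])
            cdr3_nt = row[cols["cdr3_nt"]].strip().upper()
            cdr3_aa = (row.get(cols["cdr3_aa"]) or "").strip()
            if not cdr3_aa and len(cdr3_nt) % 3 == 0 and cdr3_nt:
                cdr3_aa = translate_nt(cdr3_nt)
            prod_col = row.get("productive")
            if prod_col is not None and prod_col != "":
                productive = prod_col.lower() in ("true", "1", "yes")
            else:
                productive = (
                    len(cdr3_nt) % 3 == 0
                    and bool(cdr3_aa)
                    and "*" not in cdr3_aa
                    and cdr3_aa[0] == "C"
                    and cdr3_aa[-1] == "F"
                )
            clone_id = raw_id - id_base + 1
            clone = Clonotype(
                clone_id=clone_id, v_gene=v_gene, j_gene=j_gene,
                cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, productive=productive,
                chain=chain_of(v_gene), read_support=read_count,
            )
            fastq = reads_dir / f"reads_cln{raw_id - id_base}.fastq.gz"
            if not fastq.exists():
                fastq_plain = reads_dir / f"reads_cln{raw_id - id_base}.fastq"
                if fastq_plain.exists():
                    fastq = fastq_plain
                else:
                    warnings.warn(
                        f"clone {raw_id}: missing reads file {fastq.name}; "
                        "zero reads mapped"
                    )
                    clones.append(clone)
                    continue
            for rec in sio.read_fastq(fastq):
                read_to_clone[rec.read_id] = clone_id
            clones.append(clone)
    return clones, read_to_clone
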