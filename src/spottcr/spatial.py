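"""Link clone-supporting reads to capture spots and build the count matrix.

For every clone-supporting read, the paired read 1 yields the 16-nt spatial
barcode (bases 0-16) and 12-nt UMI (bases 16-28). Barcodes are matched
against the spot whitelist — exactly by default, optionally with unique
single-mismatch rescue. Records are deduplicated so each (barcode, UMI)
combination contributes one count, and counts are laid out as a matrix with
in-tissue spots as rows and clones as columns. Off-tissue hits are reported
separately (they are a tissue-permeabilization diagnostic, not noise to
discard silently).
"""

from __future__ import annotations

import os
from collections import Counter, defaultdict
from collections.abc import Iterable

import numpy as np

from . import io as sio
from .types import (
    BARCODE_LEN,
    LinkLog,
    LinkedRecord,
    MIN_READ1_LEN,
    ReadRecord,
    SpotCloneMatrix,
    SpotMap,
    UMI_LEN,
    ValidationError,
)


def extract_barcode_umi(read1: ReadRecord) -> tuple[str, str]:
    """Spatial barcode = bases [0,16), UMI = bases [16,28) of read 1.

    Read 1 must be at least 28 nt (the sequencing protocol requires at least
    28 cycles to cover barcode + UMI); shorter reads are a hard error.
    """
    if len(read1.sequence) < MIN_READ1_LEN:
        raise ValidationError(
            f"read {read1.read_id}: read 1 is {len(read1.sequence)} nt, "
            f"need >= {MIN_READ1_LEN} to cover barcode + UMI"
        )
    return read1.sequence[:BARCODE_LEN], read1.sequence[BARCODE_LEN:MIN_READ1_LEN]


def match_barcode(
    barcode: str, spot_map: SpotMap, max_hamming: int = 0
) -> tuple[str | None, str]:
    """Match a barcode to the whitelist; returns (matched barcode, status).

    Status is "in_tissue", "off_tissue" or "unmatched". An exact hit always
    wins. With ``max_hamming=1`` a Hamming-distance-1 whitelist barcode is
    accepted only when unique (two candidates -> unmatched). Any N in the
    barcode -> unmatched.
    """
    if max_hamming not in (0, 1):
        raise ValueError("max_hamming must be 0 or 1")
    if "N" in barcode:
        return None, "unmatched"
    entry = spot_map.get(barcode)
    if entry is not None:
        return barcode, "in_tissue" if entry.in_tissue else "off_tissue"
    if max_hamming == 1:
        hit: str | None = None
        for e in spot_map.entries:
            if sum(a != b for a, b in zip(barcode, e.barcode)) == 1:
                if hit is not None:
                    return None, "unmatched"  # ambiguous
                hit = e.barcode
        if hit is not None:
            e = spot_map.get(hit)
            return hit, "in_tissue" if e.in_tissue else "off_tissue"
    return None, "unmatched"


def deduplicate(records: Iterable[LinkedRecord]) -> list[LinkedRecord]:
    """Collapse records so each (barcode, UMI) combination is used once.

    Duplicates within one clone collapse to a single record. When one
    (barcode, UMI) pair is claimed by several clones, the clone with the most
    supporting reads in that pair wins; an exact tie discards the pair
    entirely. Output order follows first appearance of each surviving pair.
    """
    support: dict[tuple[str, str], Counter] = defaultdict(Counter)
    first: dict[tuple[str, str, int], LinkedRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        if rec.matched == "unmatched":
            raise ValidationError("deduplicate() requires matched records")
        pair = (rec.barcode, rec.umi)
        if pair not in support:
            order.append(pair)
        support[pair][rec.clone_id] += 1
        first.setdefault((rec.barcode, rec.umi, rec.clone_id), rec)
    out: list[LinkedRecord] = []
    for pair in order:
        counts = support[pair]
        top = max(counts.values())
        winners = [cid for cid, n in counts.items() if n == top]
        if len(winners) > 1:
            continue  # ambiguous pair, discarded
        out.append(first[(pair[0], pair[1], winners[0])])
    return out


def link(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    read_to_clone: dict[str, int],
    spot_map: SpotMap,
    max_hamming: int = 0,
) -> tuple[list[LinkedRecord], LinkLog]:
    """Resolve clone-supporting read pairs to spots.

    Iterates (read 1, read 2) pairs, keeps those whose id is in the clone
    map, extracts barcode/UMI from read 1 and matches the barcode. The log
    counts every clone-supporting read as in_tissue, off_tissue or
    unmatched_barcode.
    """
    records: list[LinkedRecord] = []
    log = LinkLog()
    for rec1, _rec2 in pairs:
        cid = read_to_clone.get(rec1.read_id)
        if cid is None:
            continue
        log.total += 1
        barcode, umi = extract_barcode_umi(rec1)
        matched, status = match_barcode(barcode, spot_map, max_hamming)
        if status == "unmatched":
            log.unmatched_barcode += 1
            continue
        if status == "in_tissue":
            log.in_tissue += 1
        else:
            log.off_tissue += 1
        records.append(
            LinkedRecord(
                read_id=rec1.read_id, barcode=matched, umi=umi,
                clone_id=cid, matched=status,
            )
        )
    return records, log


def link_files(
    path_r1: str | os.PathLike,
    path_r2: str | os.PathLike,
    read_to_clone: dict[str, int],
    spot_map: SpotMap,
    max_hamming: int = 0,
) -> tuple[list[LinkedRecord], LinkLog]:
    """File-level convenience wrapper around :func:`link`."""
    pairs = sio.read_fastq_pairs(path_r1, path_r2)
    return link(pairs, read_to_clone, spot_map, max_hamming)


def build_matrix(deduped: Iterable[LinkedRecord], spot_map: SpotMap) -> SpotCloneMatrix:
    """Spot-by-clone UMI matrix from deduplicated records.

    Rows are ALL in-tissue barcodes of the spot map in file order (all-zero
    rows included); columns are clones with at least one in-tissue UMI,
    ordered by clone id. Off-tissue records go to ``off_tissue_counts``.
    """
    rows = spot_map.in_tissue_barcodes
    row_ix = {b: i for i, b in enumerate(rows)}
    cell: dict[tuple[str, int], int] = defaultdict(int)
    off: dict[tuple[str, int], int] = defaultdict(int)
    for rec in deduped:
        if rec.matched == "in_tissue":
            if rec.barcode not in row_ix:
                raise ValidationError(
                    f"in-tissue record barcode {rec.barcode} absent from spot map"
                )
            cell[(rec.barcode, rec.clone_id)] += 1
        elif rec.matched == "off_tissue":
            off[(rec.barcode, rec.clone_id)] += 1
        else:
            raise ValidationError("build_matrix() requires matched records")
    cols = sorted({cid for (_, cid) in cell})
    col_ix = {c: j for j, c in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for (b, c), n in cell.items():
        counts[row_ix[b], col_ix[c]] += n
    return SpotCloneMatrix(
        row_barcodes=list(rows), col_clone_ids=cols, counts=counts,
        off_tissue_counts=dict(off),
    )


def write_link_log(log: LinkLog, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as out:
        out.write("total\tunmatched_barcode\toff_tissue\tin_tissue\n")
        out.write(f"{log.total}\t{log.unmatched_barcode}\t{log.off_tissue}\t{log.in_tissue}\n")
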