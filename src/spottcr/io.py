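"""Readers and writers for the external formats the pipeline touches.

FASTQ (plain or gzip), Space Ranger tissue positions lists (headerless v1 and
headered v2 dialects), TRBV primer-pool manifests, V/J segment references
(FASTA plus an anchor table), clone tables and the spot-by-clone matrix TSV.
All text outputs use "\\n" line endings and carry no trailing whitespace.
"""

from __future__ import annotations

import csv
import gzip
import io as _io
import os
import re
from collections.abc import Iterable, Iterator
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import (
    Clonotype,
    FastqParseError,
    FormatError,
    JSegment,
    PairingError,
    Primer,
    PrimerPool,
    ReadRecord,
    SegmentReference,
    SpotCloneMatrix,
    SpotEntry,
    SpotMap,
    VSegment,
    ValidationError,
)

_GEM_SUFFIX = re.compile(r"-\d+$")


def open_text(path: str | os.PathLike, mode: str = "rt"):
    """Open plain or gzip text transparently (by .gz extension).

    Gzip output is written with mtime=0 so identical content gives identical
    bytes — required for reproducible pipelines.
    """
    path = os.fspath(path)
    if path.endswith(".gz"):
        if "r" in mode:
            return gzip.open(path, "rt")
        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return _io.TextIOWrapper(gz, newline="\n")
    return open(path, mode, newline="" if "w" in mode else None)


def normalize_read_id(title: str) -> str:
    """FASTQ title -> read id: drop the comment and any /1 or /2 mate suffix."""
    rid = title.split(None, 1)[0]
    if rid.endswith(("/1", "/2")):
        rid = rid[:-2]
    return rid


def read_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ(.gz) file; ids are normalized."""
    n = 0
    try:
        with open_text(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                yield ReadRecord(normalize_read_id(title), seq.upper(), qual)
    except ValueError as exc:
        raise FastqParseError(
            f"{os.fspath(path)}: malformed FASTQ near line {4 * n + 1}: {exc}"
        ) from exc


def read_fastq_pairs(
    path_r1: str | os.PathLike, path_r2: str | os.PathLike
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Yield (read 1, read 2) pairs matched by normalized read id.

    Read 1 is indexed in memory; output order follows the read 2 file. Pairing
    is by name, not file order, because per-clone read exports reorder reads.
    """
    index: dict[str, ReadRecord] = {}
    for rec in read_fastq(path_r1):
        index[rec.read_id] = rec
    for rec2 in read_fastq(path_r2):
        rec1 = index.get(rec2.read_id)
        if rec1 is None:
            raise PairingError(
                f"read id {rec2.read_id!r} from {os.fspath(path_r2)} "
                f"has no mate in {os.fspath(path_r1)}"
            )
        yield rec1, rec2


def write_fastq(records: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open_text(path, "wt") as out:
        for rec in records:
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")


# ---------------------------------------------------------------------------
# tissue positions list


def read_spot_map(
    path: str | os.PathLike, suffix_policy: str = "strip_gem_suffix"
) -> SpotMap:
    """Load a Space Ranger tissue positions CSV.

    The v2 dialect (header line containing a "barcode" token) and the
    headerless v1 dialect are auto-detected. Gem-group suffixes like "-1" are
    stripped under the default policy, because raw read barcodes carry none.
    """
    rows: list[SpotEntry] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        first = next(reader, None)
        if first is None:
            return SpotMap(entries=[], suffix_policy=suffix_policy)
        has_header = any("barcode" in cell.lower() for cell in first)
        data = reader if has_header else iter([first] + list(reader))
        for lineno, row in enumerate(data, start=2 if has_header else 1):
            if len(row) != 6:
                raise FormatError(
                    f"{os.fspath(path)} line {lineno}: expected 6 columns, "
                    f"got {len(row)}"
                )
            barcode = row[0].strip()
            if suffix_policy == "strip_gem_suffix":
                barcode = _GEM_SUFFIX.sub("", barcode)
            try:
                rows.append(
                    SpotEntry(
                        barcode=barcode,
                        in_tissue=bool(int(row[1])),
                        array_row=int(row[2]),
                        array_col=int(row[3]),
                        pxl_row=int(row[4]),
                        pxl_col=int(row[5]),
                    )
                )
            except ValueError as exc:
                raise FormatError(
                    f"{os.fspath(path)} line {lineno}: {exc}"
                ) from exc
    return SpotMap(entries=rows, suffix_policy=suffix_policy)


def write_spot_map(
    spot_map: SpotMap, path: str | os.PathLike, dialect: str = "v1"
) -> None:
    """Write a tissue positions CSV in the v1 (headerless) or v2 dialect."""
    if dialect not in ("v1", "v2"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    with open(path, "w", newline="") as out:
        if dialect == "v2":
            out.write(
                "barcode,in_tissue,array_row,array_col,"
                "pxl_row_in_fullres,pxl_col_in_fullres\n"
            )
        for e in spot_map.entries:
            out.write(
                f"{e.barcode},{int(e.in_tissue)},{e.array_row},"
                f"{e.array_col},{e.pxl_row},{e.pxl_col}\n"
            )


# ---------------------------------------------------------------------------
# primer pool


def load_primer_pool(path: str | os.PathLike) -> PrimerPool:
    """Load a TRBV primer manifest TSV (v_gene_name, primer_seq, read2_tail)."""
    primers: list[Primer] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"v_gene_name", "primer_seq", "read2_tail"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"{os.fspath(path)}: primer manifest needs columns {sorted(required)}"
            )
        for row in reader:
            primers.append(
                Primer(
                    v_gene_name=row["v_gene_name"].strip(),
                    primer_seq=row["primer_seq"].strip().upper(),
                    read2_tail=row["read2_tail"].strip().upper(),
                )
            )
    return PrimerPool(primers=primers)


def write_primer_pool(pool: PrimerPool, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as out:
        out.write("v_gene_name\tprimer_seq\tread2_tail\n")
        for p in pool.primers:
            out.write(f"{p.v_gene_name}\t{p.primer_seq}\t{p.read2_tail}\n")


def pool_concentration(n_primers: int, total_conc_uM: float) -> float:
    """Per-primer concentration of an equimolar pool: total / n.

    With the standard 45-primer TRBV pool at 10 uM total this is ~0.22 uM.
    """
    if n_primers < 1:
        raise ValueError("n_primers must be >= 1")
    if total_conc_uM <= 0:
        raise ValueError("total_conc_uM must be > 0")
    return total_conc_uM / n_primers


# ---------------------------------------------------------------------------
# segment reference (FASTA + anchor TSV)


def write_reference(
    reference: SegmentReference,
    fasta_path: str | os.PathLike,
    anchors_path: str | os.PathLike,
) -> None:
    """Write segments as FASTA plus a TSV of (name, segment_type, anchor_offset)."""
    with open(fasta_path, "w", newline="") as fa:
        for v in reference.v_segments:
            fa.write(f">{v.name}\n{v.sequence}\n")
        for j in reference.j_segments:
            fa.write(f">{j.name}\n{j.sequence}\n")
        if reference.constant_prefix:
            fa.write(f">constant\n{reference.constant_prefix}\n")
    with open(anchors_path, "w", newline="") as out:
        out.write("name\tsegment_type\tanchor_offset\n")
        for v in reference.v_segments:
            out.write(f"{v.name}\tV\t{v.cys_offset}\n")
        for j in reference.j_segments:
            out.write(f"{j.name}\tJ\t{j.phe_offset}\n")
        if reference.constant_prefix:
            out.write("constant\tC\t\n")


def read_reference(
    fasta_path: str | os.PathLike, anchors_path: str | os.PathLike
) -> SegmentReference:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    v_segments: list[VSegment] = []
    j_segments: list[JSegment] = []
    constant_prefix = ""
    with open(anchors_path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            name = row["name"]
            if name not in seqs:
                raise FormatError(f"anchor table names {name!r} absent from FASTA")
            seg_type = row["segment_type"]
            if seg_type == "V":
                v_segments.append(
                    VSegment(name, seqs[name], int(row["anchor_offset"]))
                )
            elif seg_type == "J":
                j_segments.append(
                    JSegment(name, seqs[name], int(row["anchor_offset"]))
                )
            elif seg_type == "C":
                constant_prefix = seqs[name]
            else:
                raise FormatError(f"unknown segment_type {seg_type!r}")
    return SegmentReference(
        v_segments=v_segments, j_segments=j_segments, constant_prefix=constant_prefix
    )


# ---------------------------------------------------------------------------
# clone table and spot-clone matrix


def write_clones_table(clones: Iterable[Clonotype], path: str | os.PathLike) -> None:
    """Write clones as TSV, sorted by descending readCount then ascending cloneId."""
    rows = sorted(clones, key=lambda c: (-c.read_support, c.clone_id))
    with open(path, "w", newline="") as out:
        out.write(
            "cloneId\treadCount\tvGene\tjGene\tnSeqCDR3\taaSeqCDR3\t"
            "productive\tchain\n"
        )
        for c in rows:
            out.write(
                f"{c.clone_id}\t{c.read_support}\t{c.v_gene}\t{c.j_gene}\t"
                f"{c.cdr3_nt}\t{c.cdr3_aa}\t{str(c.productive).lower()}\t{c.chain}\n"
            )


def read_clones_table(path: str | os.PathLike) -> list[Clonotype]:
    clones: list[Clonotype] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            from .types import chain_of

            clones.append(
                Clonotype(
                    clone_id=int(row["cloneId"]),
                    v_gene=row["vGene"],
                    j_gene=row["jGene"],
                    cdr3_nt=row["nSeqCDR3"],
                    cdr3_aa=row["aaSeqCDR3"],
                    productive=row["productive"].lower() == "true",
                    chain=row.get("chain") or chain_of(row["vGene"]),
                    read_support=int(row["readCount"]),
                )
            )
    return clones


def write_matrix(matrix: SpotCloneMatrix, path: str | os.PathLike) -> None:
    """Write the spot-by-clone UMI matrix as TSV.

    Header: "barcode" then one "clone<id>" label per column. One row per
    in-tissue barcode (zeros included). Off-tissue hits go to a sibling file
    "<path>.off_tissue.tsv" with columns barcode, clone, umis.
    """
    path = os.fspath(path)
    with open(path, "w", newline="") as out:
        header = "barcode" + "".join(f"\tclone{cid}" for cid in matrix.col_clone_ids)
        out.write(header + "\n")
        for i, barcode in enumerate(matrix.row_barcodes):
            cells = "".join(f"\t{int(matrix.counts[i, j])}" for j in range(matrix.counts.shape[1]))
            out.write(barcode + cells + "\n")
    off_path = path + ".off_tissue.tsv"
    with open(off_path, "w", newline="") as out:
        out.write("barcode\tclone\tumis\n")
        for (barcode, cid), n in sorted(matrix.off_tissue_counts.items()):
            out.write(f"{barcode}\tclone{cid}\t{n}\n")


def read_matrix(path: str | os.PathLike) -> SpotCloneMatrix:
    """Re-parse a matrix TSV written by :func:`write_matrix` (off-tissue included)."""
    import numpy as np

    path = os.fspath(path)
    with open(path, newline="") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[0] != "barcode":
            raise FormatError(f"{path}: first header cell must be 'barcode'")
        clone_ids = [int(h.removeprefix("clone")) for h in header[1:]]
        barcodes: list[str] = []
        rows: list[list[int]] = []
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            barcodes.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    counts = np.array(rows, dtype=np.int64).reshape(len(barcodes), len(clone_ids))
    off: dict[tuple[str, int], int] = {}
    off_path = path + ".off_tissue.tsv"
    if os.path.exists(off_path):
        with open(off_path, newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            for row in reader:
                off[(row["barcode"], int(row["clone"].removeprefix("clone")))] = int(
                    row["umis"]
                )
    return SpotCloneMatrix(
        row_barcodes=barcodes, col_clone_ids=clone_ids, counts=counts,
        off_tissue_counts=off,
    )
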