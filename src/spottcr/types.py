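"""Core domain types for spatial TCR-seq analysis.

The library models a targeted-amplicon Visium workflow: read 1 of each pair
carries a 16-nt spatial barcode followed by a 12-nt UMI; read 2 carries a
TCR-beta amplicon whose CDR3 spans the conserved V-segment cysteine to the
conserved J-segment phenylalanine (FGXG motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field

BARCODE_LEN = 16
UMI_LEN = 12
MIN_READ1_LEN = BARCODE_LEN + UMI_LEN  # read 1 must cover barcode + UMI

_DNA = set("ACGTN")
_DNA_STRICT = set("ACGT")


class SpotTCRError(Exception):
    """Base class for all errors raised by this package."""


class FastqParseError(SpotTCRError):
    """A FASTQ record could not be parsed."""


class PairingError(SpotTCRError):
    """A read 2 id has no mate in the read 1 file."""


class FormatError(SpotTCRError):
    """A tabular input file does not match the expected layout."""


class ValidationError(SpotTCRError):
    """An input violates a domain invariant (duplicate barcode, bad DNA...)."""


class ExtractionError(SpotTCRError):
    """CDR3 anchor codons fall outside the read."""


class ConfigError(SpotTCRError):
    """A configuration combination is unusable."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id (no pairing suffix/comment), sequence, qualities."""

    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if not self.read_id or any(c.isspace() for c in self.read_id):
            raise ValidationError(f"bad read id: {self.read_id!r}")
        if len(self.sequence) != len(self.qualities):
            raise ValidationError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class SpotEntry:
    """One row of a Space Ranger tissue positions list."""

    barcode: str
    in_tissue: bool
    array_row: int
    array_col: int
    pxl_row: int
    pxl_col: int


@dataclass(eq=False)
class SpotMap:
    """Capture-spot whitelist: barcode -> (in_tissue, array/pixel coordinates).

    ``suffix_policy`` records whether "-N" gem-group suffixes were stripped on
    load (raw read barcodes never carry the suffix).
    """

    entries: list[SpotEntry]
    suffix_policy: str = "strip_gem_suffix"
    _index: dict[str, SpotEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, SpotEntry] = {}
        for e in self.entries:
            if len(e.barcode) != BARCODE_LEN or not set(e.barcode) <= _DNA_STRICT:
                raise ValidationError(f"bad spot barcode: {e.barcode!r}")
            if e.barcode in index:
                raise ValidationError(f"duplicate spot barcode: {e.barcode}")
            index[e.barcode] = e
        self._index = index

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def get(self, barcode: str) -> SpotEntry | None:
        return self._index.get(barcode)

    @property
    def in_tissue_barcodes(self) -> list[str]:
        """In-tissue barcodes in file order."""
        return [e.barcode for e in self.entries if e.in_tissue]

    @property
    def off_tissue_barcodes(self) -> list[str]:
        return [e.barcode for e in self.entries if not e.in_tissue]


@dataclass(frozen=True)
class Primer:
    v_gene_name: str
    primer_seq: str
    read2_tail: str


@dataclass(eq=False)
class PrimerPool:
    """An equimolar pool of TRBV-specific primers with 5' read-2 tails.

    Concentrations are unset until :func:`spottcr.io.pool_concentration` /
    :meth:`set_concentration` is applied.
    """

    primers: list[Primer]
    total_conc_uM: float | None = None
    per_primer_conc_uM: float | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.primers:
            if p.v_gene_name in seen:
                raise ValidationError(f"duplicate primer gene name: {p.v_gene_name}")
            seen.add(p.v_gene_name)
            if not p.primer_seq:
                raise ValidationError(f"empty primer sequence for {p.v_gene_name}")
            for s in (p.primer_seq, p.read2_tail):
                if not set(s) <= _DNA_STRICT:
                    raise ValidationError(
                        f"non-ACGT characters in primer entry {p.v_gene_name}"
                    )

    def __len__(self) -> int:
        return len(self.primers)

    def set_concentration(self, total_conc_uM: float) -> None:
        from .io import pool_concentration

        self.total_conc_uM = total_conc_uM
        self.per_primer_conc_uM = pool_concentration(len(self.primers), total_conc_uM)


_CODON_AA = None  # translation goes through Bio.Seq; see translate_nt


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string (standard code, '*' for stop)."""
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


@dataclass(frozen=True)
class VSegment:
    name: str
    sequence: str
    cys_offset: int  # 0-based index of the first base of the conserved Cys codon

    def __post_init__(self) -> None:
        if not 0 <= self.cys_offset <= len(self.sequence) - 3:
            raise ValidationError(f"{self.name}: cys_offset outside sequence")
        codon = self.sequence[self.cys_offset : self.cys_offset + 3]
        if translate_nt(codon) != "C":
            raise ValidationError(f"{self.name}: codon at cys_offset is not Cys")


@dataclass(frozen=True)
class JSegment:
    name: str
    sequence: str
    phe_offset: int  # 0-based index of the first base of the conserved Phe codon

    def __post_init__(self) -> None:
        if not 0 <= self.phe_offset <= len(self.sequence) - 3:
            raise ValidationError(f"{self.name}: phe_offset outside sequence")
        codon = self.sequence[self.phe_offset : self.phe_offset + 3]
        if translate_nt(codon) != "F":
            raise ValidationError(f"{self.name}: codon at phe_offset is not Phe")


@dataclass(eq=False)
class SegmentReference:
    """V/J segments with CDR3 anchor offsets, plus a constant-region prefix."""

    v_segments: list[VSegment]
    j_segments: list[JSegment]
    constant_prefix: str = ""

    def __post_init__(self) -> None:
        self._v_by_name = {v.name: v for v in self.v_segments}
        self._j_by_name = {j.name: j for j in self.j_segments}
        if len(self._v_by_name) != len(self.v_segments):
            raise ValidationError("duplicate V segment names")
        if len(self._j_by_name) != len(self.j_segments):
            raise ValidationError("duplicate J segment names")

    def v(self, name: str) -> VSegment:
        return self._v_by_name[name]

    def j(self, name: str) -> JSegment:
        return self._j_by_name[name]


def chain_of(v_gene: str) -> str:
    """Chain call from the V-gene name prefix: TRBV -> TRB, anything else -> other."""
    return "TRB" if v_gene.upper().startswith("TRBV") else "other"


@dataclass
class Clonotype:
    """A clonotype: (V gene, J gene, CDR3 nucleotide sequence) plus annotations."""

    clone_id: int
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    chain: str
    read_support: int = 0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_nt)


@dataclass(frozen=True)
class LinkedRecord:
    """One clone-supporting read resolved to (spatial barcode, UMI, clone)."""

    read_id: str
    barcode: str
    umi: str
    clone_id: int
    matched: str  # one of {"in_tissue", "off_tissue", "unmatched"}

    def __post_init__(self) -> None:
        if len(self.barcode) != BARCODE_LEN or not set(self.barcode) <= _DNA:
            raise ValidationError(f"bad barcode on {self.read_id}: {self.barcode!r}")
        if len(self.umi) != UMI_LEN or not set(self.umi) <= _DNA:
            raise ValidationError(f"bad UMI on {self.read_id}: {self.umi!r}")
        if self.matched not in ("in_tissue", "off_tissue", "unmatched"):
            raise ValidationError(f"bad matched status: {self.matched!r}")


@dataclass
class SpotCloneMatrix:
    """Deduplicated UMI counts: rows = in-tissue spots, columns = clones."""

    row_barcodes: list[str]
    col_clone_ids: list[int]
    counts: "object"  # numpy int array, shape (len(rows), len(cols))
    off_tissue_counts: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import numpy as np

        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_barcodes), len(self.col_clone_ids)):
            raise ValidationError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.row_barcodes)} rows x {len(self.col_clone_ids)} cols"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts in spot-clone matrix")

    @property
    def total_in_tissue_umis(self) -> int:
        return int(self.counts.sum())

    @property
    def total_off_tissue_umis(self) -> int:
        return int(sum(self.off_tissue_counts.values()))


@dataclass
class LinkLog:
    """Pre-dedup accounting for barcode matching of clone-supporting reads."""

    total: int = 0
    unmatched_barcode: int = 0
    off_tissue: int = 0
    in_tissue: int = 0


@dataclass
class RepertoireStats:
    """Per-sample repertoire summary mirroring the standard report columns."""

    n_reads: int
    n_tcr_umis: int
    n_clones: int
    shannon: float
    saturation: float | None
    umis_per_spot: float
    frac_reads_in_tissue: float
    n_non_trb_clones: int
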