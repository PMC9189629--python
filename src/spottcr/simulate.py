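"""Synthetic Visium-TCR dataset generator.

Emulates the library structure of the targeted spatial TCR-beta assay: read 1
carries a 16-nt spot barcode and 12-nt UMI; read 2 is a TRBV-primed amplicon
running 5'->3' through a read-2 tail, the V 3' region, the CDR3 junction, the
J segment and the start of the constant region. Molecules are PCR-duplicated
(1 + Poisson), substitution sequencing errors are applied per base, and the
generator emits complete ground truth (clones, spot placements, per-read
assignments) so every downstream stage can be verified exactly.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .types import (
    Clonotype,
    ConfigError,
    JSegment,
    Primer,
    PrimerPool,
    SegmentReference,
    SpotCloneMatrix,
    SpotEntry,
    SpotMap,
    VSegment,
    chain_of,
    translate_nt,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults describe a small tissue section: 50 spots (80% under tissue),
    20 T cell clones with geometrically skewed sizes placed on 5 spots each,
    20 molecules per clone-spot (~2,000 molecules total), PCR duplication
    mean 3, and no sequencing error or contamination unless switched on.
    """

    n_spots: int = 50
    frac_in_tissue: float = 0.8
    n_clones: int = 20
    clone_abundance: tuple = ("geometric", 0.7)  # or ("uniform",)
    clone_placement: dict[int, list[str]] | None = None
    spots_per_clone: int = 5
    umis_per_clone_spot: int = 20
    pcr_duplication_mean: float = 3.0
    seq_error_rate: float = 0.0
    frac_background_reads: float = 0.0
    frac_off_tissue: float = 0.0
    frac_bcr_like: float = 0.0
    seed: int = 0
    n_v: int = 45
    n_j: int = 13
    n_decoys: int = 0
    r1_len: int = 30
    r2_len: int = 300

    def __post_init__(self) -> None:
        for name in (
            "frac_in_tissue",
            "seq_error_rate",
            "frac_background_reads",
            "frac_off_tissue",
            "frac_bcr_like",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.n_spots < 1:
            raise ConfigError("n_spots must be >= 1")
        if self.pcr_duplication_mean < 1:
            raise ConfigError("pcr_duplication_mean must be >= 1")
        if self.frac_bcr_like > 0 and self.n_decoys == 0:
            self.n_decoys = 3


@dataclass
class TruthSet:
    """Ground truth emitted alongside the reads."""

    clones: list[Clonotype]
    placements: list[tuple[int, str, str]]  # (clone_id, barcode, umi)
    read_assignments: dict[str, tuple[int | None, str, str]]  # id -> (clone|None, bc, umi)

    def umi_counts_per_clone(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for cid, _, _ in self.placements:
            counts[cid] = counts.get(cid, 0) + 1
        return counts

    def clone_id_map(self, called_clones: list[Clonotype]) -> dict[int, int]:
        """Map called clone ids to truth clone ids via the exact clone key.

        Callers number clones by read support, which need not match the
        generator's numbering; comparisons against truth should go through
        this mapping.
        """
        truth_by_key = {c.key: c.clone_id for c in self.clones}
        return {
            c.clone_id: truth_by_key[c.key]
            for c in called_clones
            if c.key in truth_by_key
        }

    def matrix(self, spot_map: SpotMap) -> SpotCloneMatrix:
        """The expected deduplicated spot-by-clone matrix (in-tissue rows)."""
        rows = spot_map.in_tissue_barcodes
        in_tissue = set(rows)
        cell: dict[tuple[str, int], int] = {}
        off: dict[tuple[str, int], int] = {}
        for cid, barcode, _ in self.placements:
            if barcode in in_tissue:
                cell[(barcode, cid)] = cell.get((barcode, cid), 0) + 1
            else:
                off[(barcode, cid)] = off.get((barcode, cid), 0) + 1
        cols = sorted({cid for (_, cid) in cell})
        counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
        row_ix = {b: i for i, b in enumerate(rows)}
        col_ix = {c: j for j, c in enumerate(cols)}
        for (b, c), n in cell.items():
            counts[row_ix[b], col_ix[c]] = n
        return SpotCloneMatrix(
            row_barcodes=list(rows), col_clone_ids=cols, counts=counts,
            off_tissue_counts=off,
        )


# ---------------------------------------------------------------------------
# reference, primers, spots


_STOPS = {"TAA", "TAG", "TGA"}


def _scrub_stop(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    """Redraw the codon at ``pos`` until it is not a stop codon."""
    while "".join(seq[pos : pos + 3]) in _STOPS:
        seq[pos : pos + 3] = _random_dna(rng, 3)


def make_reference(
    n_v: int,
    n_j: int,
    seed: int,
    n_decoys: int = 0,
    decoy_identity: float = 0.7,
) -> SegmentReference:
    """Random V/J segment reference with valid CDR3 anchors.

    V segments are 250-300 nt and end within 10 nt of a TGT (Cys) codon at the
    recorded ``cys_offset``. J segments are 45-60 nt with a TTT/TTC (Phe)
    codon at ``phe_offset`` followed by GGN-XXX-GGN, consistent with the
    conserved FGXG motif. Optional decoy segments (named with a non-TRBV
    prefix) are V segments mutated down to ``decoy_identity``, standing in for
    cross-primed B cell receptor genes.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("n_v and n_j must be >= 1")
    rng = np.random.default_rng(seed)
    v_segments: list[VSegment] = []
    for i in range(n_v):
        length = int(rng.integers(250, 301))
        tail_after = int(rng.integers(0, 11))  # nt after the Cys codon
        cys_offset = length - 3 - tail_after
        seq = list(_random_dna(rng, length))
        seq[cys_offset : cys_offset + 3] = "TGT"
        # the post-Cys tail enters the CDR3 in frame; it must not carry a stop
        for p in range(cys_offset + 3, length - 2, 3):
            _scrub_stop(seq, p, rng)
        v_segments.append(VSegment(f"TRBV{i + 1}S", "".join(seq), cys_offset))
    j_segments: list[JSegment] = []
    for i in range(n_j):
        length = int(rng.integers(45, 61))
        phe_offset = int(rng.integers(4, 13))
        seq = list(_random_dna(rng, length))
        phe = "TTT" if rng.random() < 0.5 else "TTC"
        # F - G - X - G (motif codons right after the anchor Phe)
        motif = phe + "GG" + "ACGT"[rng.integers(0, 4)]
        motif += _random_dna(rng, 3) + "GG" + "ACGT"[rng.integers(0, 4)]
        seq[phe_offset : phe_offset + 12] = motif
        # pre-Phe codons (in frame counting back from the anchor) join the
        # CDR3 in frame; scrub stops there too
        for p in range(phe_offset - 3, -1, -3):
            _scrub_stop(seq, p, rng)
        j_segments.append(JSegment(f"TRBJ{i + 1}S", "".join(seq), phe_offset))
    for i in range(n_decoys):
        template = v_segments[i % n_v]
        seq = list(template.sequence)
        n_mut = int(round((1.0 - decoy_identity) * len(seq)))
        positions = rng.choice(len(seq), size=n_mut, replace=False)
        for p in positions:
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[rng.integers(0, 3)]
        cys = template.cys_offset
        seq[cys : cys + 3] = "TGT"  # keep the anchor intact
        for p in range(cys + 3, len(seq) - 2, 3):
            _scrub_stop(seq, p, rng)
        v_segments.append(VSegment(f"IGKV{i + 1}S", "".join(seq), cys))
    constant_prefix = _random_dna(rng, 30)
    return SegmentReference(
        v_segments=v_segments, j_segments=j_segments, constant_prefix=constant_prefix
    )


#: nt of V sequence retained between the primer 3' end and the Cys codon
_PRIMER_TO_CYS = 60
_PRIMER_LEN = 20


def make_primer_pool(reference: SegmentReference, seed: int) -> PrimerPool:
    """One primer per V segment: a 20-mer of the segment ~60 nt upstream of the
    Cys codon, carrying a shared 12-nt partial read-2 tail at the 5' end."""
    rng = np.random.default_rng(seed)
    tail = _random_dna(rng, 12)
    primers: list[Primer] = []
    for v in reference.v_segments:
        start = max(0, v.cys_offset - _PRIMER_TO_CYS - _PRIMER_LEN)
        primers.append(Primer(v.name, v.sequence[start : start + _PRIMER_LEN], tail))
    return PrimerPool(primers=primers)


def make_spot_map(n_spots: int, frac_in_tissue: float, seed: int) -> SpotMap:
    """Random whitelist of distinct 16-mer spot barcodes on a pseudo-grid."""
    rng = np.random.default_rng(seed)
    barcodes: set[str] = set()
    while len(barcodes) < n_spots:
        barcodes.add(_random_dna(rng, 16))
    ordered = sorted(barcodes)
    rng.shuffle(ordered)
    n_in = int(round(n_spots * frac_in_tissue))
    flags = np.zeros(n_spots, dtype=bool)
    flags[rng.choice(n_spots, size=n_in, replace=False)] = True
    side = int(np.ceil(np.sqrt(n_spots)))
    entries = [
        SpotEntry(
            barcode=b,
            in_tissue=bool(flags[i]),
            array_row=i // side,
            array_col=i % side,
            pxl_row=100 * (i // side),
            pxl_col=100 * (i % side),
        )
        for i, b in enumerate(ordered)
    ]
    return SpotMap(entries=entries)


# ---------------------------------------------------------------------------
# repertoire


def _abundance_weights(config: SimConfig, n: int) -> np.ndarray:
    kind = config.clone_abundance[0]
    if kind == "uniform":
        return np.ones(n)
    if kind == "geometric":
        ratio = float(config.clone_abundance[1])
        if not 0 < ratio <= 1:
            raise ConfigError("geometric ratio must be in (0,1]")
        return ratio ** np.arange(n)
    raise ConfigError(f"unknown clone_abundance: {config.clone_abundance!r}")


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across ``weights``, min 1."""
    quotas = total * weights / weights.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return np.maximum(counts, 1)


def make_repertoire(reference: SegmentReference, config: SimConfig) -> list[Clonotype]:
    """Draw the clonotypes of one synthetic repertoire.

    Every clone is productive: CDR3 = V Cys codon region + 0-21 random
    junction nucleotides (length adjusted to keep frame) + the J region up to
    and including the Phe codon, redrawn until the translation C...F carries
    no stop. ``read_support`` on the returned clones holds the *intended
    number of distinct molecules* (the UMI budget realized by
    :func:`emit_reads`), apportioned by ``clone_abundance``; decoy-derived
    clones take a ``frac_bcr_like`` share on top of the TRB total.
    """
    rng = np.random.default_rng(config.seed + 1)
    trb_v = [v for v in reference.v_segments if chain_of(v.name) == "TRB"]
    decoy_v = [v for v in reference.v_segments if chain_of(v.name) != "TRB"]
    if not trb_v:
        raise ConfigError("reference has no TRBV segments")

    def draw_clone(clone_id: int, v: VSegment) -> Clonotype:
        j = reference.j_segments[int(rng.integers(0, len(reference.j_segments)))]
        v_part = v.sequence[v.cys_offset :]
        j_part = j.sequence[: j.phe_offset + 3]
        for _ in range(100):
            n_len = int(rng.integers(0, 22))
            n_len -= (len(v_part) + n_len + len(j_part)) % 3
            if n_len < 0:
                n_len += 3
            cdr3_nt = v_part + _random_dna(rng, n_len) + j_part
            aa = translate_nt(cdr3_nt)
            if "*" not in aa:
                return Clonotype(
                    clone_id=clone_id, v_gene=v.name, j_gene=j.name,
                    cdr3_nt=cdr3_nt, cdr3_aa=aa, productive=True,
                    chain=chain_of(v.name),
                )
        raise ConfigError("could not draw a productive CDR3 in 100 attempts")

    clones: list[Clonotype] = []
    seen_keys: set[tuple[str, str, str]] = set()
    cid = 1
    while len(clones) < config.n_clones:
        v = trb_v[int(rng.integers(0, len(trb_v)))]
        clone = draw_clone(cid, v)
        if clone.key in seen_keys:
            continue
        seen_keys.add(clone.key)
        clones.append(clone)
        cid += 1
    total = config.n_clones * config.spots_per_clone * config.umis_per_clone_spot
    budgets = _apportion(total, _abundance_weights(config, config.n_clones))
    for clone, b in zip(clones, budgets):
        clone.read_support = int(b)

    if config.frac_bcr_like > 0:
        if not decoy_v:
            raise ConfigError("frac_bcr_like > 0 but reference has no decoy segments")
        f = config.frac_bcr_like
        n_decoy_clones = max(1, int(round(f * config.n_clones)))
        decoy_total = max(n_decoy_clones, int(round(total * f / (1.0 - f))))
        decoy_budgets = _apportion(decoy_total, np.ones(n_decoy_clones))
        for k in range(n_decoy_clones):
            v = decoy_v[k % len(decoy_v)]
            clone = draw_clone(cid, v)
            if clone.key in seen_keys:
                continue
            seen_keys.add(clone.key)
            clone.read_support = int(decoy_budgets[k])
            clones.append(clone)
            cid += 1
    return clones


# ---------------------------------------------------------------------------
# read emission


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    if mask.any():
        cur = _BASE_INDEX[arr[mask]]
        new = (cur + rng.integers(1, 4, size=cur.size)) % 4
        arr[mask] = _BASES[new]
    return arr.tobytes().decode()


def emit_reads(
    reference: SegmentReference,
    repertoire: list[Clonotype],
    spot_map: SpotMap,
    config: SimConfig,
    out_dir: str | os.PathLike,
    primer_pool: PrimerPool | None = None,
) -> tuple[Path, Path, TruthSet]:
    """Emit paired FASTQ.gz files plus the truth set.

    Each clone's UMI budget (``read_support``) is placed on its spots; each
    molecule is replicated 1 + Poisson(pcr_duplication_mean - 1) times and
    per-base substitution errors are applied to both mates. Off-tissue
    contamination assigns a fraction of molecules to whitelist barcodes with
    in_tissue=0. Background reads carry random non-TCR read 2 sequence.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if primer_pool is None:
        primer_pool = make_primer_pool(reference, config.seed)
    rng = np.random.default_rng(config.seed + 2)

    in_tissue = spot_map.in_tissue_barcodes
    off_tissue = spot_map.off_tissue_barcodes
    if not in_tissue and config.frac_off_tissue < 1:
        raise ConfigError("spot map has no in-tissue spots")
    if config.frac_off_tissue > 0 and not off_tissue:
        raise ConfigError("frac_off_tissue > 0 but no off-tissue spots exist")

    primer_by_gene = {p.v_gene_name: p for p in primer_pool.primers}

    def amplicon(clone: Clonotype) -> str:
        v = reference.v(clone.v_gene)
        j = reference.j(clone.j_gene)
        p = primer_by_gene[clone.v_gene]
        start = v.sequence.find(p.primer_seq)
        if start < 0:
            raise ConfigError(f"primer for {clone.v_gene} not found in segment")
        seq = (
            p.read2_tail
            + v.sequence[start : v.cys_offset]
            + clone.cdr3_nt
            + j.sequence[j.phe_offset + 3 :]
            + reference.constant_prefix
        )
        return seq[: config.r2_len]

    # --- place molecules
    placements: list[tuple[int, str, str]] = []
    used_umis: dict[str, set[str]] = {}
    for clone in repertoire:
        if config.clone_placement is not None and clone.clone_id in config.clone_placement:
            spots = list(config.clone_placement[clone.clone_id])
        else:
            k = min(config.spots_per_clone, len(in_tissue)) if in_tissue else 0
            spots = list(rng.choice(in_tissue, size=k, replace=False)) if k else []
        for _ in range(clone.read_support):
            if config.frac_off_tissue > 0 and rng.random() < config.frac_off_tissue:
                barcode = off_tissue[int(rng.integers(0, len(off_tissue)))]
            elif spots:
                barcode = spots[int(rng.integers(0, len(spots)))]
            else:
                barcode = off_tissue[int(rng.integers(0, len(off_tissue)))]
            used = used_umis.setdefault(barcode, set())
            while True:
                umi = _random_dna(rng, 12)
                if umi not in used:
                    used.add(umi)
                    break
            placements.append((clone.clone_id, barcode, umi))

    amplicon_by_clone = {c.clone_id: amplicon(c) for c in repertoire}

    # --- expand molecules into reads (PCR duplication)
    molecules: list[tuple[int | None, str, str]] = list(placements)
    dup = 1 + rng.poisson(config.pcr_duplication_mean - 1.0, size=len(molecules))
    reads: list[tuple[int | None, str, str]] = []
    for mol, k in zip(molecules, dup):
        reads.extend([mol] * int(k))

    # --- background (non-TCR) reads
    f_bg = config.frac_background_reads
    n_bg = int(round(len(reads) * f_bg / (1.0 - f_bg))) if f_bg > 0 else 0
    for _ in range(n_bg):
        barcode = in_tissue[int(rng.integers(0, len(in_tissue)))]
        umi = _random_dna(rng, 12)
        reads.append((None, barcode, umi))

    order = rng.permutation(len(reads))
    r1_path = out_dir / "reads_R1.fastq.gz"
    r2_path = out_dir / "reads_R2.fastq.gz"
    assignments: dict[str, tuple[int | None, str, str]] = {}
    bg_len = min(config.r2_len, 150)
    with sio.open_text(r1_path, "wt") as f1, sio.open_text(r2_path, "wt") as f2:
        for serial, ix in enumerate(order):
            cid, barcode, umi = reads[int(ix)]
            rid = f"sim{serial:07d}"
            assignments[rid] = (cid, barcode, umi)
            r1 = barcode + umi + "T" * max(0, config.r1_len - 28)
            r2 = amplicon_by_clone[cid] if cid is not None else _random_dna(rng, bg_len)
            r1 = _apply_errors(r1, config.seq_error_rate, rng)
            r2 = _apply_errors(r2, config.seq_error_rate, rng)
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")

    truth = TruthSet(
        clones=list(repertoire), placements=placements, read_assignments=assignments
    )
    return r1_path, r2_path, truth


def write_truth(truth: TruthSet, out_dir: str | os.PathLike) -> None:
    """Write truth tables: clones TSV, placements TSV, per-read assignments TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.write_clones_table(truth.clones, out_dir / "truth_clones.tsv")
    with open(out_dir / "truth_placements.tsv", "w", newline="") as out:
        out.write("clone_id\tbarcode\tumi\n")
        for cid, barcode, umi in truth.placements:
            out.write(f"{cid}\t{barcode}\t{umi}\n")
    with open(out_dir / "truth_reads.tsv", "w", newline="") as out:
        out.write("read_id\tclone_id\tbarcode\tumi\n")
        for rid in sorted(truth.read_assignments):
            cid, barcode, umi = truth.read_assignments[rid]
            out.write(f"{rid}\t{-1 if cid is None else cid}\t{barcode}\t{umi}\n")


def simulate_dataset(
    config: SimConfig, out_dir: str | os.PathLike
) -> dict[str, object]:
    """Generate a complete dataset under ``out_dir``.

    Writes the segment reference (FASTA + anchors), primer manifest, tissue
    positions CSV (v1 dialect), paired FASTQ.gz and truth tables; returns the
    in-memory objects keyed by name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = make_reference(
        config.n_v, config.n_j, config.seed, n_decoys=config.n_decoys
    )
    pool = make_primer_pool(reference, config.seed)
    spot_map = make_spot_map(config.n_spots, config.frac_in_tissue, config.seed + 3)
    repertoire = make_repertoire(reference, config)
    r1, r2, truth = emit_reads(
        reference, repertoire, spot_map, config, out_dir, primer_pool=pool
    )
    sio.write_reference(
        reference, out_dir / "segments.fasta", out_dir / "segment_anchors.tsv"
    )
    sio.write_primer_pool(pool, out_dir / "primer_pool.tsv")
    sio.write_spot_map(spot_map, out_dir / "tissue_positions_list.csv", dialect="v1")
    write_truth(truth, out_dir)
    return {
        "reference": reference,
        "primer_pool": pool,
        "spot_map": spot_map,
        "repertoire": repertoire,
        "truth": truth,
        "r1": r1,
        "r2": r2,
    }
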