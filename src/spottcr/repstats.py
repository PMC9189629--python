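"""Repertoire statistics and QC for the spatial TCR assay.

Implements the per-sample summary columns (# reads, # TCR UMIs, # clones,
Shannon diversity, sequencing saturation, UMIs per spot) and two QC checks:
chain contamination (non-TRB clones, typically cross-primed B cell receptor
light chains) and the fraction of clone-supporting reads falling in spots
under tissue.
"""

from __future__ import annotations

import json
import math
import os
from collections.abc import Iterable, Sequence

from .types import (
    Clonotype,
    LinkLog,
    LinkedRecord,
    RepertoireStats,
    SpotCloneMatrix,
    SpotMap,
)


def shannon_diversity(umi_counts_per_clone: Sequence[int], base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over clone frequencies.

    Natural log by default (a monoclonal repertoire gives 0); pass ``base``
    to change the log base.
    """
    counts = list(umi_counts_per_clone)
    if not counts:
        raise ValueError("shannon_diversity: empty input")
    if any(c <= 0 for c in counts):
        raise ValueError("shannon_diversity: counts must be positive")
    total = sum(counts)
    h = 0.0
    for c in counts:
        p = c / total
        h -= p * math.log(p)
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def saturation(n_clone_reads: int, n_umis: int) -> float:
    """Sequencing saturation: 1 - unique UMIs / clone-supporting reads.

    ``n_clone_reads`` counts barcode-matched clone-supporting reads before
    deduplication; ``n_umis`` the deduplicated molecules.
    """
    if n_clone_reads < 1:
        raise ValueError("saturation: n_clone_reads must be >= 1")
    if not 0 <= n_umis <= n_clone_reads:
        raise ValueError("saturation: need 0 <= n_umis <= n_clone_reads")
    return 1.0 - n_umis / n_clone_reads


def umis_per_spot(n_umis: int, spot_map: SpotMap) -> float:
    """Mean TCR UMIs per in-tissue spot."""
    n_spots = len(spot_map.in_tissue_barcodes)
    if n_spots == 0:
        raise ValueError("umis_per_spot: spot map has no in-tissue spots")
    return n_umis / n_spots


def fraction_in_tissue(log: LinkLog) -> float:
    """Fraction of clone-supporting reads whose barcode maps under tissue."""
    total = log.in_tissue + log.off_tissue + log.unmatched_barcode
    if total == 0:
        raise ValueError("fraction_in_tissue: empty link log")
    return log.in_tissue / total


def chain_filter(
    clones: Iterable[Clonotype],
) -> tuple[list[Clonotype], list[Clonotype]]:
    """Partition clones into kept TRB clones and flagged non-TRB clones.

    Flagged clones (e.g. IGKV-assigned, from cross-primed BCR transcripts)
    should be excluded from the spatial matrix and reported with their V
    gene names.
    """
    kept: list[Clonotype] = []
    flagged: list[Clonotype] = []
    for c in clones:
        (kept if c.chain == "TRB" else flagged).append(c)
    return kept, flagged


def clone_overlap(
    spatial: Iterable[LinkedRecord],
    clones_by_id: dict[int, Clonotype],
    reference_clone_keys: set,
    granularity: str = "nt",
    weight: str = "umi",
) -> float:
    """Fraction of spatial UMIs whose clone is also in an external clone set.

    ``reference_clone_keys`` holds (v, j, cdr3_nt) triples when
    ``granularity="nt"`` or CDR3 amino-acid strings when ``granularity="aa"``.
    UMI-weighted by default (each deduplicated record counts once);
    ``weight="clone"`` counts each distinct clone once instead.
    """
    records = list(spatial)
    if not records:
        raise ValueError("clone_overlap: empty spatial record set")

    def key_of(cid: int):
        c = clones_by_id[cid]
        return c.key if granularity == "nt" else c.cdr3_aa

    if weight == "clone":
        cids = {r.clone_id for r in records}
        hit = sum(1 for cid in cids if key_of(cid) in reference_clone_keys)
        return hit / len(cids)
    hit = sum(1 for r in records if key_of(r.clone_id) in reference_clone_keys)
    return hit / len(records)


def summarize(
    n_reads: int,
    matrix: SpotCloneMatrix,
    link_log: LinkLog,
    clones: Iterable[Clonotype],
    spot_map: SpotMap,
    log_base: float | None = None,
) -> RepertoireStats:
    """Assemble the per-sample summary from pipeline outputs.

    UMI totals, clone counts and diversity are computed over in-tissue UMIs;
    saturation uses all barcode-matched clone-supporting reads (in- plus
    off-tissue) against all deduplicated UMIs.
    """
    col_sums = matrix.counts.sum(axis=0)
    umi_counts = [int(x) for x in col_sums if x > 0]
    n_in_tissue_umis = matrix.total_in_tissue_umis
    n_umis_all = n_in_tissue_umis + matrix.total_off_tissue_umis
    n_matched_reads = link_log.in_tissue + link_log.off_tissue
    shannon = shannon_diversity(umi_counts, base=log_base) if umi_counts else 0.0
    sat = saturation(n_matched_reads, n_umis_all) if n_matched_reads else None
    _, flagged = chain_filter(clones)
    frac = fraction_in_tissue(link_log) if link_log.total else 0.0
    return RepertoireStats(
        n_reads=n_reads,
        n_tcr_umis=n_in_tissue_umis,
        n_clones=len(umi_counts),
        shannon=shannon,
        saturation=sat,
        umis_per_spot=umis_per_spot(n_in_tissue_umis, spot_map),
        frac_reads_in_tissue=frac,
        n_non_trb_clones=len(flagged),
    )


_TSV_COLUMNS = [
    ("# reads", "n_reads"),
    ("#TCR UMIs", "n_tcr_umis"),
    ("# clones", "n_clones"),
    ("Diversity (Shannon)", "shannon"),
    ("TCR sequencing saturation", "saturation"),
    ("TCR UMIs/spot", "umis_per_spot"),
    ("Fraction reads in tissue", "frac_reads_in_tissue"),
    ("# non-TRB clones", "n_non_trb_clones"),
]


def write_stats(
    stats: RepertoireStats, path: str | os.PathLike, sample: str = "sample"
) -> None:
    """One-row TSV with the standard column names, plus a JSON sidecar."""
    path = os.fspath(path)

    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    with open(path, "w", newline="") as out:
        out.write("sample\t" + "\t".join(label for label, _ in _TSV_COLUMNS) + "\n")
        out.write(
            sample
            + "".join(f"\t{fmt(getattr(stats, attr))}" for _, attr in _TSV_COLUMNS)
            + "\n"
        )
    with open(path + ".json", "w") as out:
        json.dump(
            {attr: getattr(stats, attr) for _, attr in _TSV_COLUMNS},
            out,
            indent=2,
        )
        out.write("\n")
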