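"""FASTQ to filtered per-variant count table.

The amplicon design is a variant region between two constant flanks, read
from both ends so the pair always overlaps. Processing follows the assay's
QC rules: pairs are merged by overlap consensus (the higher-quality base
wins at conflicts), each flank must match the reference with at most 20% of
mismatches, any base below Phred 30 inside the variant region discards the
read, the region must exactly match a designed coding sequence, and at the
table level variants need at least 10 input reads in every biological
replicate (1000 pooled input reads when the variant is one nucleotide away
from WT, since such counts are inflated by sequencing errors on WT reads).
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .library import DesignedLibrary
from .simulate import revcomp


@dataclass
class QCReport:
    """Per-sample read accounting across the filter cascade."""

    reads_in: int = 0
    merge_failed: int = 0
    flank_failed: int = 0
    quality_failed: int = 0
    non_designed: int = 0
    counted: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class TrimSettings:
    flank5: str = ""
    flank3: str = ""
    max_mismatch_frac: float = 0.20
    min_overlap: int = 10
    min_phred: int = 30
    quality_mode: str = "min"  # 'min': every region base >= threshold; 'mean'
    match_level: str = "nt"  # exact match at 'nt' or translated 'aa' level


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def merge_pair(
    r1_seq: str,
    r1_qual: list[int],
    r2_seq: str,
    r2_qual: list[int],
    min_overlap: int = 10,
    max_overlap_mismatch_frac: float = 0.20,
) -> tuple[str, list[int]] | None:
    """Overlap-merge a read pair into one construct-oriented consensus.

    R2 is reverse-complemented, every admissible construct length is scored by
    mismatches in the implied overlap, and the best (fewest mismatches, ties
    to the longest overlap) is accepted if its mismatch fraction is within
    budget. Conflicting overlap bases take the higher-quality call.
    Returns None when no acceptable overlap exists.
    """
    r2 = revcomp(r2_seq)
    q2 = r2_qual[::-1]
    l1, l2 = len(r1_seq), len(r2)
    best = None  # (mismatches, -overlap, total_len)
    for total in range(max(l1, l2), l1 + l2 - min_overlap + 1):
        off = total - l2  # start of r2 within the construct
        ov = l1 - off
        if ov <= 0:
            continue
        mm = _mismatches(r1_seq[off:], r2[:ov])
        cand = (mm, -ov, total)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    mm, neg_ov, total = best
    ov = -neg_ov
    if mm > max_overlap_mismatch_frac * ov:
        return None
    off = total - l2
    seq = list(r1_seq[:off])
    qual = list(r1_qual[:off])
    for i in range(ov):
        b1, p1 = r1_seq[off + i], r1_qual[off + i]
        b2, p2 = r2[i], q2[i]
        if b1 == b2 or p1 >= p2:
            seq.append(b1)
            qual.append(max(p1, p2) if b1 == b2 else p1)
        else:
            seq.append(b2)
            qual.append(p2)
    seq += list(r2[ov:])
    qual += list(q2[ov:])
    return "".join(seq), qual


def trim_flanks(
    merged_seq: str,
    merged_qual: list[int],
    flank5: str,
    flank3: str,
    max_mismatch_frac: float = 0.20,
) -> tuple[str, list[int]] | None:
    """Strip the constant flanks, tolerating at most floor(frac*len) mismatches each.

    Matching is ungapped at the expected offsets (construct start and end);
    returns the in-between variant region with its qualities, or None.
    """
    n5, n3 = len(flank5), len(flank3)
    if len(merged_seq) < n5 + n3 + 1:
        return None
    if _mismatches(merged_seq[:n5], flank5) > math.floor(max_mismatch_frac * n5):
        return None
    if _mismatches(merged_seq[-n3:], flank3) > math.floor(max_mismatch_frac * n3):
        return None
    return merged_seq[n5: len(merged_seq) - n3], merged_qual[n5: len(merged_qual) - n3]


def merge_and_trim(
    r1_seq: str,
    r1_qual: list[int],
    r2_seq: str,
    r2_qual: list[int],
    settings: TrimSettings,
) -> tuple[str, list[int]] | str:
    """Full pair -> variant-region step; returns a reject reason code on failure."""
    merged = merge_pair(
        r1_seq, r1_qual, r2_seq, r2_qual,
        settings.min_overlap, settings.max_mismatch_frac,
    )
    if merged is None:
        return "unmergeable"
    region = trim_flanks(
        merged[0], merged[1], settings.flank5, settings.flank3,
        settings.max_mismatch_frac,
    )
    if region is None:
        return "flank_mismatch"
    return region


def quality_filter(region_qual: list[int], min_phred: int = 30, mode: str = "min") -> bool:
    """True = keep. 'min' discards the read if any region base is below the
    threshold (strict: exactly Phred 30 passes); 'mean' uses the region mean."""
    if not region_qual:
        return False
    if mode == "min":
        return min(region_qual) >= min_phred
    if mode == "mean":
        return sum(region_qual) / len(region_qual) >= min_phred
    raise ValueError(f"unknown quality mode {mode!r}")


def _translate(nt: str) -> str | None:
    from Bio.Seq import Seq

    if len(nt) % 3:
        return None
    aa = str(Seq(nt).translate())
    return None if "*" in aa else aa


def count_variants(
    regions, library: DesignedLibrary, match_level: str = "nt"
) -> tuple[dict[str, int], int]:
    """Tally exact matches of variant regions against the designed set.

    Returns (counts per variant_id, number of non-designed reads discarded).
    """
    if len(library) == 0:
        raise ValueError("empty designed library")
    if match_level == "nt":
        index = {v.nt_seq: v.variant_id for v in library}
        key = lambda r: r
    elif match_level == "aa":
        index = {v.canonical_seq: v.variant_id for v in library}
        key = _translate
    else:
        raise ValueError(f"unknown match level {match_level!r}")
    counts: dict[str, int] = {}
    non_designed = 0
    for region in regions:
        k = key(region)
        vid = index.get(k) if k is not None else None
        if vid is None:
            non_designed += 1
        else:
            counts[vid] = counts.get(vid, 0) + 1
    return counts, non_designed


def _open_read(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def quantify_sample(r1_path, r2_path, library: DesignedLibrary, settings: TrimSettings):
    """Process one paired FASTQ sample into per-variant counts plus QC tallies."""
    qc = QCReport()
    regions = []
    with _open_read(r1_path) as f1, _open_read(r2_path) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            qc.reads_in += 1
            out = merge_and_trim(
                str(rec1.seq),
                rec1.letter_annotations["phred_quality"],
                str(rec2.seq),
                rec2.letter_annotations["phred_quality"],
                settings,
            )
            if out == "unmergeable":
                qc.merge_failed += 1
                continue
            if out == "flank_mismatch":
                qc.flank_failed += 1
                continue
            region, rqual = out
            if not quality_filter(rqual, settings.min_phred, settings.quality_mode):
                qc.quality_failed += 1
                continue
            regions.append(region)
    counts, non_designed = count_variants(regions, library, settings.match_level)
    qc.non_designed = non_designed
    qc.counted = sum(counts.values())
    return counts, qc


def quantify_samples(
    sample_sheet: pd.DataFrame,
    library: DesignedLibrary,
    settings: TrimSettings,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Turn a sample sheet (sample, bio_rep, tech_rep, role, r1, r2) into a
    CountTable with one row per (variant, bio_rep, tech_rep)."""
    per_sample: dict[tuple[int, int], dict[str, dict[str, int]]] = {}
    qc_all: dict[str, dict[str, int]] = {}
    for _, row in sample_sheet.iterrows():
        counts, qc = quantify_sample(row["r1"], row["r2"], library, settings)
        qc_all[row["sample"]] = qc.as_dict()
        per_sample.setdefault((int(row["bio_rep"]), int(row["tech_rep"])), {})[
            row["role"]
        ] = counts
    ids = [v.variant_id for v in library]
    rows = []
    for (b, t), roles in sorted(per_sample.items()):
        cin = roles.get("input", {})
        cout = roles.get("output", {})
        for vid in ids:
            rows.append((vid, b, t, cin.get(vid, 0), cout.get(vid, 0)))
    table = pd.DataFrame(
        rows, columns=["variant_id", "bio_rep", "tech_rep", "count_in", "count_out"]
    )
    return table, qc_all


def apply_read_filters(
    counts: pd.DataFrame,
    library: DesignedLibrary,
    min_input_reads: int = 10,
    single_nt_min_input: int = 1000,
    single_nt_pooled: bool = True,
    wt_id: str = "WT",
) -> pd.DataFrame:
    """Drop low-coverage variants from the count table.

    A variant is dropped when its input count (technical replicates pooled)
    is below ``min_input_reads`` in any biological replicate, or when it is
    reachable from WT by a single nucleotide change and its input total
    (pooled across replicates by default) is below ``single_nt_min_input``.
    The WT reference is never dropped. Idempotent.
    """
    per_bio = (
        counts.groupby(["variant_id", "bio_rep"])["count_in"].sum().unstack(fill_value=0)
    )
    low = per_bio.min(axis=1) < min_input_reads
    drop = set(per_bio.index[low])

    single_nt = {
        v.variant_id for v in library if v.nt_min_changes == 1.0
    }
    if single_nt:
        if single_nt_pooled:
            totals = per_bio.sum(axis=1)
            drop |= {
                vid for vid in per_bio.index
                if vid in single_nt and totals[vid] < single_nt_min_input
            }
        else:
            drop |= set(
                per_bio.index[(per_bio < single_nt_min_input).any(axis=1)]
            ) & single_nt
    drop.discard(wt_id)
    return counts[~counts["variant_id"].isin(drop)].reset_index(drop=True)


def write_qc_report(qc: dict, path) -> None:
    Path(path).write_text(json.dumps(qc, indent=2, sort_keys=True))
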