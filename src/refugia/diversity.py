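"""Per-individual heterozygosity and runs of homozygosity (ROH).

Heterozygosity is the fraction of an individual's called genotypes at
variant sites that are heterozygous — the number of heterozygous sites
divided by the number of homozygous plus heterozygous sites. An optional
``callable_bp`` divisor supports genome-length-normalised rates on real
data.

ROH detection follows the PLINK ``--homozyg`` windowed algorithm: sliding
windows of consecutive SNPs pass when they contain at most
``window_het_max`` heterozygous and ``window_miss_max`` missing calls; a
SNP's hit fraction is the proportion of windows covering it that pass, and
maximal runs of SNPs with hit fraction >= ``hit_frac`` (trimmed to
homozygous called end points, so an isolated heterozygote inside a long
homozygous tract does not split it) are reported when they satisfy the SNP
count and physical length thresholds. The default minimum length is
lowered to 5 kb so the 5 kb - 1 Mb tract-age band is reachable; a tract of
length L cM dates the underlying inbreeding loop to roughly
g = 100 / (2 L) generations ago.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int  # 0-based half-open
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def heterozygosity(gm: GenotypeMatrix, callable_bp: float | None = None) -> np.ndarray:
    """Per-individual heterozygosity; NaN (logged) for individuals with no calls.

    With ``callable_bp`` the denominator is that genome length instead of
    the called-genotype count.
    """
    d = gm.dosages
    het = (d == 1).sum(axis=1).astype(float)
    called = (d != MISSING).sum(axis=1).astype(float)
    if callable_bp is not None:
        return het / float(callable_bp)
    none_called = called == 0
    if none_called.any():
        logger.warning("heterozygosity: %d individuals with zero called sites -> NaN",
                       int(none_called.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(none_called, np.nan, het / np.maximum(called, 1))


def detect_roh(
    dosages: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    sample_id: str = "",
    window_snps: int = 50,
    window_het_max: int = 1,
    window_miss_max: int = 5,
    hit_frac: float = 0.05,
    min_snps: int = 25,
    min_length_bp: int = 5000,
) -> list[ROHSegment]:
    """Windowed ROH calls for one individual; positions are 1-based per chromosome.

    Segment bounds are the first/last SNP positions of the run, end
    exclusive at last + 1, reported 0-based half-open.
    """
    dosages = np.asarray(dosages)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    segments: list[ROHSegment] = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        d = dosages[sel]
        pos = positions[sel]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on {chrom}")
        n = len(d)
        if n < window_snps:
            logger.info("detect_roh: %s has %d < %d SNPs, skipped", chrom, n, window_snps)
            continue
        eligible = _eligible_snps(d, window_snps, window_het_max, window_miss_max, hit_frac)
        hom = (d == 0) | (d == 2)
        for lo, hi in _runs(eligible):
            idx = np.arange(lo, hi)
            hom_idx = idx[hom[idx]]
            if len(hom_idx) == 0:
                continue
            a, b = hom_idx[0], hom_idx[-1]
            n_snps = b - a + 1
            start = int(pos[a]) - 1  # to 0-based
            end = int(pos[b])  # exclusive at last position + 1
            if n_snps >= min_snps and end - start >= min_length_bp:
                segments.append(ROHSegment(sample_id, str(chrom), start, end, int(n_snps)))
    return segments


def _eligible_snps(d, W, het_max, miss_max, hit_frac):
    n = len(d)
    het = (d == 1).astype(np.int64)
    miss = (d == MISSING).astype(np.int64)
    chet = np.concatenate(([0], np.cumsum(het)))
    cmiss = np.concatenate(([0], np.cumsum(miss)))
    n_win = n - W + 1
    starts = np.arange(n_win)
    ok = ((chet[starts + W] - chet[starts]) <= het_max) & \
         ((cmiss[starts + W] - cmiss[starts]) <= miss_max)
    cok = np.concatenate(([0], np.cumsum(ok.astype(np.int64))))
    i = np.arange(n)
    w_lo = np.maximum(0, i - W + 1)
    w_hi = np.minimum(i, n_win - 1)
    covering = (w_hi - w_lo + 1).astype(float)
    hits = cok[w_hi + 1] - cok[w_lo]
    return hits / covering >= hit_frac


def _runs(mask):
    """Yield (start, stop) of maximal True runs, stop exclusive."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.where(diff == 1)[0]
    stops = np.where(diff == -1)[0]
    return zip(starts, stops)


def roh_table(gm: GenotypeMatrix, vt: pd.DataFrame, **params) -> pd.DataFrame:
    """ROH segments for every individual, as a DataFrame."""
    chroms = vt["chrom"].to_numpy()
    positions = vt["pos"].to_numpy()
    rows = []
    for i, sid in enumerate(gm.sample_ids):
        for seg in detect_roh(gm.dosages[i], chroms, positions, sample_id=sid, **params):
            rows.append((seg.sample_id, seg.chrom, seg.start_bp, seg.end_bp,
                         seg.n_snps, seg.length_bp))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def roh_summary(segments: pd.DataFrame, lo_bp: float = 5000, hi_bp: float = 1e6,
                sample_ids=None) -> pd.DataFrame:
    """Per-individual count and total length of ROH with lo_bp <= length < hi_bp.

    ``sample_ids`` forces rows (with zeros) for individuals without segments.
    """
    if len(segments) == 0:
        band = pd.DataFrame(columns=SEGMENT_COLUMNS)
    else:
        band = segments[(segments["length_bp"] >= lo_bp) & (segments["length_bp"] < hi_bp)]
    agg = band.groupby("sample_id")["length_bp"].agg(roh_count="count", roh_total_bp="sum")
    if sample_ids is not None:
        agg = agg.reindex(sample_ids, fill_value=0)
    agg.index.name = "sample_id"
    return agg.reset_index()


def roh_age(length_bp: float, cM_per_Mb: float = 1.0) -> float:
    """Generations since the inbreeding loop: g = 100 / (2 * length in cM)."""
    if length_bp <= 0:
        raise ValueError("ROH length must be positive")
    length_cM = length_bp * cM_per_Mb / 1e6
    return 100.0 / (2.0 * length_cM)


def segments_to_bed(segments: pd.DataFrame, path):
    """Write segments as BED (0-based half-open) with a sample_id column."""
    cols = segments[["chrom", "start_bp", "end_bp", "sample_id"]]
    cols.to_csv(path, sep="\t", header=False, index=False)
    return path
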