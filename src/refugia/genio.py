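"""Genotype/variant/sample data model, VCF and CSV IO, and SNP-set filters.

Core containers
---------------
``GenotypeMatrix``
    individuals x sites matrix of diploid alternate-allele dosages
    (int8; 0, 1, 2, or ``MISSING`` = -1), with a parallel ``sample_ids`` list.
``VariantTable``
    a pandas DataFrame with columns ``chrom, pos, ref, alt, ancestral,
    vclass`` — one row per biallelic SNP, sorted and unique on (chrom, pos).
    ``pos`` is 1-based (VCF convention); internal intervals elsewhere in the
    package are 0-based half-open, conversions happen only in readers/writers.
    ``ancestral`` is a base or ``"."`` when unknown; ``vclass`` is one of
    ``SYN``, ``NONSYN``, ``LOF``, ``OTHER``.
``SampleTable``
    a pandas DataFrame with columns ``sample_id, site_id, lon, lat``.

Filters implement the SNP-selection steps used upstream of the
isolation-by-distance test: a strict minor-allele-frequency cut and
PLINK-style ``indep-pairwise`` LD pruning on genotype dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ancestral", "vclass"]
SAMPLE_COLUMNS = ["sample_id", "site_id", "lon", "lat"]
CLASSES = ("SYN", "NONSYN", "LOF", "OTHER")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix: rows are individuals, columns are sites."""

    dosages: np.ndarray  # (n_individuals, n_sites) int8; -1 = missing
    sample_ids: list

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length must match number of rows")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def take_sites(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, index], list(self.sample_ids))

    def take_individuals(self, index) -> "GenotypeMatrix":
        ids = [self.sample_ids[i] for i in np.atleast_1d(index)]
        return GenotypeMatrix(self.dosages[np.atleast_1d(index), :], ids)


def validate_variant_table(vt: pd.DataFrame) -> pd.DataFrame:
    missing_cols = set(VARIANT_COLUMNS) - set(vt.columns)
    if missing_cols:
        raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
    if vt.duplicated(["chrom", "pos"]).any():
        raise ValueError("variant table has duplicate (chrom, pos)")
    if not vt["vclass"].isin(CLASSES).all():
        raise ValueError(f"vclass must be one of {CLASSES}")
    return vt


def validate_sample_table(st: pd.DataFrame, gm: GenotypeMatrix | None = None) -> pd.DataFrame:
    missing_cols = set(SAMPLE_COLUMNS) - set(st.columns)
    if missing_cols:
        raise ValueError(f"sample table missing columns: {sorted(missing_cols)}")
    if st["sample_id"].duplicated().any():
        raise ValueError("sample_ids must be unique")
    if (st["lon"].abs() > 180).any() or (st["lat"].abs() > 90).any():
        raise ValueError("lon/lat out of range")
    if gm is not None:
        absent = set(gm.sample_ids) - set(st["sample_id"])
        if absent:
            raise ValueError(f"individuals missing from sample table: {sorted(absent)[:5]} ...")
    return st


# ---------------------------------------------------------------------------
# VCF / CSV IO
# ---------------------------------------------------------------------------

_GT_TYPE_TO_DOSAGE = {0: 0, 1: 1, 2: MISSING, 3: 2}  # cyvcf2 gt_types codes


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a diploid VCF into a (GenotypeMatrix, VariantTable) pair.

    Multi-allelic and non-SNP records are skipped (count logged). Missing
    genotypes become ``MISSING``. INFO tags ``AA`` (ancestral allele) and
    ``CLASS`` (SYN/NONSYN/LOF) are honoured when present; otherwise the
    ancestral state is unknown (``"."``) and the class is ``OTHER``.
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    sample_ids = list(vcf.samples)
    rows = []
    dosage_cols = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = np.array([_GT_TYPE_TO_DOSAGE[t] for t in var.gt_types], dtype=np.int8)
        aa = var.INFO.get("AA") or "."
        if aa not in (var.REF, var.ALT[0]):
            aa = "."
        vclass = var.INFO.get("CLASS") or "OTHER"
        if vclass not in CLASSES:
            vclass = "OTHER"
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], aa, vclass))
        dosage_cols.append(gt)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    vt = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    gm = GenotypeMatrix(np.column_stack(dosage_cols), sample_ids)
    return gm, validate_variant_table(vt)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, vt: pd.DataFrame, path) -> Path:
    """Write a minimal VCF 4.2 with GT plus INFO AA/CLASS tags."""
    validate_variant_table(vt)
    if len(vt) != gm.n_sites:
        raise ValueError("variant table and genotype matrix disagree on site count")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Functional class: SYN|NONSYN|LOF|OTHER">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in vt["chrom"].unique():
            span = int(vt.loc[vt["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={span + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in gm.sample_ids) + "\n")
        chroms = vt["chrom"].to_numpy()
        poss = vt["pos"].to_numpy()
        refs = vt["ref"].to_numpy()
        alts = vt["alt"].to_numpy()
        aas = vt["ancestral"].to_numpy()
        classes = vt["vclass"].to_numpy()
        for j in range(gm.n_sites):
            info = []
            if aas[j] != ".":
                info.append(f"AA={aas[j]}")
            info.append(f"CLASS={classes[j]}")
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t"
                f"{';'.join(info)}\tGT\t{gts}\n"
            )
    return path


def read_samples(path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path))


def write_samples(st: pd.DataFrame, path) -> Path:
    validate_sample_table(st)
    path = Path(path)
    st.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Site frequencies and filters
# ---------------------------------------------------------------------------

def alt_allele_freqs(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site alternate-allele frequency over non-missing alleles (NaN if none called)."""
    d = gm.dosages
    called = d != MISSING
    n_alleles = 2.0 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def filter_maf(gm: GenotypeMatrix, vt: pd.DataFrame, threshold: float = 0.10):
    """Keep sites whose minor-allele frequency is strictly greater than *threshold*."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5)")
    p = alt_allele_freqs(gm)
    maf = np.minimum(p, 1.0 - p)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) > threshold)[0]
    return gm.take_sites(keep), vt.iloc[keep].reset_index(drop=True)


def _dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, missing pairwise-deleted."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    xv -= xv.mean()
    yv -= yv.mean()
    denom = np.sqrt((xv @ xv) * (yv @ yv))
    if denom == 0:
        return 0.0
    return float((xv @ yv) / denom) ** 2


def ld_prune(
    gm: GenotypeMatrix,
    vt: pd.DataFrame,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.2,
):
    """PLINK-style ``indep-pairwise`` pruning on genotype-dosage correlation.

    Windows of ``window_snps`` consecutive SNPs advance by ``step_snps`` along
    each chromosome (window positions indexed on the original site order, so
    SNPs removed earlier still anchor the schedule). Within a window, while
    any surviving pair exceeds ``r2_max``, the pair member with the lower
    non-missing count is removed (ties: the later position goes).
    """
    d = gm.dosages
    n_called = (d != MISSING).sum(axis=0)
    keep = np.ones(gm.n_sites, dtype=bool)
    has_missing = bool((d == MISSING).any())
    for chrom in vt["chrom"].unique():
        idx = np.where((vt["chrom"] == chrom).to_numpy())[0]
        n = len(idx)
        if n == 0:
            continue
        starts = range(0, max(n - window_snps, 0) + 1, step_snps) if n >= window_snps else [0]
        for s in starts:
            win = idx[s : s + window_snps]
            _prune_window(d, n_called, keep, win, r2_max, has_missing)
    kept = np.where(keep)[0]
    return gm.take_sites(kept), vt.iloc[kept].reset_index(drop=True)


def _prune_window(d, n_called, keep, win, r2_max, has_missing) -> None:
    while True:
        live = win[keep[win]]
        m = len(live)
        if m < 2:
            return
        if has_missing:
            r2 = np.empty((m, m))
            for a in range(m):
                r2[a, a] = 1.0
                for b in range(a + 1, m):
                    r2[a, b] = r2[b, a] = _dosage_r2(d[:, live[a]], d[:, live[b]])
        else:
            x = d[:, live].astype(float)
            with np.errstate(invalid="ignore"):
                r2 = np.corrcoef(x, rowvar=False) ** 2
            r2 = np.nan_to_num(r2, nan=0.0)
        iu = np.triu_indices(m, k=1)
        offending = r2[iu] > r2_max
        if not offending.any():
            return
        first = int(np.argmax(offending))
        a, b = int(iu[0][first]), int(iu[1][first])
        sa, sb = live[a], live[b]
        # drop the lower-call-count member; ties drop the later position
        drop = sb if n_called[sb] <= n_called[sa] else sa
        keep[drop] = False


def derived_freqs(gm: GenotypeMatrix, vt: pd.DataFrame) -> np.ndarray:
    """Per-site derived-allele frequency polarized on the ancestral annotation.

    Ancestral = ref: derived frequency is the alt frequency; ancestral = alt:
    its complement; unknown ancestral state: NaN (the site is then excluded
    from load metrics downstream).
    """
    p_alt = alt_allele_freqs(gm)
    anc = vt["ancestral"].to_numpy()
    ref = vt["ref"].to_numpy()
    alt = vt["alt"].to_numpy()
    out = np.full(len(vt), np.nan)
    is_ref = anc == ref
    is_alt = anc == alt
    out[is_ref] = p_alt[is_ref]
    out[is_alt] = 1.0 - p_alt[is_alt]
    return out
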