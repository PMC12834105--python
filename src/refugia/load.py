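"""Genetic-load statistics from functional classes and derived-allele polarization.

Three load proxies per individual:

* ``ratio_ns`` = Pn / (Pn + Ps), where Pn and Ps count the nonsynonymous and
  synonymous polymorphic sites at which the individual carries at least one
  derived allele (carrier sites);
* ``freq_ratio`` = (Pn * fn_bar) / (Ps * fs_bar), where fn_bar and fs_bar
  are the mean population derived-allele frequencies over the individual's
  carried nonsynonymous and synonymous sites — a site-frequency-spectrum
  weighted version of the first metric;
* ``lof_dosage`` — the summed derived-allele dosage at loss-of-function
  sites (allele count, not carrier-site count).

Sites with unknown ancestral state are excluded throughout. By default the
nonsynonymous class is missense only (``NONSYN``); ``include_lof_in_nonsyn``
folds LOF sites into Pn for sensitivity analyses. Undefined ratios (empty
denominators) are NaN and are dropped by downstream interpolation and
correlation steps. ``population_load`` is the per-sampling-site companion:
Pn/Ps count sites segregating within the group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

LOAD_COLUMNS = ["sample_id", "Pn", "Ps", "fn_bar", "fs_bar", "ratio_ns",
                "freq_ratio", "lof_dosage"]


def _derived_dosages(gm: GenotypeMatrix, vt: pd.DataFrame) -> np.ndarray:
    """Per-individual derived-allele dosage; NaN where missing or unpolarized."""
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    anc = vt["ancestral"].to_numpy()
    flip = anc == vt["alt"].to_numpy()
    unknown = ~flip & (anc != vt["ref"].to_numpy())
    d[:, flip] = 2.0 - d[:, flip]
    d[:, unknown] = np.nan
    return d


def compute_load(gm: GenotypeMatrix, vt: pd.DataFrame, dfreq: np.ndarray,
                 include_lof_in_nonsyn: bool = False) -> pd.DataFrame:
    """Per-individual load metrics; ``dfreq`` is the per-site population
    derived-allele frequency (NaN = unpolarized, site skipped)."""
    dfreq = np.asarray(dfreq, dtype=float)
    usable = ~np.isnan(dfreq)
    vclass = vt["vclass"].to_numpy()
    is_syn = usable & (vclass == "SYN")
    is_lof = usable & (vclass == "LOF")
    is_non = usable & ((vclass == "NONSYN") | (include_lof_in_nonsyn & is_lof))
    if not (is_syn | is_non | is_lof).any():
        raise ValueError("no classified sites with known ancestral state")

    dd = _derived_dosages(gm, vt)
    carrier = dd >= 1  # NaN compares False

    rows = []
    for i, sid in enumerate(gm.sample_ids):
        car_n = carrier[i] & is_non
        car_s = carrier[i] & is_syn
        Pn = int(car_n.sum())
        Ps = int(car_s.sum())
        fn_bar = float(dfreq[car_n].mean()) if Pn else np.nan
        fs_bar = float(dfreq[car_s].mean()) if Ps else np.nan
        ratio_ns = Pn / (Pn + Ps) if (Pn + Ps) > 0 else np.nan
        freq_ratio = (Pn * fn_bar) / (Ps * fs_bar) if Ps > 0 and fs_bar and not np.isnan(fs_bar) else np.nan
        lof = dd[i, is_lof]
        lof_dosage = float(np.nansum(lof))
        rows.append((sid, Pn, Ps, fn_bar, fs_bar, ratio_ns, freq_ratio, lof_dosage))
    return pd.DataFrame(rows, columns=LOAD_COLUMNS)


def population_load(gm: GenotypeMatrix, vt: pd.DataFrame, dfreq: np.ndarray,
                    grouping: pd.Series | dict) -> pd.DataFrame:
    """Per-group load metrics: Pn/Ps count sites *segregating* within the group,
    fn_bar/fs_bar average the within-group derived frequency over those sites.

    ``grouping`` maps sample_id -> site_id. Groups of size < 2 are an error.
    """
    grouping = pd.Series(grouping)
    dfreq = np.asarray(dfreq, dtype=float)
    usable = ~np.isnan(dfreq)
    vclass = vt["vclass"].to_numpy()
    is_syn = usable & (vclass == "SYN")
    is_non = usable & (vclass == "NONSYN")
    is_lof = usable & (vclass == "LOF")
    dd = _derived_dosages(gm, vt)
    sid_index = pd.Index(gm.sample_ids)

    rows = []
    for group, members in grouping.groupby(grouping):
        ids = list(members.index)
        if len(ids) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 individuals")
        rows_idx = sid_index.get_indexer(ids)
        if (rows_idx < 0).any():
            raise ValueError(f"group {group!r} names individuals absent from the genotype matrix")
        sub = dd[rows_idx]
        with np.errstate(invalid="ignore"):
            gfreq = np.nanmean(sub, axis=0) / 2.0
        segregating = (gfreq > 0) & (gfreq < 1)
        seg_n = segregating & is_non
        seg_s = segregating & is_syn
        Pn = int(seg_n.sum())
        Ps = int(seg_s.sum())
        fn_bar = float(gfreq[seg_n].mean()) if Pn else np.nan
        fs_bar = float(gfreq[seg_s].mean()) if Ps else np.nan
        ratio_ns = Pn / (Pn + Ps) if (Pn + Ps) > 0 else np.nan
        freq_ratio = (Pn * fn_bar) / (Ps * fs_bar) if Ps > 0 and fs_bar and not np.isnan(fs_bar) else np.nan
        lof_dosage = float(np.nansum(sub[:, is_lof]))
        rows.append((group, Pn, Ps, fn_bar, fs_bar, ratio_ns, freq_ratio, lof_dosage))
    return pd.DataFrame(rows, columns=["site_id"] + LOAD_COLUMNS[1:])
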