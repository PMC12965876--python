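"""Per-site soil biodiversity response metrics.

Count tables are pandas DataFrames with sites as rows and taxa as columns
(`read_count_table` auto-detects the transposed orientation).  All diversity
quantities use natural logarithms (nats).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "srs_normalize",
    "richness_shannon",
    "multidiversity",
    "functional_abundance",
    "pmog",
    "read_count_table",
]


def srs_normalize(table: pd.DataFrame, c_min: int, seed: int | None = None) -> pd.DataFrame:
    """Scaling with ranked subsampling (SRS) to a common depth ``c_min``.

    Each site's counts are scaled by ``c_min / total``; integer parts are
    kept and the remaining deficit is distributed one unit each to taxa
    ranked by descending fractional part.  Ties among equal fractional parts
    are broken by descending original abundance, then stable input order
    (pass ``seed`` for randomized tie-breaking instead).  Every normalized
    site total equals exactly ``c_min``; sites with fewer than ``c_min``
    reads are dropped with a warning.
    """
    if c_min <= 0:
        raise ValueError("c_min must be a positive integer")
    totals = table.sum(axis=1)
    low = totals[totals < c_min]
    if len(low) == len(table):
        raise ValueError(f"all {len(table)} sites have library size < c_min={c_min}")
    if len(low):
        warnings.warn(
            f"dropping {len(low)} site(s) with library size < c_min={c_min}: "
            f"{', '.join(map(str, low.index[:5]))}{'...' if len(low) > 5 else ''}"
        )
        table = table.drop(index=low.index)
        totals = totals.drop(index=low.index)

    rng = np.random.default_rng(seed) if seed is not None else None
    out = np.empty(table.shape, dtype=np.int64)
    counts = table.to_numpy(dtype=np.float64)
    for i in range(len(table)):
        row = counts[i]
        scaled = row * (c_min / row.sum())
        floors = np.floor(scaled)
        deficit = int(round(c_min - floors.sum()))
        if deficit:
            frac = scaled - floors
            if rng is None:
                jitter = -np.arange(len(row), dtype=np.float64)  # stable input order
            else:
                jitter = rng.random(len(row))
            order = np.lexsort((jitter, row, frac))[::-1]
            floors[order[:deficit]] += 1
        out[i] = floors
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def richness_shannon(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site richness (taxa with count > 0) and Shannon diversity in nats.

    ``shannon = -sum p_i ln p_i`` over positive counts.  All-zero sites get
    richness 0 and Shannon 0 with a warning.
    """
    counts = table.to_numpy(dtype=np.float64)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} all-zero site(s); richness and Shannon set to 0")
    richness = (counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[:, None]
        terms = np.where(counts > 0, -p * np.log(p), 0.0)
    shannon = np.where(totals > 0, np.nansum(terms, axis=1), 0.0)
    return pd.DataFrame({"richness": richness, "shannon": shannon}, index=table.index)


def multidiversity(richness_by_group: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Composite diversity: mean of per-group min-max standardized richness.

    ``z_g = (richness_g - min_g) / (max_g - min_g)`` across the analyzed
    sites; the index is the unweighted mean over groups (1/6 weighting for
    the default six organism groups).  A group with zero range contributes a
    constant 0.5 so the equal weighting stays meaningful.

    Returns the index series and the z-score table.
    """
    if len(richness_by_group) < 2:
        raise ValueError("multidiversity needs >= 2 sites (min-max scaling requires a range)")
    z = pd.DataFrame(index=richness_by_group.index, columns=richness_by_group.columns, dtype=float)
    for col in richness_by_group.columns:
        x = richness_by_group[col].astype(float)
        rng_ = x.max() - x.min()
        if rng_ == 0:
            warnings.warn(f"group {col!r} has zero richness range; z set to constant 0.5")
            z[col] = 0.5
        else:
            z[col] = (x - x.min()) / rng_
    index = z.mean(axis=1)
    index.name = "multidiversity"
    return index, z


def functional_abundance(
    table: pd.DataFrame, assignment: Mapping[str, str]
) -> pd.DataFrame:
    """Relative abundance (%) of each functional group per site.

    The percentage is the summed reads of taxa assigned to the group divided
    by the site's total reads (assigned or not) times 100.  Sites with zero
    total reads are reported as missing.
    """
    totals = table.sum(axis=1).astype(float)
    groups = sorted(set(assignment.values()))
    out = pd.DataFrame(index=table.index, columns=groups, dtype=float)
    for g in groups:
        taxa = [t for t, lab in assignment.items() if lab == g and t in table.columns]
        out[g] = table[taxa].sum(axis=1) / totals * 100.0 if taxa else 0.0
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} site(s) with zero reads; abundance undefined")
        out.loc[totals == 0, :] = np.nan
    return out


def pmog(og_count, functional_reads):
    """Functional gene-group diversity: orthologous groups per million
    functionally annotated reads, ``og_count / functional_reads * 1e6``.

    Accepts scalars or aligned arrays; zero read totals yield missing values
    with a warning.
    """
    og = np.asarray(og_count, dtype=float)
    reads = np.asarray(functional_reads, dtype=float)
    if np.any(og < 0):
        raise ValueError("og_count must be non-negative")
    if np.any(reads == 0):
        warnings.warn("functional_reads contains zeros; pmOG undefined there")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(reads > 0, og / reads * 1e6, np.nan)
    return float(out) if out.ndim == 0 else out


def read_count_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a count table TSV; the key column must be named ``site_id``.

    If the header carries no ``site_id`` column the table is assumed to be
    taxa x sites with site ids in the header and is transposed.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.name != "site_id":
        if "site_id" == str(df.columns.name) or df.index.name in (None, "taxon", "taxon_id"):
            df = df.T
            df.index.name = "site_id"
        else:
            raise ValueError("count table must carry a 'site_id' key column or header")
    return df
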