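"""Predictor-table preparation.

LOQ censoring of residue concentrations, near-zero-variance screening of
pesticide columns, environmental transforms (negative-exponential pH,
log conductivity), occurrence aggregation by pesticide type, and NOEC-based
ecotoxicological risk quotients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PesticideCatalog",
    "NZVReport",
    "RiskTable",
    "censor_loq",
    "near_zero_variance_filter",
    "transform_environment",
    "aggregate_occurrence",
    "risk_quotients",
]

log = logging.getLogger(__name__)

PESTICIDE_TYPES = ("fungicide", "herbicide", "insecticide")

CATALOG_COLUMNS = ("pesticide", "type", "chemical_group", "mode_of_action", "noec_min", "loq")


@dataclass
class PesticideCatalog:
    """Per-pesticide metadata: type, chemical group, mode of action,
    minimum no-observed-effect concentration (NOEC_min, mg/kg, may be
    missing) and limit of quantification (LOQ, mg/kg)."""

    table: pd.DataFrame  # indexed by pesticide name

    def __post_init__(self) -> None:
        missing = set(CATALOG_COLUMNS[1:]) - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        bad_type = set(self.table["type"].dropna()) - set(PESTICIDE_TYPES)
        if bad_type:
            raise ValueError(f"unknown pesticide type label(s): {sorted(bad_type)}")
        noec = self.table["noec_min"].dropna()
        if (noec <= 0).any():
            raise ValueError("noec_min must be > 0 where present")
        if (self.table["loq"] <= 0).any():
            raise ValueError("loq must be > 0")

    @classmethod
    def read_tsv(cls, path) -> "PesticideCatalog":
        return cls(pd.read_csv(path, sep="\t", index_col="pesticide"))

    @classmethod
    def default_for(cls, pesticides, loq: float = 0.001, rng=None) -> "PesticideCatalog":
        """Synthetic catalog covering the given pesticide names (round-robin
        types, lognormal NOEC_min around 0.025 mg/kg)."""
        rng = np.random.default_rng(rng)
        n = len(pesticides)
        types = [PESTICIDE_TYPES[i % 3] for i in range(n)]
        noec = np.round(np.exp(rng.normal(np.log(0.025), 0.8, size=n)), 6)
        table = pd.DataFrame(
            {
                "type": types,
                "chemical_group": [f"group_{i % 5 + 1}" for i in range(n)],
                "mode_of_action": [f"moa_{i % 7 + 1}" for i in range(n)],
                "noec_min": noec,
                "loq": loq,
            },
            index=pd.Index(pesticides, name="pesticide"),
        )
        return cls(table)


def censor_loq(raw: pd.DataFrame, catalog: PesticideCatalog) -> pd.DataFrame:
    """Set concentrations strictly below their pesticide's LOQ to exactly 0.

    Values equal to the LOQ are retained ("below LOQ" is strict).  Detection
    downstream is defined as value > 0.
    """
    if (raw.to_numpy() < 0).any():
        bad = raw.columns[(raw < 0).any()].tolist()
        raise ValueError(f"negative concentrations in columns: {bad}")
    loq = catalog.table["loq"].reindex(raw.columns)
    if loq.isna().any():
        raise ValueError(f"catalog lacks LOQ for: {loq.index[loq.isna()].tolist()}")
    out = raw.copy()
    mask = out.lt(loq, axis=1)
    out[mask] = 0.0
    return out


@dataclass
class NZVReport:
    """Outcome of near-zero-variance screening."""

    kept: list[str]
    removed: dict[str, str] = field(default_factory=dict)  # column -> reason

    def to_frame(self) -> pd.DataFrame:
        rows = [{"pesticide": c, "kept": True, "reason": ""} for c in self.kept]
        rows += [{"pesticide": c, "kept": False, "reason": r} for c, r in self.removed.items()]
        return pd.DataFrame(rows)


def near_zero_variance_filter(
    conc: pd.DataFrame, freq_ratio_max: float = 19.0, unique_pct_min: float = 5.0
) -> NZVReport:
    """Drop pesticide columns with (near-)zero variance across sites.

    A column is removed when the frequency ratio of its most common value to
    its second most common value exceeds ``freq_ratio_max`` (default 95/5 =
    19, strict inequality) AND the percentage of distinct values out of the
    number of sites is below ``unique_pct_min`` (default 5%) — the two
    conditions jointly define a near-zero-variance predictor, matching the
    behaviour of the standard screening implementation this mirrors.
    Constant columns are always removed.
    """
    if conc.empty:
        raise ValueError("empty concentration matrix")
    n = len(conc)
    if n < 2:
        raise ValueError("near-zero-variance screening needs >= 2 sites")
    kept, removed = [], {}
    for col in conc.columns:
        counts = conc[col].value_counts()
        n_distinct = len(counts)
        if n_distinct == 1:
            removed[col] = "zero variance (constant column)"
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        distinct_pct = n_distinct / n * 100.0
        if ratio > freq_ratio_max and distinct_pct < unique_pct_min:
            removed[col] = (
                f"frequency ratio {ratio:.3g} > {freq_ratio_max:g}; "
                f"distinct values {distinct_pct:.3g}% < {unique_pct_min:g}%"
            )
        else:
            kept.append(col)
    for col, reason in removed.items():
        log.info("near-zero-variance filter removed %s: %s", col, reason)
    return NZVReport(kept=kept, removed=removed)


def transform_environment(
    env: pd.DataFrame, ph_col: str = "soil_pH", ec_col: str = "soil_EC"
) -> pd.DataFrame:
    """Apply the standard environmental transforms.

    pH is negatively exponentially transformed (``exp(-pH)``) and electrical
    conductivity is natural-log transformed; every other column passes
    through untouched.
    """
    out = env.copy()
    if ph_col in out.columns:
        out[ph_col] = np.exp(-out[ph_col].astype(float))
        log.info("transformed %s -> exp(-%s)", ph_col, ph_col)
    if ec_col in out.columns:
        ec = out[ec_col].astype(float)
        if (ec <= 0).any():
            bad = out.index[ec <= 0].tolist()
            raise ValueError(f"non-positive conductivity at sites: {bad[:10]}")
        out[ec_col] = np.log(ec)
        log.info("transformed %s -> ln(%s)", ec_col, ec_col)
    return out


def aggregate_occurrence(conc: pd.DataFrame, catalog: PesticideCatalog) -> pd.DataFrame:
    """Per-site detection counts: total and split by pesticide type.

    A pesticide is detected at a site when its (censored) concentration is
    strictly positive.  ``n_detected`` always equals the sum of the per-type
    counts.
    """
    types = catalog.table["type"].reindex(conc.columns)
    if types.isna().any():
        raise ValueError(f"catalog lacks type for: {types.index[types.isna()].tolist()}")
    detected = conc > 0
    out = pd.DataFrame(index=conc.index)
    out["n_detected"] = detected.sum(axis=1)
    for t in PESTICIDE_TYPES:
        cols = types.index[types == t]
        out[f"n_{t}s"] = detected[cols].sum(axis=1) if len(cols) else 0
    return out


@dataclass
class RiskTable:
    """NOEC-based risk quotients and cumulative sums per site."""

    rq: pd.DataFrame  # site x pesticide risk quotients (unitless)
    cumulative: pd.DataFrame  # per-site cumulative risk, total and per type
    excluded: list[str]  # pesticides without NOEC_min, left out of the sums


def risk_quotients(
    conc: pd.DataFrame, catalog: PesticideCatalog, assessment_factor: float = 5.0
) -> RiskTable:
    """Ecotoxicological risk quotients: ``rq = conc / NOEC_min * AF``.

    The assessment factor defaults to 5, in line with regulatory practice.
    Pesticides with no reported NOEC_min are excluded from all sums and
    listed in ``excluded`` (and the run log).  Cumulative risk per site sums
    the quotients of detected pesticides, overall and per type.
    """
    noec = catalog.table["noec_min"].reindex(conc.columns)
    excluded = noec.index[noec.isna()].tolist()
    if excluded:
        log.info("excluding %d pesticide(s) without NOEC_min from risk sums: %s",
                 len(excluded), excluded)
    included = [c for c in conc.columns if c not in excluded]
    rq = conc[included].div(noec[included], axis=1) * assessment_factor
    types = catalog.table["type"].reindex(included)
    cumulative = pd.DataFrame(index=conc.index)
    cumulative["cumulative_risk"] = rq.sum(axis=1)
    for t in PESTICIDE_TYPES:
        cols = types.index[types == t]
        cumulative[f"cumulative_risk_{t}"] = rq[cols].sum(axis=1) if len(cols) else 0.0
    return RiskTable(rq=rq, cumulative=cumulative, excluded=excluded)
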