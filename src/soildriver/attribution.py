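"""Driver attribution: variable-importance ranking and variation partitioning.

Variation partitioning decomposes the explained variance of the final
selected model into unique and shared fractions across up to four driver
groups (pesticides, soil properties, climate, ecosystem type).  One GLM is
fitted per non-empty subset of groups — the union of their selected terms,
with no re-selection — and its r² (squared predicted–observed correlation)
recorded.  The 2^k − 1 Venn-region fractions are then recovered by
inclusion–exclusion (Möbius inversion) of the subset r² values; negative
shared fractions are passed through unclipped, as in the classical
``varpart`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .glm import FittedGLM, fit_glm

__all__ = ["VIPTable", "PartitionResult", "vip", "variation_partition", "attribute_all"]


def vip(model: FittedGLM) -> pd.DataFrame:
    """Variable importance: ``|coefficient / standard error|`` per retained
    term, with the coefficient's sign giving the direction of association.

    Multi-level factor terms are summarized by their maximum component
    importance (sign taken from that component).  A zero standard error
    yields infinite importance, flagged by the value itself.
    """
    non_intercept = [t for t in model.terms]
    if not non_intercept:
        raise ValueError("VIP needs at least one non-intercept term")
    rows = []
    for term in model.terms:
        cols = model.term_columns[term]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_abs = np.abs(model.params[cols].to_numpy() / model.bse[cols].to_numpy())
        t_abs = np.where(np.isnan(t_abs), np.inf, t_abs)
        best = int(np.argmax(t_abs))
        rows.append(
            {
                "term": term,
                "importance": float(t_abs[best]),
                "sign": "+" if model.params[cols[best]] >= 0 else "-",
                "group": model.groups.get(term, "other"),
            }
        )
    out = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("term")


# kept for interface symmetry with PartitionResult
VIPTable = pd.DataFrame


@dataclass
class PartitionResult:
    """Unique/shared explained-variance decomposition over driver groups.

    ``fractions`` maps each non-empty group subset (frozenset) to its
    exclusive Venn-region fraction; ``r2`` maps each subset to its
    sub-model's r².  ``unique[g]`` is the singleton region of group g and
    equals ``r2(full) − r2(full − g)`` by construction.  All region
    fractions plus the residual sum to 1.
    """

    groups: list[str]
    r2: dict[frozenset, float]
    fractions: dict[frozenset, float]
    unique: dict[str, float]
    residual: float

    @property
    def full_r2(self) -> float:
        return self.r2[frozenset(self.groups)] if self.groups else 0.0

    def total(self, group: str) -> float:
        """Total fraction involving a group: sum of regions containing it."""
        return sum(f for s, f in self.fractions.items() if group in s)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(sorted(s)), "size": len(s), "fraction": f}
            for s, f in sorted(self.fractions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        rows.append({"subset": "residual", "size": 0, "fraction": self.residual})
        return pd.DataFrame(rows)


def _nonempty_subsets(groups: list[str]):
    for r in range(1, len(groups) + 1):
        yield from (frozenset(c) for c in combinations(groups, r))


def variation_partition(
    data: pd.DataFrame,
    response: str,
    groups: dict[str, list[str]],
    link: str = "log",
) -> PartitionResult:
    """Partition explained variance across predictor groups.

    ``groups`` maps ≤ 4 group names to the final model's terms belonging to
    each.  Groups with no terms are dropped and contribute exactly 0.  Any
    sub-model failing to converge aborts the partition with the culprit
    subset named.
    """
    active = {g: list(t) for g, t in groups.items() if t}
    dropped = [g for g in groups if not groups[g]]
    names = sorted(active)
    if len(names) > 4:
        raise ValueError("at most 4 driver groups are supported")
    if not names:
        return PartitionResult(groups=[], r2={}, fractions={}, unique={}, residual=1.0)

    r2: dict[frozenset, float] = {}
    for subset in _nonempty_subsets(names):
        terms = sorted({t for g in subset for t in active[g]})
        fit = fit_glm(data, response, terms, link=link)
        if not fit.converged:
            raise RuntimeError(f"sub-model for subset {sorted(subset)} did not converge")
        r2[subset] = fit.r2

    # Treat r2(S) as the measure of the union of the groups' variance
    # regions.  Intersection measures by inclusion-exclusion, then exclusive
    # Venn regions by Moebius inversion over the superset lattice.
    full = frozenset(names)
    inter: dict[frozenset, float] = {}
    for s in _nonempty_subsets(names):
        inter[s] = sum(
            (-1) ** (len(w) + 1) * r2[frozenset(w)]
            for r in range(1, len(s) + 1)
            for w in combinations(sorted(s), r)
        )
    fractions: dict[frozenset, float] = {}
    for t in _nonempty_subsets(names):
        fractions[t] = sum(
            (-1) ** (len(s) - len(t)) * inter[s]
            for r in range(len(t), len(names) + 1)
            for s in (frozenset(c) for c in combinations(names, r))
            if t <= s
        )
    unique = {g: fractions[frozenset([g])] for g in names}
    unique.update({g: 0.0 for g in dropped})
    residual = 1.0 - r2[full]
    return PartitionResult(groups=names, r2=r2, fractions=fractions,
                           unique=unique, residual=residual)


def attribute_all(
    models: dict[str, FittedGLM], data: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack VIP and partition outputs across biodiversity metrics.

    ``models`` maps metric name to a final (two-stage) fit carrying
    term -> driver-group labels.  Returns tidy long-format frames:
    ``(partitions, vips)`` keyed by metric.  Metrics whose model retained no
    term from a group get fraction 0 for that group.
    """
    part_rows, vip_rows = [], []
    for metric, model in models.items():
        groups: dict[str, list[str]] = {"pesticides": [], "soil": [], "climate": [],
                                        "ecosystem": []}
        for term, g in model.groups.items():
            groups.setdefault(g, []).append(term)
        part = variation_partition(data, metric, groups, link=model.link)
        frame = part.to_frame()
        frame.insert(0, "metric", metric)
        part_rows.append(frame)
        for g in ("pesticides", "soil", "climate", "ecosystem"):
            if not groups.get(g):  # group absent from the final model -> fraction 0
                part_rows.append(pd.DataFrame(
                    [{"metric": metric, "subset": g, "size": 1, "fraction": 0.0}]))
        if model.terms:
            v = vip(model).reset_index()
            v.insert(0, "metric", metric)
            vip_rows.append(v)
    partitions = pd.concat(part_rows, ignore_index=True) if part_rows else pd.DataFrame()
    vips = pd.concat(vip_rows, ignore_index=True) if vip_rows else pd.DataFrame()
    return partitions, vips
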