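"""Complementary analyses around the main GLM pipeline.

Presence/absence environmental comparisons (Kruskal-Wallis), Spearman
correlation screens of biodiversity metrics against aggregated pesticide
metrics (occurrence counts and cumulative risks), and pairwise ecosystem
comparisons of per-site residue counts with Benjamini-Hochberg correction
and a compact letter display.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import FittedGLM

__all__ = [
    "presence_env_tests",
    "spearman_screen",
    "ecosystem_residue_comparison",
    "compact_letter_display",
    "bh_adjust",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _kruskal_two_group(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square(1) p for two groups, tolerating the
    all-identical degenerate case (H = 0, p = 1)."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)


def presence_env_tests(
    models: dict[str, FittedGLM], conc: pd.DataFrame, env: pd.DataFrame
) -> pd.DataFrame:
    """Environmental conditions associated with pesticide presence.

    For each pesticide retained in a final model and each environmental
    variable selected in the same model, sites are split by presence
    (censored concentration > 0) and the environmental values compared with
    a Kruskal-Wallis test (rank-based, tie-corrected; the two-group case is
    equivalent to a Wilcoxon rank-sum test).  Raw and BH-adjusted p-values
    are reported side by side.  Tests with an empty presence group are
    skipped with a reason.
    """
    rows = []
    for metric, model in models.items():
        pest_terms = [t for t, g in model.groups.items() if g == "pesticides"]
        env_terms = [t for t, g in model.groups.items()
                     if g in ("soil", "climate") and t in env.columns]
        for pest in pest_terms:
            present = conc[pest] > 0
            for var in env_terms:
                n_p, n_a = int(present.sum()), int((~present).sum())
                if n_p == 0 or n_a == 0:
                    rows.append({"metric": metric, "pesticide": pest, "env_var": var,
                                 "n_present": n_p, "n_absent": n_a, "H": np.nan,
                                 "p": np.nan, "skipped": "empty presence group"})
                    continue
                h, p = _kruskal_two_group(env.loc[present, var].to_numpy(float),
                                          env.loc[~present, var].to_numpy(float))
                rows.append({"metric": metric, "pesticide": pest, "env_var": var,
                             "n_present": n_p, "n_absent": n_a, "H": h, "p": p,
                             "skipped": ""})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def spearman_screen(biodiv: pd.DataFrame, aggregates: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of each biodiversity metric against each
    aggregated pesticide metric, BH-adjusted across the full screen.

    Spearman (average-rank ties, asymptotic p) admits monotone nonlinear
    associations.  Constant columns yield missing correlations.  Requires
    >= 4 complete pairs per cell.
    """
    common = biodiv.index.intersection(aggregates.index)
    rows = []
    for metric in biodiv.columns:
        for agg in aggregates.columns:
            x = biodiv.loc[common, metric].astype(float)
            y = aggregates.loc[common, agg].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 4:
                raise ValueError(f"fewer than 4 complete pairs for {metric} vs {agg}")
            xs, ys = x[ok], y[ok]
            if xs.nunique() < 2 or ys.nunique() < 2:
                rho, p = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = stats.spearmanr(xs, ys)
            rows.append({"metric": metric, "aggregate": agg, "n": int(ok.sum()),
                         "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def compact_letter_display(
    labels: list[str], sig_pairs: set[frozenset]
) -> dict[str, str]:
    """Assign letters so two groups share a letter iff their difference is
    NOT significant (insert-and-absorb algorithm)."""
    letter_sets: list[set[str]] = []
    for lab in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((lab, other)) not in sig_pairs for other in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
            # absorb: add every label compatible with the new set
            for other in labels:
                if other != lab and all(
                    frozenset((other, m)) not in sig_pairs for m in letter_sets[-1]
                ):
                    letter_sets[-1].add(other)
    # drop redundant sets (subsets of others)
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, s in enumerate(letter_sets):
        for lab in sorted(s, key=labels.index):
            out[lab] += alphabet[i % 26]
    return out


def ecosystem_residue_comparison(
    conc: pd.DataFrame,
    env: pd.DataFrame,
    ecosystem_col: str = "ecosystem",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise ecosystem comparison of per-site detected-residue counts.

    Two-sided Wilcoxon rank-sum (Mann-Whitney) tests on the number of
    pesticides detected per site, for every ecosystem pair, BH-adjusted
    across pairs; a compact letter display groups ecosystems whose adjusted
    difference is not significant at ``alpha``.
    """
    counts = (conc > 0).sum(axis=1)
    eco = env[ecosystem_col].astype(str)
    levels = [lv for lv in eco.unique() if (eco == lv).sum() >= 2]
    if len(levels) < 2:
        raise ValueError("need >= 2 ecosystems with >= 2 sites each")
    rows = []
    for a, b in combinations(levels, 2):
        xa, xb = counts[eco == a].to_numpy(), counts[eco == b].to_numpy()
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"ecosystem_a": a, "ecosystem_b": b,
                     "n_a": len(xa), "n_b": len(xb), "U": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = {frozenset((r.ecosystem_a, r.ecosystem_b))
           for r in out.itertuples() if r.q < alpha}
    letters = compact_letter_display(levels, sig)
    return out, letters
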