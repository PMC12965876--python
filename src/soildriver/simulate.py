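"""Synthetic generators for every pipeline input.

The study design being emulated: hundreds of European soil-monitoring sites,
each carrying a zero-inflated pesticide residue concentration vector
(values below the limit of quantification recorded as exact zeros), a set of
correlated soil and climate covariates plus a five-level ecosystem factor,
per-organism-group taxon count tables, per-site functional-gene summaries,
and soil biodiversity response metrics.  Responses are drawn from the same
Gaussian log-link model family the analysis fits, with per-driver-group
unique explained-variance fractions controlled as ground truth, so the whole
attribution machinery can be validated against known answers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "CalibrationError",
    "ECOSYSTEM_LEVELS",
    "ORGANISM_GROUPS",
    "GENE_GROUPS",
    "generate_concentrations",
    "generate_environment",
    "generate_counts",
    "generate_response",
    "generate_dataset",
]

ECOSYSTEM_LEVELS = (
    "annual_cropland",
    "permanent_cropland",
    "former_cropland",
    "extensive_grassland",
    "woodland",
)

#: observed site counts per ecosystem in the emulated monitoring design
#: (210, 34, 19, 97, 13 of 373)
ECOSYSTEM_PROPORTIONS = (210 / 373, 34 / 373, 19 / 373, 97 / 373, 13 / 373)

ORGANISM_GROUPS = ("archaea", "bacteria", "fungi", "protists", "nematodes", "arthropods")

GENE_GROUPS = (
    "N_fixation",
    "nitrification",
    "denitrification",
    "P_mineralization",
    "cellulose_degradation",
    "chitin_degradation",
)


class CalibrationError(RuntimeError):
    """Raised when coefficient calibration cannot reach the requested group_r2."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated monitoring campaign: 373 sites, five
    ecosystem types with the observed proportions, 11 soil and 7 climate
    covariates, and residue concentrations on the mg/kg scale with LOQ
    censoring at 0.001 mg/kg.
    """

    n_sites: int = 373
    n_pesticides: int = 24
    detect_prob: float = 0.3
    conc_log_mean: float = -4.6  # lognormal mean of detected residues, exp(-4.6) ~ 0.01 mg/kg
    conc_log_sd: float = 1.0
    loq: float = 0.001  # mg/kg, lower end of the reported 0.001-0.025 range
    n_soil_vars: int = 11
    n_climate_vars: int = 7
    ecosystem_levels: Sequence[str] = ECOSYSTEM_LEVELS
    ecosystem_probs: Sequence[float] = ECOSYSTEM_PROPORTIONS
    env_correlation: float = 0.3  # exchangeable correlation within the soil and climate blocks
    group_r2: Mapping[str, float] = field(
        default_factory=lambda: {"pesticides": 0.15, "soil": 0.20, "climate": 0.10}
    )
    noise_sd: float = 5.0
    response_mean: float = 100.0  # baseline of the response on its natural scale
    response_names: Sequence[str] = ("biodiversity_index",)
    n_true_per_group: int = 2
    orthogonalize: bool = False
    n_taxa: int = 150
    dirichlet_conc: float = 0.5
    library_size_range: tuple[int, int] = (5000, 50000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites <= 0 or self.n_pesticides <= 0:
            raise ValueError("n_sites and n_pesticides must be positive")
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError(f"detect_prob must lie in [0, 1], got {self.detect_prob}")
        if self.loq < 0:
            raise ValueError("loq must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.ecosystem_levels) != len(self.ecosystem_probs):
            raise ValueError("ecosystem_levels and ecosystem_probs must align")
        if abs(sum(self.ecosystem_probs) - 1.0) > 1e-8:
            raise ValueError("ecosystem_probs must sum to 1")
        if any(v < 0 for v in self.group_r2.values()):
            raise ValueError("group_r2 fractions must be non-negative")
        if sum(self.group_r2.values()) >= 1.0:
            raise ValueError("group_r2 fractions must sum to < 1 (residual must be positive)")
        if not -1.0 < self.env_correlation < 1.0:
            raise ValueError("env_correlation must lie in (-1, 1)")

    def child_rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class SyntheticDataset:
    """All pipeline inputs plus the generating truth record."""

    concentrations: pd.DataFrame
    environment: pd.DataFrame
    counts: dict[str, pd.DataFrame]
    gene_summaries: pd.DataFrame
    responses: pd.DataFrame
    truth: dict

    @property
    def site_ids(self) -> pd.Index:
        return self.concentrations.index

    def write(self, outdir: str | Path) -> None:
        """Write every table as TSV (site_id key column) and the truth as JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.concentrations.rename_axis("site_id").to_csv(outdir / "concentrations.tsv", sep="\t")
        self.environment.rename_axis("site_id").to_csv(outdir / "environment.tsv", sep="\t")
        for group, table in self.counts.items():
            table.rename_axis("site_id").to_csv(outdir / f"counts_{group}.tsv", sep="\t")
        self.gene_summaries.rename_axis("site_id").to_csv(outdir / "gene_summaries.tsv", sep="\t")
        self.responses.rename_axis("site_id").to_csv(outdir / "responses.tsv", sep="\t")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, default=list))


def _site_index(n: int) -> pd.Index:
    return pd.Index([f"site_{i + 1:04d}" for i in range(n)], name="site_id")


def generate_concentrations(cfg: SimulationConfig) -> pd.DataFrame:
    """Zero-inflated, LOQ-censored site x pesticide residue matrix (mg/kg).

    Each entry is 0 with probability ``1 - detect_prob``, otherwise a
    lognormal draw; draws below ``loq`` are censored to exactly 0.  One
    additional near-constant column (``pest_rare``, detected at ~2% of
    sites) is always planted so the near-zero-variance filter downstream
    has something to remove.
    """
    cfg.validate()
    rng = cfg.child_rng(0)
    n, p = cfg.n_sites, cfg.n_pesticides
    detected = rng.random((n, p)) < cfg.detect_prob
    values = rng.lognormal(cfg.conc_log_mean, cfg.conc_log_sd, size=(n, p))
    conc = np.where(detected, values, 0.0)
    conc[conc < cfg.loq] = 0.0

    cols = [f"pest_{i + 1:02d}" for i in range(p)]
    df = pd.DataFrame(conc, index=_site_index(n), columns=cols)

    # planted all-rare column: a handful of identical detections
    n_rare = max(1, round(0.02 * n))
    rare = np.zeros(n)
    rare_sites = rng.choice(n, size=n_rare, replace=False)
    rare[rare_sites] = max(cfg.loq, np.exp(cfg.conc_log_mean))
    df["pest_rare"] = rare
    return df


def _block_corr(size: int, rho: float) -> np.ndarray:
    c = np.full((size, size), rho)
    np.fill_diagonal(c, 1.0)
    return c


def generate_environment(cfg: SimulationConfig) -> pd.DataFrame:
    """Correlated soil and climate covariates plus the ecosystem factor.

    Soil and climate blocks are drawn from independent multivariate normals
    with exchangeable within-block correlation ``env_correlation``.  The two
    special soil columns get realistic scales: ``soil_pH`` around 6.5 and a
    strictly positive lognormal ``soil_EC`` (electrical conductivity).
    """
    cfg.validate()
    rng = cfg.child_rng(1)
    n = cfg.n_sites

    def draw_block(k: int) -> np.ndarray:
        corr = _block_corr(k, cfg.env_correlation)
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as err:
            raise ValueError("environment correlation matrix is not positive definite") from err
        return rng.standard_normal((n, k)) @ chol.T

    soil = draw_block(cfg.n_soil_vars)
    climate = draw_block(cfg.n_climate_vars)

    soil_cols = ["soil_pH", "soil_EC"] + [f"soil_{i + 1:02d}" for i in range(2, cfg.n_soil_vars)]
    soil_cols = soil_cols[: cfg.n_soil_vars]
    env = pd.DataFrame(soil, index=_site_index(n), columns=soil_cols)
    if "soil_pH" in env:
        env["soil_pH"] = 6.5 + env["soil_pH"]
    if "soil_EC" in env:
        env["soil_EC"] = np.exp(0.5 * env["soil_EC"])  # dS/m, strictly positive
    for j in range(cfg.n_climate_vars):
        env[f"climate_{j + 1:02d}"] = climate[:, j]
    env["ecosystem"] = pd.Categorical(
        rng.choice(list(cfg.ecosystem_levels), size=n, p=list(cfg.ecosystem_probs)),
        categories=list(cfg.ecosystem_levels),
    )
    return env


def generate_counts(cfg: SimulationConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Multinomial taxon count tables and functional-gene summaries.

    Per organism group: a Dirichlet-distributed taxon probability profile and
    per-site multinomial draws with library sizes uniform over
    ``library_size_range``.  Gene summaries carry, per site and gene group,
    an orthologous-group count and a functionally annotated read total.
    """
    cfg.validate()
    rng = cfg.child_rng(2)
    n, s = cfg.n_sites, cfg.n_taxa
    sites = _site_index(n)

    counts: dict[str, pd.DataFrame] = {}
    for group in ORGANISM_GROUPS:
        probs = rng.dirichlet(np.full(s, cfg.dirichlet_conc))
        libs = rng.integers(cfg.library_size_range[0], cfg.library_size_range[1] + 1, size=n)
        mat = np.vstack([rng.multinomial(lib, probs) for lib in libs])
        counts[group] = pd.DataFrame(
            mat, index=sites, columns=[f"{group[:4]}_taxon_{j + 1:04d}" for j in range(s)]
        )

    rows = {}
    for gg in GENE_GROUPS:
        reads = rng.integers(100_000, 2_000_000, size=n)
        ogs = rng.poisson(150 + 50 * rng.random(n) * (reads / 1e6))
        rows[f"og_count_{gg}"] = ogs
        rows[f"functional_reads_{gg}"] = reads
    gene_summaries = pd.DataFrame(rows, index=sites)
    return counts, gene_summaries


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _true_design(
    env: pd.DataFrame, conc: pd.DataFrame, cfg: SimulationConfig
) -> tuple[dict[str, list[str]], np.ndarray, list[str]]:
    """Pick true predictors per driver group and build the standardized design."""
    k = cfg.n_true_per_group
    groups: dict[str, list[str]] = {}
    if "pesticides" in cfg.group_r2:
        # prefer well-detected columns so the signal carrier has variance
        det = (conc > 0).mean()
        usable = det[det > 0.05].index.tolist()
        groups["pesticides"] = usable[:k]
    if "soil" in cfg.group_r2:
        soil_cols = [c for c in env.columns if c.startswith("soil_")]
        groups["soil"] = soil_cols[:k]
    if "climate" in cfg.group_r2:
        climate_cols = [c for c in env.columns if c.startswith("climate_")]
        groups["climate"] = climate_cols[:k]
    if "ecosystem" in cfg.group_r2:
        groups["ecosystem"] = ["ecosystem"]

    cols: list[np.ndarray] = []
    col_groups: list[str] = []
    for g, names in groups.items():
        for name in names:
            if name == "ecosystem":
                dummies = pd.get_dummies(env["ecosystem"], drop_first=True).to_numpy(float)
                for j in range(dummies.shape[1]):
                    cols.append(_standardize(dummies[:, j]))
                    col_groups.append(g)
            else:
                src = conc if name in conc.columns else env
                cols.append(_standardize(src[name].to_numpy(float)))
                col_groups.append(g)
    x = np.column_stack(cols) if cols else np.empty((len(env), 0))

    if cfg.orthogonalize and x.shape[1] > 1:
        # sequential Gram-Schmidt keeps each column attributable to its group
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        x = np.column_stack([_standardize(q[:, j]) for j in range(q.shape[1])])
    return groups, x, col_groups


def _subset_r2(mu: np.ndarray, x: np.ndarray, idx: list[int], total_var: float) -> float:
    """Fraction of total variance captured by OLS of the mean surface on columns idx."""
    if not idx:
        return 0.0
    design = np.column_stack([np.ones(len(mu)), x[:, idx]])
    beta, *_ = np.linalg.lstsq(design, mu, rcond=None)
    resid = mu - design @ beta
    return (mu.var() - resid.var()) / total_var


def generate_response(
    env: pd.DataFrame, conc: pd.DataFrame, cfg: SimulationConfig
) -> tuple[pd.DataFrame, dict]:
    """Biodiversity responses from a Gaussian log-link generative model.

    For each requested metric, ``y = exp(eta) + eps`` with
    ``eta = b0 + sum_g s_g * z_g`` where ``z_g`` is the unit-variance signal
    of driver group ``g``.  The per-group scales ``s_g`` are calibrated by a
    deterministic fixed-point search on the realized design so each group's
    unique explained-variance fraction matches ``cfg.group_r2`` (analytic
    r-squared under a log link being intractable).  ``eps`` is iid
    ``N(0, noise_sd^2)``.
    """
    cfg.validate()
    if not env.index.equals(conc.index):
        raise ValueError("environment and concentration tables must share site ids")
    rng = cfg.child_rng(3)
    n = len(env)
    groups, x, col_groups = _true_design(env, conc, cfg)
    group_names = [g for g in groups if cfg.group_r2.get(g, 0.0) > 0 and groups[g]]
    targets = {g: cfg.group_r2[g] for g in group_names}
    b0 = float(np.log(cfg.response_mean))

    # per-group unit-variance signal carrier
    signals = {}
    for g in group_names:
        idx = [j for j, cg in enumerate(col_groups) if cg == g]
        z = x[:, idx].sum(axis=1)
        signals[g] = _standardize(z)

    if cfg.noise_sd == 0 or not group_names:
        scales = {g: float(np.sqrt(t)) * 0.1 for g, t in targets.items()}
    else:
        total_signal = sum(targets.values())
        v_tot = cfg.noise_sd**2 / (1.0 - total_signal)
        scales = {
            g: float(np.sqrt(t * v_tot)) / cfg.response_mean for g, t in targets.items()
        }
        # fixed-point refinement against the realized design
        sig_mat = np.column_stack([signals[g] for g in group_names])
        gidx = {g: [i] for i, g in enumerate(group_names)}
        all_idx = list(range(len(group_names)))
        for _ in range(12):
            eta = b0 + sum(scales[g] * signals[g] for g in group_names)
            mu = np.exp(eta)
            total_var = mu.var() + cfg.noise_sd**2
            full = _subset_r2(mu, sig_mat, all_idx, total_var)
            realized = {
                g: full - _subset_r2(mu, sig_mat, [i for i in all_idx if i not in gidx[g]],
                                     total_var)
                for g in group_names
            }
            if all(abs(realized[g] - targets[g]) < 1e-3 for g in group_names):
                break
            for g in group_names:
                if realized[g] <= 1e-12:
                    scales[g] *= 2.0
                else:
                    scales[g] *= float(np.sqrt(targets[g] / realized[g]))
                if not np.isfinite(scales[g]):
                    raise CalibrationError(
                        f"calibration diverged for group {g!r}; "
                        f"group_r2={targets} unattainable with noise_sd={cfg.noise_sd}"
                    )
        else:
            if any(abs(realized[g] - targets[g]) > 0.02 for g in group_names):
                raise CalibrationError(
                    f"calibration did not converge: realized={realized}, targets={targets}"
                )

    eta = b0 + sum(scales[g] * signals[g] for g in group_names) if group_names else np.full(n, b0)
    mu = np.exp(eta)
    responses = {}
    for name in cfg.response_names:
        responses[name] = mu + rng.normal(0.0, cfg.noise_sd, size=n)
    resp = pd.DataFrame(responses, index=env.index)

    truth = {
        "true_predictors": {g: list(v) for g, v in groups.items()},
        "group_scales": {g: scales.get(g, 0.0) for g in groups},
        "group_r2": dict(cfg.group_r2),
        "intercept": b0,
        "noise_sd": cfg.noise_sd,
        "orthogonalized": cfg.orthogonalize,
    }
    return resp, truth


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full aligned input bundle from one config (one global seed)."""
    cfg.validate()
    conc = generate_concentrations(cfg)
    env = generate_environment(cfg)
    counts, gene_summaries = generate_counts(cfg)
    responses, truth = generate_response(env, conc, cfg)
    return SyntheticDataset(
        concentrations=conc,
        environment=env,
        counts=counts,
        gene_summaries=gene_summaries,
        responses=responses,
        truth=truth,
    )
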