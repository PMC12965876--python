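"""Top-level modelling interface.

:class:`SoilDriverModel` bundles one biodiversity response with the four
candidate driver groups (pesticide concentrations, soil properties, climate
variables, ecosystem type) and, on :meth:`~SoilDriverModel.fit`, runs the
full attribution analysis: near-zero-variance screening of the pesticide
columns, two-stage scope-constrained AIC stepwise selection of a Gaussian
log-link GLM, variable-importance ranking, variation partitioning, and
residual/collinearity diagnostics.  The returned
:class:`SoilDriverResults` carries the estimates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import attribution, glm, prep

__all__ = ["SoilDriverModel", "SoilDriverResults"]


class SoilDriverModel:
    """Driver-attribution model for one soil biodiversity metric.

    Parameters
    ----------
    data : DataFrame
        Site-level frame holding the response, the (already LOQ-censored)
        pesticide concentration columns, and the environmental columns.
    response : str
        Name of the biodiversity metric column (richness, Shannon,
        multidiversity, functional-group %, pmOG, ...).
    pesticide_terms, soil_terms, climate_terms : list of str
        Candidate predictor columns per driver group.
    ecosystem_term : str or None
        Categorical ecosystem column (single factor term), or None.
    nzv_kwargs : dict
        Options for the near-zero-variance filter applied to the pesticide
        candidates before selection.
    link : str
        GLM link; the analysis default is ``"log"`` (Gaussian family).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        pesticide_terms: list[str],
        soil_terms: list[str],
        climate_terms: list[str],
        ecosystem_term: str | None = "ecosystem",
        nzv_kwargs: dict | None = None,
        link: str = "log",
    ):
        missing = [c for c in [response, *pesticide_terms, *soil_terms, *climate_terms]
                   if c not in data.columns]
        if missing:
            raise ValueError(f"columns absent from data: {missing}")
        if ecosystem_term is not None and ecosystem_term not in data.columns:
            ecosystem_term = None
        self.data = data
        self.response = response
        self.pesticide_terms = list(pesticide_terms)
        self.soil_terms = list(soil_terms)
        self.climate_terms = list(climate_terms)
        self.ecosystem_term = ecosystem_term
        self.nzv_kwargs = nzv_kwargs or {}
        self.link = link

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kwargs) -> "SoilDriverModel":
        """Build from one frame, inferring driver groups from column prefixes
        (``pest_*``, ``soil_*``, ``climate_*``, ``ecosystem``)."""
        kwargs.setdefault("pesticide_terms", [c for c in data.columns if c.startswith("pest_")])
        kwargs.setdefault("soil_terms", [c for c in data.columns if c.startswith("soil_")])
        kwargs.setdefault("climate_terms", [c for c in data.columns if c.startswith("climate_")])
        return cls(data, response, **kwargs)

    def fit(self) -> "SoilDriverResults":
        nzv = prep.near_zero_variance_filter(self.data[self.pesticide_terms], **self.nzv_kwargs) \
            if self.pesticide_terms else prep.NZVReport(kept=[])
        final = glm.two_stage_selection(
            self.data,
            self.response,
            soil_terms=self.soil_terms,
            climate_terms=self.climate_terms,
            pesticide_terms=nzv.kept,
            ecosystem_term=self.ecosystem_term,
            link=self.link,
        )
        groups: dict[str, list[str]] = {"pesticides": [], "soil": [], "climate": [],
                                        "ecosystem": []}
        for term, g in final.groups.items():
            groups.setdefault(g, []).append(term)
        partition = attribution.variation_partition(self.data, self.response, groups,
                                                    link=self.link)
        vip_table = attribution.vip(final) if final.terms else pd.DataFrame()
        vifs = glm.vif_check(final, self.data) if (
            sum(len(final.term_columns[t]) for t in final.terms) >= 2) else pd.DataFrame()
        diagnostics = glm.residual_diagnostics(final)
        return SoilDriverResults(
            model=self, final=final, stage1=final.stage1, filter_report=nzv,
            vip_table=vip_table, partition=partition, vifs=vifs, diagnostics=diagnostics,
        )


@dataclass
class SoilDriverResults:
    """Results of a fitted :class:`SoilDriverModel`."""

    model: SoilDriverModel
    final: glm.FittedGLM
    stage1: glm.FittedGLM | None
    filter_report: prep.NZVReport
    vip_table: pd.DataFrame
    partition: attribution.PartitionResult
    vifs: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def selected_terms(self) -> list[str]:
        return list(self.final.terms)

    @property
    def r2(self) -> float:
        return self.final.r2

    def summary(self) -> str:
        lines = [
            "=" * 70,
            f"Soil biodiversity driver attribution  —  response: {self.model.response}",
            "=" * 70,
            self.final.summary(),
            "",
            f"near-zero-variance filter: kept {len(self.filter_report.kept)} "
            f"of {len(self.filter_report.kept) + len(self.filter_report.removed)} "
            f"pesticide columns",
            "",
            "variation partitioning (fraction of response variance):",
            self.partition.to_frame().to_string(index=False,
                                                float_format=lambda v: f"{v: .4f}"),
        ]
        if len(self.vip_table):
            lines += ["", "variable importance (|t|, signed):",
                      self.vip_table.to_string(float_format=lambda v: f"{v: .3f}")]
        if self.diagnostics:
            lines += ["", f"residual normal-QQ correlation: {self.diagnostics['qq_corr']:.4f}"
                          f"   Shapiro-Wilk p: {self.diagnostics['shapiro_p']:.3g}"]
        return "\n".join(lines)
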