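"""Convenience driver chaining the standard analysis end to end.

Runs the canonical order of operations on a dataset (simulated or
loaded): detection filtering over human samples, mouse cross-reactive
probe masking, annotation-based exclusions, beta computation, BMIQ
probe-type normalization, logit2 transform, empirical-Bayes batch
adjustment, passage-vs-patient contrasts per model, treatment contrasts
at F3, and the in-vitro cell-line contrast when present.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .batch import batch_adjust
from .bmiq import NormalizationModel, bmiq_normalize
from .diffmeth import Contrast, fit_moderated
from .manifest_io import IntensityData, ProbeManifest, SampleSheet
from .preprocess import (
    FilterReport,
    beta_to_m,
    compute_beta,
    detection_filter,
    exclude_probes,
    mouse_mask,
)
from .strategy import dac_demethylated_sites, stable_sites
from .synthetic import SimulatedDataset, SimulationDesign, simulate_dataset


@dataclass
class PipelineResult:
    """Matrices, filter accounting and contrast results of one full run."""

    beta_raw: pd.DataFrame
    beta_norm: pd.DataFrame
    m_adj: pd.DataFrame
    report: FilterReport
    norm_model: NormalizationModel
    gen_results: dict[tuple[str, str], pd.DataFrame]
    res_dac: pd.DataFrame
    res_cisplatin: pd.DataFrame
    res_invitro: pd.DataFrame | None

    @property
    def universe(self) -> pd.Index:
        return self.m_adj.index

    @property
    def stable(self) -> pd.Index:
        return stable_sites(self.gen_results)

    @property
    def invivo_dac(self) -> pd.Index:
        return dac_demethylated_sites(self.res_dac)

    @property
    def invitro_dac(self) -> pd.Index | None:
        if self.res_invitro is None:
            return None
        return dac_demethylated_sites(self.res_invitro)


def run_standard_pipeline(
    intensities: IntensityData,
    manifest: ProbeManifest,
    samples: SampleSheet,
    models: tuple[str, ...],
    generations: tuple[str, ...],
    treated_model: str,
    include_invitro: bool = True,
) -> PipelineResult:
    data, rep_det = detection_filter(intensities, samples)
    data, rep_mouse = mouse_mask(data, samples)
    data, rep_ann = exclude_probes(data, manifest)
    report = rep_det.merge(rep_mouse).merge(rep_ann)

    beta = compute_beta(data.meth, data.unmeth)
    beta_norm, norm_model = bmiq_normalize(beta, manifest)
    m = beta_to_m(beta_norm)
    m_adj = batch_adjust(m, samples.df.loc[m.columns, "batch"])

    gen_results: dict[tuple[str, str], pd.DataFrame] = {}
    for model in models:
        f0 = list(samples.select(model=model, generation=generations[0], treatment="none"))
        for gen in generations[1:]:
            grp = list(samples.select(model=model, generation=gen, treatment="none"))
            res, _ = fit_moderated(m_adj, Contrast(f"{model}_{gen}_vs_{generations[0]}", grp, f0))
            gen_results[(model, gen)] = res

    vehicle = list(samples.select(treatment="vehicle"))
    dac = list(samples.select(treatment="DAC", model=treated_model))
    cis = list(samples.select(treatment="cisplatin"))
    res_dac, _ = fit_moderated(m_adj, Contrast("DAC_vs_vehicle", dac, vehicle))
    res_cis, _ = fit_moderated(m_adj, Contrast("cisplatin_vs_vehicle", cis, vehicle))

    res_invitro = None
    if include_invitro:
        sk_dac = list(samples.select(model="SKOV3", treatment="DAC"))
        sk_ctl = list(samples.select(model="SKOV3", treatment="none"))
        if sk_dac and sk_ctl:
            res_invitro, _ = fit_moderated(m_adj, Contrast("invitro_DAC", sk_dac, sk_ctl))

    return PipelineResult(
        beta_raw=beta,
        beta_norm=beta_norm,
        m_adj=m_adj,
        report=report,
        norm_model=norm_model,
        gen_results=gen_results,
        res_dac=res_dac,
        res_cisplatin=res_cis,
        res_invitro=res_invitro,
    )


def run_simulated_pipeline(design: SimulationDesign) -> tuple[SimulatedDataset, PipelineResult]:
    """Simulate one dataset under ``design`` and run the standard analysis."""
    sim = simulate_dataset(design)
    result = run_standard_pipeline(
        sim.intensities,
        sim.manifest,
        sim.samples,
        models=design.models,
        generations=design.generations,
        treated_model=design.treated_model,
        include_invitro=design.include_invitro,
    )
    return sim, result
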