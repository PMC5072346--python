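"""Synthetic Infinium-450K-like datasets with known ground truth.

The generator emulates the statistical structure of a high-grade serous
ovarian cancer (HGSOC) patient-derived-xenograft (PDX) methylome study:

* a trimodal beta-value landscape (lowly / partially / highly methylated
  sites, LMS / PMS / HMS) drawn from a per-state beta-distribution
  mixture;
* type-II probe dynamic-range compression (multiplicative shrinkage of
  M-values toward 0), the bias BMIQ normalization corrects;
* per-batch location/scale shifts on the M-value scale;
* a small per-generation methylome drift during PDX propagation;
* a decitabine (DAC) arm demethylating ~10% of CpGs, predominantly at
  highly methylated sites, and a cisplatin arm touching ~0.5% of CpGs in
  mixed directions;
* an in-vitro DAC-sensitive cell-line arm whose affected sites contain
  the in-vivo DAC targets (used by the candidate screen);
* mouse cross-reactive probes that pass detection in a mouse control
  sample;
* channel intensities constructed so that beta computed with the
  standard +100 offset reproduces the latent beta exactly.

All treatment, drift and model effects are planted on the M-value
(logit2) scale and back-transformed, which keeps beta bounded in (0,1).
Randomness is organised as one stream for probe-level structure and one
stream per sample keyed by (seed, CRC32(sample_id)), so a sample's data
do not depend on the order in which samples are generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .manifest_io import IntensityData, ProbeManifest, SampleSheet

STATES = ("LMS", "PMS", "HMS")


@dataclass
class BatchEffect:
    """Location shift (M-value units) and scale factor for one batch."""

    shift: float = 0.0
    scale: float = 1.0


@dataclass
class TreatmentEffect:
    """A planted treatment effect.

    fraction_affected: proportion of probes perturbed in the treated arm.
    delta_m: M-value shift magnitude; applied with negative sign
        (demethylation) to ``down_fraction`` of affected probes and
        positive sign to the rest.
    target_state: if "HMS", affected probes are drawn with 8:1 weighting
        toward highly methylated sites, mimicking where a demethylating
        agent has room to act.
    """

    fraction_affected: float
    delta_m: float
    down_fraction: float
    target_state: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_affected <= 1:
            raise ValueError("fraction_affected must be in [0,1]")
        if not 0 <= self.down_fraction <= 1:
            raise ValueError("down_fraction must be in [0,1]")
        if self.delta_m >= 0 and self.down_fraction > 0:
            raise ValueError("delta_m must be negative for the 'down' arm")


@dataclass
class SimulationDesign:
    """Study design of the simulated PDX methylome experiment.

    Defaults encode the study conditions the pipeline is meant to
    reproduce: three PDX models propagated over generations F0-F3 with
    three biological replicates per arm, F3 treatment arms (vehicle /
    DAC / cisplatin), an SKOV3-like in-vitro DAC arm, one mouse-tail
    control, two scanner batches, and effect sizes large enough that a
    3-vs-3 moderated-t comparison has near-complete power (within-arm
    noise sd 0.3 M-units against planted shifts of 2-3 M-units).
    """

    n_probes: int = 20_000
    fraction_type_ii: float = 0.72
    state_proportions: tuple[float, float, float] = (0.35, 0.25, 0.40)
    state_beta_params: tuple[tuple[float, float], ...] = (
        (1.5, 18.0),  # LMS, mean ~0.08
        (6.0, 6.0),  # PMS, mean 0.5
        (18.0, 2.5),  # HMS, mean ~0.88
    )
    models: tuple[str, ...] = ("PDX36", "PDX37", "PDX56")
    generations: tuple[str, ...] = ("F0", "F1", "F2", "F3")
    replicates: int = 3
    batch_effects: dict[str, BatchEffect] = field(
        default_factory=lambda: {"B1": BatchEffect(0.0, 1.0), "B2": BatchEffect(0.4, 1.15)}
    )
    drift_fraction: float = 0.01
    drift_delta_m: float = 2.0
    model_shift_fraction: float = 0.05
    model_shift_delta_m: float = 2.0
    noise_sd: float = 0.3
    type_ii_compression: float = 0.8
    dac_effect: TreatmentEffect = field(
        default_factory=lambda: TreatmentEffect(0.106, -3.0, 0.976, "HMS")
    )
    cisplatin_effect: TreatmentEffect = field(
        default_factory=lambda: TreatmentEffect(0.0053, -2.5, 0.61, None)
    )
    include_invitro: bool = True
    invitro_fraction_affected: float = 0.393
    mouse_crossreactive_fraction: float = 0.097
    intensity_scale: float = 5000.0
    detection_noise: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.state_proportions) - 1.0) > 1e-9:
            raise ValueError("state_proportions must sum to 1")
        for p in (
            self.fraction_type_ii,
            self.drift_fraction,
            self.model_shift_fraction,
            self.mouse_crossreactive_fraction,
            self.detection_noise,
            self.invitro_fraction_affected,
        ):
            if not 0 <= p <= 1:
                raise ValueError("all proportions must lie in [0,1]")

    @property
    def treated_model(self) -> str:
        return self.models[0]


def default_study_design(seed: int = 0, n_probes: int = 20_000) -> SimulationDesign:
    """Design matching the reported study conditions at desk scale.

    DAC affects 10.6% of CpGs with 97.6% of affected sites demethylated;
    cisplatin affects 0.53% with 61% demethylated; per-generation drift
    leaves roughly 1% of probes significant per passage-vs-patient
    comparison; ~9.7% of probes are mouse cross-reactive.
    """
    return SimulationDesign(n_probes=n_probes, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset (for recovery tests)."""

    probe_state: pd.Series
    latent_beta: pd.Series
    mouse_probes: pd.Index
    dac_delta_m: pd.Series  # 0 where unaffected, signed shift otherwise
    cisplatin_delta_m: pd.Series
    invitro_delta_m: pd.Series
    drift: pd.DataFrame  # columns: model, generation, probe_id, delta_m
    model_shift: pd.DataFrame  # columns: model, probe_id, delta_m

    @property
    def dac_affected(self) -> pd.Index:
        return self.dac_delta_m.index[self.dac_delta_m != 0]

    @property
    def dac_down(self) -> pd.Index:
        return self.dac_delta_m.index[self.dac_delta_m < 0]

    @property
    def cisplatin_affected(self) -> pd.Index:
        return self.cisplatin_delta_m.index[self.cisplatin_delta_m != 0]

    @property
    def invitro_down(self) -> pd.Index:
        return self.invitro_delta_m.index[self.invitro_delta_m < 0]

    def drifting_probes(self, model: str | None = None) -> pd.Index:
        df = self.drift
        if model is not None:
            df = df[df["model"] == model]
        return pd.Index(df["probe_id"].unique())


@dataclass
class SimulatedDataset:
    intensities: IntensityData
    beta: pd.DataFrame
    manifest: ProbeManifest
    samples: SampleSheet
    truth: GroundTruth
    design: SimulationDesign


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])


def _logit2(beta: np.ndarray) -> np.ndarray:
    b = np.clip(beta, 1e-6, 1 - 1e-6)
    return np.log2(b / (1 - b))


def _expit2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-m))


def _signed_shifts(
    rng: np.random.Generator, probes: pd.Index, n: int, magnitude: float,
    down_fraction: float, weights: np.ndarray | None = None,
) -> pd.Series:
    """Draw n affected probes and a signed M-shift for each."""
    out = pd.Series(0.0, index=probes)
    if n == 0:
        return out
    p = None if weights is None else weights / weights.sum()
    chosen = rng.choice(len(probes), size=n, replace=False, p=p)
    mags = magnitude * rng.uniform(0.8, 1.2, size=n)
    n_down = int(round(down_fraction * n))
    signs = np.ones(n)
    signs[rng.permutation(n)[:n_down]] = -1.0
    out.iloc[chosen] = signs * mags
    return out


def _make_manifest(design: SimulationDesign, rng: np.random.Generator) -> ProbeManifest:
    n = design.n_probes
    probes = pd.Index([f"cg{i:08d}" for i in range(1, n + 1)], name="probe_id")
    autosomes = [str(i) for i in range(1, 23)]
    chrom_w = np.array([1.0 / (1 + 0.08 * i) for i in range(22)])
    chrom_p = np.concatenate([chrom_w / chrom_w.sum() * 0.965, [0.030, 0.005]])
    chroms = rng.choice(autosomes + ["X", "Y"], size=n, p=chrom_p)
    positions = rng.integers(1, 200_000_000, size=n)
    design_type = np.where(rng.random(n) < design.fraction_type_ii, "II", "I")
    compartment = rng.choice(
        ["TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic"],
        size=n,
        p=[0.14, 0.12, 0.09, 0.07, 0.31, 0.04, 0.23],
    )
    cgi = rng.choice(["Island", "Shore", "Shelf", "OpenSea"], size=n, p=[0.31, 0.23, 0.10, 0.36])
    # HIL class loosely tracks CGI relation: islands are mostly high-density
    hil = np.empty(n, dtype=object)
    for rel, probs in {
        "Island": (0.8, 0.15, 0.05),
        "Shore": (0.15, 0.6, 0.25),
        "Shelf": (0.02, 0.28, 0.7),
        "OpenSea": (0.01, 0.09, 0.9),
    }.items():
        mask = cgi == rel
        hil[mask] = rng.choice(["HC", "IC", "LC"], size=mask.sum(), p=probs)
    n_genes = max(50, n // 12)
    pool = np.array([f"GENE{i:05d}" for i in range(1, n_genes + 1)])
    genes = np.empty(n, dtype=object)
    for i in range(n):
        if compartment[i] == "Intergenic" or rng.random() < 0.05:
            genes[i] = ""
        elif rng.random() < 0.05:
            g = rng.choice(n_genes, size=2, replace=False)
            genes[i] = ";".join(pool[g])
        else:
            genes[i] = pool[rng.integers(n_genes)]
    df = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "design_type": design_type,
            "compartment": compartment,
            "cgi_relation": cgi,
            "hil_class": hil,
            "genes": genes,
            "snp_flag": rng.random(n) < 0.015,
            "crosshyb_flag": rng.random(n) < 0.02,
        },
        index=probes,
    )
    return ProbeManifest(df)


def _make_samples(design: SimulationDesign) -> SampleSheet:
    rows = []
    batches = list(design.batch_effects)

    def add(sample_id, model, generation, treatment, species="human"):
        batch = batches[len(rows) % len(batches)]
        rows.append((sample_id, model, generation, treatment, batch, species))

    for model in design.models:
        for gen in design.generations:
            for r in range(1, design.replicates + 1):
                add(f"{model}_{gen}_r{r}", model, gen, "none")
    for trt in ("vehicle", "DAC", "cisplatin"):
        for r in range(1, design.replicates + 1):
            add(f"{design.treated_model}_F3_{trt}_r{r}", design.treated_model, "F3", trt)
    if design.include_invitro:
        for trt in ("none", "DAC"):
            for r in range(1, design.replicates + 1):
                add(f"SKOV3_{trt}_r{r}", "SKOV3", "NA", trt)
    add("mouse_tail", "mouse", "NA", "none", species="mouse")
    df = pd.DataFrame(
        rows, columns=["sample_id", "model", "generation", "treatment", "batch", "species"]
    )
    return SampleSheet(df)


def simulate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Generate one full synthetic dataset with its ground truth.

    Identical design + seed yields bit-identical output.
    """
    if design.n_probes < 100:
        raise ValueError("n_probes must be >= 100 (mixture fitting downstream)")
    probe_rng = np.random.default_rng([design.seed & 0x7FFFFFFF, 0xA11CE])
    manifest = _make_manifest(design, probe_rng)
    samples = _make_samples(design)
    probes = manifest.probe_ids
    n = design.n_probes

    # latent methylation state and baseline beta
    state_idx = probe_rng.choice(3, size=n, p=np.asarray(design.state_proportions))
    latent = np.empty(n)
    for k, (a, b) in enumerate(design.state_beta_params):
        mask = state_idx == k
        latent[mask] = probe_rng.beta(a, b, size=mask.sum())
    probe_state = pd.Series(np.array(STATES)[state_idx], index=probes, name="state")
    latent_beta = pd.Series(latent, index=probes, name="latent_beta")
    base_m = _logit2(latent)

    # planted structure
    mouse_n = int(round(design.mouse_crossreactive_fraction * n))
    mouse_probes = pd.Index(
        probes[probe_rng.choice(n, size=mouse_n, replace=False)]
    ).sort_values()

    hms_weights = np.where(probe_state.values == "HMS", 8.0, 1.0)
    dac = design.dac_effect
    dac_delta = _signed_shifts(
        probe_rng, probes, int(round(dac.fraction_affected * n)), abs(dac.delta_m),
        dac.down_fraction, hms_weights if dac.target_state == "HMS" else None,
    )
    cis = design.cisplatin_effect
    cis_delta = _signed_shifts(
        probe_rng, probes, int(round(cis.fraction_affected * n)), abs(cis.delta_m),
        cis.down_fraction, None,
    )
    # in-vitro DAC-sensitive set: contains every in-vivo DAC target, plus
    # extra sites up to the cell line's larger affected fraction
    invitro_delta = dac_delta.copy()
    n_extra = int(round(design.invitro_fraction_affected * n)) - int((dac_delta != 0).sum())
    if design.include_invitro and n_extra > 0:
        unaffected = np.flatnonzero(dac_delta.values == 0)
        extra = probe_rng.choice(unaffected, size=n_extra, replace=False)
        mags = abs(dac.delta_m) * probe_rng.uniform(0.8, 1.2, size=n_extra)
        signs = np.where(probe_rng.random(n_extra) < dac.down_fraction, -1.0, 1.0)
        invitro_delta.iloc[extra] = signs * mags

    drift_rows = []
    n_drift = int(round(design.drift_fraction * n))
    for model in design.models:
        for gen in design.generations[1:]:
            chosen = probe_rng.choice(n, size=n_drift, replace=False)
            signs = np.where(probe_rng.random(n_drift) < 0.5, -1.0, 1.0)
            mags = design.drift_delta_m * probe_rng.uniform(0.8, 1.2, size=n_drift)
            for i, idx in enumerate(chosen):
                drift_rows.append((model, gen, probes[idx], signs[i] * mags[i]))
    drift = pd.DataFrame(drift_rows, columns=["model", "generation", "probe_id", "delta_m"])

    shift_rows = []
    n_shift = int(round(design.model_shift_fraction * n))
    shift_models = list(design.models) + (["SKOV3"] if design.include_invitro else [])
    for model in shift_models:
        chosen = probe_rng.choice(n, size=n_shift, replace=False)
        signs = np.where(probe_rng.random(n_shift) < 0.5, -1.0, 1.0)
        mags = design.model_shift_delta_m * probe_rng.uniform(0.8, 1.2, size=n_shift)
        for i, idx in enumerate(chosen):
            shift_rows.append((model, probes[idx], signs[i] * mags[i]))
    model_shift = pd.DataFrame(shift_rows, columns=["model", "probe_id", "delta_m"])

    truth = GroundTruth(
        probe_state=probe_state,
        latent_beta=latent_beta,
        mouse_probes=mouse_probes,
        dac_delta_m=dac_delta,
        cisplatin_delta_m=cis_delta,
        invitro_delta_m=invitro_delta,
        drift=drift,
        model_shift=model_shift,
    )

    # fast lookups for per-sample assembly
    probe_pos = pd.Series(np.arange(n), index=probes)
    drift_map: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (model, gen), grp in drift.groupby(["model", "generation"]):
        drift_map[(model, gen)] = (probe_pos[grp["probe_id"]].values, grp["delta_m"].values)
    shift_map: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for model, grp in model_shift.groupby("model"):
        shift_map[model] = (probe_pos[grp["probe_id"]].values, grp["delta_m"].values)

    type_ii = (manifest.df["design_type"] == "II").values
    mouse_mask_arr = probes.isin(mouse_probes)

    meth = {}
    unmeth = {}
    detp = {}
    beta_out = {}
    for sample_id, row in samples.df.iterrows():
        rng = _sample_rng(design.seed, sample_id)
        if row["species"] == "mouse":
            # mouse tail: no human signal; detectable only at cross-reactive probes
            b = rng.uniform(0.05, 0.95, size=n)
            p = np.where(
                mouse_mask_arr, rng.uniform(0.0, 0.005, size=n), rng.uniform(0.05, 1.0, size=n)
            )
        else:
            m = base_m.copy()
            model = row["model"]
            if model in shift_map:
                pos, delta = shift_map[model]
                m[pos] = m[pos] + delta
            key = (model, row["generation"])
            if key in drift_map:
                pos, delta = drift_map[key]
                m[pos] = m[pos] + delta
            if row["treatment"] == "DAC":
                eff = invitro_delta.values if model == "SKOV3" else dac_delta.values
                m = m + eff
            elif row["treatment"] == "cisplatin":
                m = m + cis_delta.values
            m = m + rng.normal(0.0, design.noise_sd, size=n)
            m = np.where(type_ii, m * design.type_ii_compression, m)
            be = design.batch_effects[row["batch"]]
            m = m * be.scale + be.shift
            b = _expit2(m)
            fail = rng.random(n) < design.detection_noise
            p = np.where(fail, rng.uniform(0.05, 1.0, size=n), rng.uniform(0.0, 0.005, size=n))
        # intensities: choose total so that M/(M+U+100) equals b exactly
        total = rng.gamma(20.0, design.intensity_scale / 20.0, size=n)
        total = np.maximum(total, 100.0 / np.maximum(1.0 - b, 1e-6) + 1.0)
        meth[sample_id] = b * total
        unmeth[sample_id] = total * (1.0 - b) - 100.0
        detp[sample_id] = p
        beta_out[sample_id] = b

    sample_ids = samples.sample_ids
    intensities = IntensityData(
        pd.DataFrame(meth, index=probes)[sample_ids],
        pd.DataFrame(unmeth, index=probes)[sample_ids],
        pd.DataFrame(detp, index=probes)[sample_ids],
    )
    beta = pd.DataFrame(beta_out, index=probes)[sample_ids]
    return SimulatedDataset(intensities, beta, manifest, samples, truth, design)


def design_to_dict(design: SimulationDesign) -> dict:
    """Plain-dict mirror of a design (YAML/JSON serializable)."""
    return asdict(design)


def design_to_yaml(design: SimulationDesign, path) -> None:
    """Write a design as YAML (lists stand in for tuples)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def design_from_yaml(path) -> SimulationDesign:
    """Reconstruct a design (including nested effect objects) from YAML."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["state_proportions"] = tuple(raw["state_proportions"])
    raw["state_beta_params"] = tuple(tuple(p) for p in raw["state_beta_params"])
    raw["models"] = tuple(raw["models"])
    raw["generations"] = tuple(raw["generations"])
    raw["batch_effects"] = {k: BatchEffect(**v) for k, v in raw["batch_effects"].items()}
    raw["dac_effect"] = TreatmentEffect(**raw["dac_effect"])
    raw["cisplatin_effect"] = TreatmentEffect(**raw["cisplatin_effect"])
    return SimulationDesign(**raw)
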