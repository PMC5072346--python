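"""Filtering cascade and value transforms for 450K-style intensity data.

The cascade turns raw two-channel intensities into an analysis-ready
beta/M matrix: detection-p filtering over human samples, exclusion of
sex-chromosome / SNP / cross-hybridizing probes, masking of probes
detectable in a mouse host-control sample, beta computation with the
standard +100 offset, and the logit2 beta<->M transform pair.  Every
removal is recorded in a :class:`FilterReport` so the cascade is
auditable and replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manifest_io import IntensityData, ProbeManifest, SampleSheet

BETA_CLAMP = 1e-6  # keeps the logit finite without materially moving data


@dataclass
class FilterReport:
    """Per-stage accounting of probe removals, in application order."""

    input_probes: int
    stages: list[tuple[str, int]] = field(default_factory=list)
    retained: int = 0

    def add_stage(self, name: str, removed: int) -> None:
        self.stages.append((name, removed))

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.stages)

    def validate(self) -> None:
        if self.retained + self.total_removed != self.input_probes:
            raise AssertionError(
                f"filter accounting broken: {self.retained} retained + "
                f"{self.total_removed} removed != {self.input_probes} input"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, n) for s, n in self.stages]
        rows.append(("retained", self.retained))
        return pd.DataFrame(rows, columns=["stage", "probes"])

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Chain this report with one computed on this report's output."""
        if other.input_probes != self.retained:
            raise ValueError("reports do not chain: probe counts disagree")
        merged = FilterReport(self.input_probes, list(self.stages) + list(other.stages))
        merged.retained = other.retained
        merged.validate()
        return merged


def compute_beta(meth, unmeth, offset: float = 100.0):
    """Methylation fraction beta = M / (M + U + offset).

    Accepts scalars, arrays or aligned DataFrames; the +100 offset
    regularizes probes where both channels are dim.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    m = np.asarray(meth, dtype=float) if not isinstance(meth, pd.DataFrame) else meth
    u = np.asarray(unmeth, dtype=float) if not isinstance(unmeth, pd.DataFrame) else unmeth
    if (np.asarray(m) < 0).any() or (np.asarray(u) < 0).any():
        raise ValueError("intensities must be non-negative")
    return m / (m + u + offset)


def detection_filter(
    data: IntensityData,
    samples: SampleSheet | None = None,
    threshold: float = 0.01,
    scope: str = "any_sample",
) -> tuple[IntensityData, FilterReport]:
    """Drop probes that fail detection (p >= threshold) in human samples.

    scope="any_sample" (default) removes a probe failing in at least one
    human sample; scope="all_samples" only when it fails in every one.
    """
    if not 0 < threshold < 1:
        raise ValueError("detection threshold must lie in (0, 1)")
    if scope not in ("any_sample", "all_samples"):
        raise ValueError(f"unknown scope {scope!r}")
    cols = data.sample_ids if samples is None else data.meth.columns.intersection(
        samples.human_samples
    )
    fails = data.detection_p[cols].values >= threshold
    drop = fails.any(axis=1) if scope == "any_sample" else fails.all(axis=1)
    report = FilterReport(len(data.probe_ids))
    report.add_stage("detection", int(drop.sum()))
    keep = data.probe_ids[~drop]
    report.retained = len(keep)
    report.validate()
    return data.subset_probes(keep), report


def exclude_probes(
    data: IntensityData,
    manifest: ProbeManifest,
    drop_sex: bool = True,
    drop_snp: bool = True,
    drop_crosshyb: bool = True,
) -> tuple[IntensityData, FilterReport]:
    """Remove annotation-flagged probes in the fixed order sex -> SNP -> cross-hyb.

    A probe matching several criteria is counted once, at the first
    matching stage.
    """
    missing = data.probe_ids.difference(manifest.df.index)
    if len(missing):
        raise ValueError(f"manifest does not cover probes: {missing.tolist()[:5]}")
    ann = manifest.df.loc[data.probe_ids]
    report = FilterReport(len(data.probe_ids))
    removed = pd.Series(False, index=data.probe_ids)
    for name, active, mask in (
        ("sex_chromosomes", drop_sex, ann["chromosome"].isin(["X", "Y"])),
        ("snp", drop_snp, ann["snp_flag"]),
        ("crosshyb", drop_crosshyb, ann["crosshyb_flag"]),
    ):
        if not active:
            continue
        new = mask & ~removed
        report.add_stage(name, int(new.sum()))
        removed |= new
    keep = data.probe_ids[~removed]
    report.retained = len(keep)
    report.validate()
    return data.subset_probes(keep), report


def mouse_mask(
    data: IntensityData, samples: SampleSheet, threshold: float = 0.01
) -> tuple[IntensityData, FilterReport]:
    """Remove probes detectable (p < threshold) in the mouse control sample.

    Probes with a confident signal in mouse tail DNA are cross-reactive
    with the host genome and would contaminate xenograft methylation
    calls.  The mouse sample itself is dropped from the matrices.
    """
    mouse = [s for s in samples.mouse_samples if s in data.sample_ids]
    if len(mouse) != 1:
        raise ValueError(f"expected exactly one mouse sample in the data, found {len(mouse)}")
    detectable = data.detection_p[mouse[0]] < threshold
    report = FilterReport(len(data.probe_ids))
    report.add_stage("mouse_detected", int(detectable.sum()))
    keep = data.probe_ids[~detectable]
    report.retained = len(keep)
    report.validate()
    return data.subset_probes(keep).drop_samples(mouse), report


def beta_to_m(beta):
    """logit2 transform m = log2(beta / (1 - beta)), clamped at 1e-6."""
    arr = np.clip(np.asarray(beta, dtype=float), BETA_CLAMP, 1 - BETA_CLAMP)
    m = np.log2(arr / (1 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2^m / (2^m + 1)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index, name=m.name)
    return b
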