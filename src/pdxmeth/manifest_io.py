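"""Data model and text-format I/O for the methylome pipeline.

Every other module consumes the containers defined here: the probe
manifest (static per-probe annotation of an Infinium-450K-style array),
the sample sheet describing xenograft models, passages and treatment
arms, intensity and beta-value matrices, GMT gene-set collections and
survival tables.

Conventions enforced throughout:

* probe/sample identifiers are unique;
* genomic positions are 1-based in the manifest, 0-based half-open in
  exported BED;
* chromosome labels carry no ``chr`` prefix internally (BED writers add
  it);
* missing beta entries are written as the literal ``NA``;
* multi-gene probes store semicolon-delimited symbols that are split and
  de-duplicated (order preserved) on access.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
DESIGN_TYPES = ("I", "II")
COMPARTMENTS = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic")
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
HIL_CLASSES = ("HC", "IC", "LC")
GENERATIONS = ("F0", "F1", "F2", "F3", "NA")
TREATMENTS = ("none", "vehicle", "DAC", "cisplatin", "carboplatin")
SPECIES = ("human", "mouse")

MANIFEST_COLUMNS = (
    "chromosome",
    "position",
    "design_type",
    "compartment",
    "cgi_relation",
    "hil_class",
    "genes",
    "snp_flag",
    "crosshyb_flag",
)
SAMPLE_COLUMNS = ("model", "generation", "treatment", "batch", "species")


class SchemaError(ValueError):
    """A required column is missing or a table is structurally malformed."""


class DataValidationError(ValueError):
    """A value violates the closed vocabulary or an invariant of its type."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _check_enum(series: pd.Series, allowed: Sequence[str], what: str) -> None:
    bad = ~series.astype(str).isin(allowed)
    if bad.any():
        offenders = series[bad]
        first = offenders.index[0]
        raise DataValidationError(
            f"unknown {what} label {offenders.iloc[0]!r} at row {first!r} "
            f"(allowed: {', '.join(allowed)})"
        )


def split_genes(cell: object) -> list[str]:
    """Split a semicolon-delimited gene cell, de-duplicating but keeping order."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    seen: dict[str, None] = {}
    for g in str(cell).split(";"):
        g = g.strip()
        if g:
            seen.setdefault(g, None)
    return list(seen)


class ProbeManifest:
    """Validated per-probe annotation table, indexed by probe id."""

    def __init__(self, df: pd.DataFrame):
        _require_columns(df, MANIFEST_COLUMNS, "probe manifest")
        if df.index.name != "probe_id":
            if "probe_id" not in df.columns:
                raise SchemaError("probe manifest is missing required column(s): probe_id")
            df = df.set_index("probe_id")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise DataValidationError(f"duplicate probe_id(s) in manifest: {dups}")
        df = df.copy()
        df["chromosome"] = df["chromosome"].astype(str)
        _check_enum(df["chromosome"], CHROMOSOMES, "chromosome")
        df["position"] = df["position"].astype(int)
        if (df["position"] < 1).any():
            raise DataValidationError("manifest positions must be >= 1 (1-based)")
        _check_enum(df["design_type"], DESIGN_TYPES, "design_type")
        _check_enum(df["compartment"], COMPARTMENTS, "compartment")
        _check_enum(df["cgi_relation"], CGI_RELATIONS, "cgi_relation")
        _check_enum(df["hil_class"], HIL_CLASSES, "hil_class")
        df["genes"] = df["genes"].fillna("").astype(str)
        df["snp_flag"] = df["snp_flag"].astype(bool)
        df["crosshyb_flag"] = df["crosshyb_flag"].astype(bool)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def genes_of(self, probe_id: str) -> list[str]:
        return split_genes(self.df.at[probe_id, "genes"])

    def gene_lists(self) -> pd.Series:
        """Series of gene-symbol lists, one per probe (possibly empty)."""
        return self.df["genes"].map(split_genes)

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.df.index)
        if len(missing):
            raise DataValidationError(f"probes absent from manifest: {missing.tolist()[:5]}")
        return ProbeManifest(self.df.loc[idx])


class SampleSheet:
    """Validated sample annotation (model, passage, treatment, batch, species)."""

    def __init__(self, df: pd.DataFrame):
        _require_columns(df, SAMPLE_COLUMNS, "sample sheet")
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise SchemaError("sample sheet is missing required column(s): sample_id")
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise DataValidationError(f"duplicate sample_id(s): {dups}")
        df = df.copy()
        _check_enum(df["generation"], GENERATIONS, "generation")
        _check_enum(df["treatment"], TREATMENTS, "treatment")
        _check_enum(df["species"], SPECIES, "species")
        mouse = df["species"] == "mouse"
        if mouse.any():
            bad = mouse & ((df["treatment"] != "none") | (df["generation"] != "NA"))
            if bad.any():
                raise DataValidationError(
                    "mouse samples must have treatment='none' and generation='NA': "
                    f"{df.index[bad].tolist()}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def human_samples(self) -> pd.Index:
        return self.df.index[self.df["species"] == "human"]

    @property
    def mouse_samples(self) -> pd.Index:
        return self.df.index[self.df["species"] == "mouse"]

    def select(self, **conditions) -> pd.Index:
        """Sample ids matching all given column=value conditions."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in conditions.items():
            mask &= self.df[col] == val
        return self.df.index[mask]


@dataclass
class IntensityData:
    """Methylated/unmethylated channel intensities with detection p-values.

    All three frames are probes x samples with identical labels.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame in (("unmeth", self.unmeth), ("detection_p", self.detection_p)):
            if not frame.index.equals(self.meth.index) or not frame.columns.equals(
                self.meth.columns
            ):
                raise DataValidationError(f"intensity frame {name!r} labels do not match meth")
        if (self.meth.values < 0).any() or (self.unmeth.values < 0).any():
            raise DataValidationError("channel intensities must be non-negative")

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    def subset_probes(self, probe_ids: pd.Index) -> "IntensityData":
        return IntensityData(
            self.meth.loc[probe_ids], self.unmeth.loc[probe_ids], self.detection_p.loc[probe_ids]
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "IntensityData":
        cols = self.meth.columns.difference(pd.Index(sample_ids), sort=False)
        return IntensityData(self.meth[cols], self.unmeth[cols], self.detection_p[cols])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with an optional explicit background."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> ProbeManifest:
    return ProbeManifest(pd.read_csv(path, dtype={"chromosome": str}))


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, index_label="probe_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype=str))


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> None:
    samples.df.to_csv(path, index_label="sample_id")


def read_beta(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta matrix; 'NA' cells become NaN."""
    beta = pd.read_csv(path, index_col=0, na_values=["NA"])
    vals = beta.values
    finite = vals[np.isfinite(vals)]
    if len(finite) and (finite.min() < 0 or finite.max() > 1):
        raise DataValidationError("beta values must lie in [0, 1]")
    return beta


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, na_rep="NA", float_format="%.6f", index_label="probe_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an unconstrained probes x samples matrix (M-values, intensities)."""
    return pd.read_csv(path, index_col=0, na_values=["NA"])


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, na_rep="NA", float_format="%.6f", index_label="probe_id")


def read_intensities(
    meth_path: str | Path, unmeth_path: str | Path, detp_path: str | Path
) -> IntensityData:
    return IntensityData(
        read_matrix(meth_path), read_matrix(unmeth_path), read_matrix(detp_path)
    )


def write_intensities(
    data: IntensityData, meth_path: str | Path, unmeth_path: str | Path, detp_path: str | Path
) -> None:
    write_matrix(data.meth, meth_path)
    write_matrix(data.unmeth, unmeth_path)
    write_matrix(data.detection_p, detp_path)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB members..."""
    sets: dict[str, list[str]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataValidationError(
                    f"GMT line {lineno} has no members (need name, description, genes)"
                )
            name = parts[0]
            if name in sets:
                raise DataValidationError(f"duplicate gene-set name {name!r} at line {lineno}")
            seen: dict[str, None] = {}
            for g in parts[2:]:
                g = g.strip()
                if g:
                    seen.setdefault(g, None)
            if not seen:
                raise DataValidationError(f"gene set {name!r} at line {lineno} is empty")
            sets[name] = list(seen)
    if n_lines == 0:
        logger.warning("GMT file %s is empty; returning an empty collection", path)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival table with columns id, time, event, marker."""
    df = pd.read_csv(path)
    _require_columns(df, ("id", "time", "event", "marker"), "survival table")
    if df["id"].duplicated().any():
        raise DataValidationError("duplicate subject ids in survival table")
    if (df["time"] < 0).any():
        raise DataValidationError("survival times must be non-negative")
    df["event"] = df["event"].astype(int)
    if not df["event"].isin([0, 1]).all():
        raise DataValidationError("event indicator must be 0/1")
    return df


_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


def write_candidate_bed(
    sites: Iterable[str],
    manifest: ProbeManifest,
    path: str | Path,
    delta_beta: Mapping[str, float] | pd.Series | None = None,
) -> None:
    """Export CpG sites as BED (0-based half-open, 1 bp per site).

    The score column carries |delta beta| scaled to 0-1000 (0 when no
    effect sizes are supplied).  Output is sorted by chromosome then
    start; chromosome labels gain the UCSC ``chr`` prefix.
    """
    idx = pd.Index(sites)
    missing = idx.difference(manifest.df.index)
    if len(missing):
        raise DataValidationError(f"probes absent from manifest: {missing.tolist()[:10]}")
    rows = []
    for probe in idx:
        chrom = manifest.df.at[probe, "chromosome"]
        pos = int(manifest.df.at[probe, "position"])
        if delta_beta is not None and probe in delta_beta:
            score = int(round(min(1.0, abs(float(delta_beta[probe]))) * 1000))
        else:
            score = 0
        rows.append((_CHROM_ORDER[chrom], f"chr{chrom}", pos - 1, pos, probe, score))
    rows.sort(key=lambda r: (r[0], r[2]))
    with open(path, "w") as fh:
        fh.write("# candidate CpG sites (BED: 0-based half-open)\n")
        for _, chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")
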