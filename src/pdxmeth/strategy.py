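"""Multi-stage screen for DAC-demethylation-sensitive candidate genes.

The screen intersects three CpG-site sets over a common probe universe:

1. *propagation-stable* sites — never significantly differentially
   methylated in any passage-vs-patient comparison of any xenograft
   model;
2. *in-vivo DAC-demethylated* sites — significantly hypomethylated in
   DAC-treated versus vehicle-treated xenograft tumors;
3. *in-vitro DAC-sensitive* sites — the analogous set from a
   DAC-treated cell line.

Sites surviving all three stages are mapped to gene symbols through the
manifest, and the resulting candidate list is tested for gene-set
enrichment with an upper-tail hypergeometric test and Bonferroni
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import significant_sites
from .manifest_io import GeneSetCollection, ProbeManifest, split_genes

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Stage-by-stage output of the intersection screen.

    Invariant (asserted on construction): final sites are a subset of
    every upstream stage.
    """

    stable_sites: pd.Index
    invivo_dac_sites: pd.Index
    invitro_dac_sites: pd.Index
    stable_and_invivo: pd.Index
    final_sites: pd.Index
    genes: list[str] = field(default_factory=list)
    n_unmapped: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.stable_and_invivo.isin(self.stable_sites).all()
        assert self.stable_and_invivo.isin(self.invivo_dac_sites).all()
        assert self.final_sites.isin(self.stable_and_invivo).all()
        assert self.final_sites.isin(self.invitro_dac_sites).all()
        assert len(self.genes) == len(set(self.genes))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "stable_sites": len(self.stable_sites),
                "invivo_dac_sites": len(self.invivo_dac_sites),
                "invitro_dac_sites": len(self.invitro_dac_sites),
                "stable_and_invivo": len(self.stable_and_invivo),
                "final_sites": len(self.final_sites),
                "genes": len(self.genes),
            }
        )


def stable_sites(
    generation_results: Mapping[object, pd.DataFrame], p_cut: float = 0.01
) -> pd.Index:
    """Probes significant in NO passage-vs-patient contrast of any model.

    ``generation_results`` maps (model, generation) keys to moderated-t
    result frames, all over one common probe universe.
    """
    results = list(generation_results.values())
    if not results:
        raise ValueError("no generation contrasts supplied")
    universe = results[0].index
    unstable = pd.Series(False, index=universe)
    for key, res in generation_results.items():
        if not res.index.sort_values().equals(universe.sort_values()):
            raise ValueError(f"contrast {key!r} covers a different probe universe")
        unstable |= res["p"].reindex(universe) < p_cut
    return universe[~unstable].sort_values()


def dac_demethylated_sites(
    dac_result: pd.DataFrame, p_cut: float = 0.01, q_cut: float | None = 0.10
) -> pd.Index:
    """Significant sites with strictly negative delta beta (demethylated)."""
    sig = significant_sites(dac_result, p_cut=p_cut, q_cut=q_cut)
    return sig.index[sig["delta_beta"] < 0].sort_values()


def intersect_strategy(
    stable: pd.Index,
    invivo: pd.Index,
    invitro: pd.Index,
    manifest: ProbeManifest | None = None,
    provenance: dict | None = None,
) -> CandidateSet:
    """Chain the three screening stages; outputs are lexicographically sorted."""
    stable = pd.Index(stable).sort_values()
    invivo = pd.Index(invivo).sort_values()
    invitro = pd.Index(invitro).sort_values()
    stable_and_invivo = stable.intersection(invivo).sort_values()
    final = stable_and_invivo.intersection(invitro).sort_values()
    genes: list[str] = []
    n_unmapped = 0
    if manifest is not None:
        genes, n_unmapped = map_sites_to_genes(final, manifest)
    return CandidateSet(
        stable_sites=stable,
        invivo_dac_sites=invivo,
        invitro_dac_sites=invitro,
        stable_and_invivo=stable_and_invivo,
        final_sites=final,
        genes=genes,
        n_unmapped=n_unmapped,
        provenance=provenance or {},
    )


def map_sites_to_genes(sites: pd.Index, manifest: ProbeManifest) -> tuple[list[str], int]:
    """Union of manifest gene symbols over sites (ordered, de-duplicated).

    Returns the gene list and the count of sites contributing no symbol
    (intergenic / unannotated).
    """
    idx = pd.Index(sites)
    missing = idx.difference(manifest.df.index)
    if len(missing):
        raise ValueError(f"sites absent from manifest: {missing.tolist()[:5]}")
    genes: dict[str, None] = {}
    n_unmapped = 0
    for probe in idx:
        symbols = split_genes(manifest.df.at[probe, "genes"])
        if not symbols:
            n_unmapped += 1
        for g in symbols:
            genes.setdefault(g, None)
    return list(genes), n_unmapped


def enrich(
    genes: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    alpha: float = 0.001,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a candidate list.

    P[X >= overlap] when drawing ``len(genes)`` from ``len(universe)``
    genes of which ``len(set)`` are successes; Bonferroni-adjusted over
    the sets actually tested (those with overlap >= min_overlap).
    Candidate genes outside the universe are dropped with a warning; gene
    sets are intersected with the universe.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    candidates = [g for g in dict.fromkeys(genes) if g in universe_set]
    dropped = len(set(genes)) - len(candidates)
    if dropped:
        logger.warning("%d candidate gene(s) outside the universe were dropped", dropped)
    n_universe = len(universe_set)
    n_list = len(candidates)
    cand_set = set(candidates)
    rows = []
    for name, members in collection.sets.items():
        in_universe = [g for g in members if g in universe_set]
        overlap_genes = sorted(cand_set & set(in_universe))
        k = len(overlap_genes)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(in_universe), n_list))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(in_universe),
                "list_size": n_list,
                "universe_size": n_universe,
                "p": p,
                "overlap_genes": ";".join(overlap_genes),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap",
            "set_size",
            "list_size",
            "universe_size",
            "p",
            "overlap_genes",
        ],
    )
    n_tested = len(result)
    result["p_bonferroni"] = np.minimum(1.0, result["p"] * n_tested)
    result["significant"] = result["p_bonferroni"] < alpha
    return result.sort_values("p_bonferroni", kind="stable").reset_index(drop=True)
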