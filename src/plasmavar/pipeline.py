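"""End-to-end glue: BAM + reference + trained model -> site read data -> calls."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    OBSERVATION_COLUMNS,
    ReadFilter,
    build_observations,
    iter_alignments,
)
from .calling import (
    CallResult,
    CandidateSite,
    SiteReadData,
    call_cancer,
    call_variant,
)
from .model import ErrorModelArtifact, predict_error_rates


def extract_site_observations(
    bam_path: str | Path,
    reference: Mapping[str, str],
    sites: Sequence[CandidateSite],
    read_filter: ReadFilter | None = None,
    sample: str = "",
) -> pd.DataFrame:
    """One observation per read covering each candidate site (match or not)."""
    targets = {(s.chrom, s.pos): (s.ref_allele, s.alt_allele) for s in sites}
    rows = []
    for rec in iter_alignments(str(bam_path)):
        for obs in build_observations(rec, reference, target_sites=targets,
                                      read_filter=read_filter, sample=sample):
            rows.append(obs.as_row())
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def site_read_data(obs: pd.DataFrame, site: CandidateSite,
                   artifact: ErrorModelArtifact) -> SiteReadData:
    """Filter one site's observations to {R, M} and attach error-rate pairs."""
    df = obs[(obs["chrom"] == site.chrom)
             & (obs["genomic_pos"] == site.pos)
             & obs["obs_allele"].isin([site.ref_allele, site.alt_allele])]
    df = df.reset_index(drop=True)
    if len(df) == 0:
        return SiteReadData(site=site, is_alt=np.empty(0, bool),
                            e_rm=np.empty(0), e_mr=np.empty(0))
    e_rm, e_mr = predict_error_rates(artifact, df, site.ref_allele,
                                     site.alt_allele)
    return SiteReadData(site=site,
                        is_alt=(df["obs_allele"] == site.alt_allele).to_numpy(),
                        e_rm=e_rm, e_mr=e_mr)


def prepare_catalog_data(
    bam_path: str | Path,
    reference: Mapping[str, str],
    catalog: Sequence[CandidateSite],
    artifact: ErrorModelArtifact,
    read_filter: ReadFilter | None = None,
) -> list[SiteReadData]:
    obs = extract_site_observations(bam_path, reference, catalog, read_filter)
    return [site_read_data(obs, s, artifact) for s in catalog]


def call_variants_in_bam(bam_path, reference, catalog, artifact,
                         read_filter: ReadFilter | None = None
                         ) -> list[tuple[CandidateSite, CallResult]]:
    """Single-site variant calls (r = 1, 1 df) for every catalog site."""
    data = prepare_catalog_data(bam_path, reference, catalog, artifact,
                                read_filter)
    return [(d.site, call_variant(d)) for d in data]


def call_cancer_in_bam(bam_path, reference, catalog, artifact,
                       read_filter: ReadFilter | None = None) -> CallResult:
    """Catalog-aggregated cancer call (joint f, r estimate; 2 df LRT)."""
    data = prepare_catalog_data(bam_path, reference, catalog, artifact,
                                read_filter)
    return call_cancer(data)
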