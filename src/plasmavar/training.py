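"""Assemble the error-model training table.

Training data are all read-alignment mismatches (outside germline variants
and the patient's mutation catalog) plus a downsampled random subset of
reference-matching read positions.  The match sampling fraction beta is
recorded so predicted probabilities can be rescaled back to the unsampled
distribution at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    NUCLEOTIDES,
    OBSERVATION_COLUMNS,
    AlignedReadRecord,
    ReadFilter,
    aligned_query_offsets,
    build_observations,
    iter_alignments,
    map_query_to_reference,
    parse_md_mismatches,
)


@dataclass
class TrainingTable:
    """Observations plus the bookkeeping needed for probability rescaling."""

    df: pd.DataFrame
    match_sampling_fraction: float  # beta
    n_mismatches: int
    n_matches: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.match_sampling_fraction <= 1:
            raise ValueError("match sampling fraction must be in (0, 1]")
        bad = ~self.df["obs_allele"].isin(NUCLEOTIDES)
        if bad.any():
            raise ValueError("observed alleles outside {A,C,G,T} in table")

    @property
    def beta(self) -> float:
        return self.match_sampling_fraction

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        sidecar = {"match_sampling_fraction": self.match_sampling_fraction,
                   "n_mismatches": self.n_mismatches,
                   "n_matches": self.n_matches,
                   "provenance": self.provenance}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainingTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(df=df, match_sampling_fraction=meta["match_sampling_fraction"],
                   n_mismatches=meta["n_mismatches"], n_matches=meta["n_matches"],
                   provenance=meta.get("provenance", {}))


def _records(bam_paths: Sequence[str]) -> Iterable[tuple[str, AlignedReadRecord]]:
    for path in bam_paths:
        sample = Path(path).stem
        for rec in iter_alignments(path):
            yield sample, rec


def collect_training_observations(
    bam_paths: Sequence[str],
    reference: Mapping[str, str],
    exclusions: set | frozenset = frozenset(),
    read_filter: ReadFilter | None = None,
) -> pd.DataFrame:
    """All MD-tag mismatches across samples, minus excluded positions.

    ``exclusions`` holds ``(chrom, pos)`` pairs from the germline VCF and the
    patient mutation catalogs.
    """
    rows = []
    for sample, rec in _records(bam_paths):
        for obs in build_observations(rec, reference, exclusions=exclusions,
                                      read_filter=read_filter, sample=sample):
            rows.append(obs.as_row())
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def sample_match_observations(
    bam_paths: Sequence[str],
    reference: Mapping[str, str],
    beta: float | None = None,
    target_count: int | None = None,
    seed: int = 0,
    exclusions: set | frozenset = frozenset(),
    read_filter: ReadFilter | None = None,
) -> tuple[pd.DataFrame, float]:
    """Uniform random subset of reference-matching read positions.

    Exactly one of ``beta`` (per-position keep probability) or
    ``target_count`` must be given; returns the table and the realised
    sampling fraction.
    """
    if (beta is None) == (target_count is None):
        raise ValueError("give exactly one of beta or target_count")
    if beta is not None and not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    rf = read_filter or ReadFilter()
    rng = np.random.default_rng(seed)

    def match_positions(rec: AlignedReadRecord):
        mismatch_q = {q for q, _, _ in parse_md_mismatches(rec)}
        for q in aligned_query_offsets(rec.cigar):
            if q in mismatch_q:
                continue
            gpos = map_query_to_reference(rec.cigar, rec.pos, q)
            if gpos is None or (rec.chrom, gpos) in exclusions:
                continue
            yield q, gpos

    candidates: list[tuple[str, AlignedReadRecord, int, int]] = []
    n_candidates = 0
    for sample, rec in _records(bam_paths):
        if not rf.passes(rec):
            continue
        for q, gpos in match_positions(rec):
            n_candidates += 1
            candidates.append((sample, rec, q, gpos))
    if target_count is not None:
        keep_p = min(1.0, target_count / n_candidates) if n_candidates else 1.0
    else:
        keep_p = beta
    keep = rng.random(n_candidates) < keep_p

    # group kept positions by read so each read is walked once
    by_read: dict[int, tuple[str, AlignedReadRecord, dict]] = {}
    for (sample, rec, q, gpos), k in zip(candidates, keep):
        if not k:
            continue
        entry = by_read.setdefault(id(rec), (sample, rec, {}))
        entry[2][(rec.chrom, gpos)] = (rec.seq[q].upper(), "N")
    rows = []
    for sample, rec, targets in by_read.values():
        for obs in build_observations(rec, reference, target_sites=targets,
                                      read_filter=rf, sample=sample):
            rows.append(obs.as_row())
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    realised = len(df) / n_candidates if n_candidates else keep_p
    return df, float(realised if beta is None else beta)


def assemble_training_table(
    mismatches: pd.DataFrame,
    matches: pd.DataFrame,
    beta: float,
    seed: int = 0,
    provenance: dict | None = None,
) -> TrainingTable:
    """Concatenate, seeded-shuffle and wrap as a TrainingTable."""
    if list(mismatches.columns) != list(matches.columns):
        raise ValueError("mismatch and match tables have different schemas")
    df = pd.concat([mismatches, matches], ignore_index=True)
    df = df[df["obs_allele"].isin(NUCLEOTIDES)].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return TrainingTable(
        df=df, match_sampling_fraction=beta,
        n_mismatches=int((df["obs_allele"] != df["ref_allele"]).sum()),
        n_matches=int((df["obs_allele"] == df["ref_allele"]).sum()),
        provenance={"seed": seed, **(provenance or {})},
    )


def build_training_table(
    bam_paths: Sequence[str],
    reference: Mapping[str, str],
    exclusions: set | frozenset = frozenset(),
    beta: float | None = None,
    match_mismatch_ratio: float = 10.0,
    seed: int = 0,
    read_filter: ReadFilter | None = None,
) -> TrainingTable:
    """One-call pipeline: harvest mismatches, sample matches, assemble.

    When ``beta`` is not given, matches are sampled to roughly
    ``match_mismatch_ratio`` times the mismatch count.
    """
    mm = collect_training_observations(bam_paths, reference, exclusions,
                                       read_filter)
    if beta is not None:
        matches, realised = sample_match_observations(
            bam_paths, reference, beta=beta, seed=seed,
            exclusions=exclusions, read_filter=read_filter)
    else:
        target = int(match_mismatch_ratio * max(len(mm), 1))
        matches, realised = sample_match_observations(
            bam_paths, reference, target_count=target, seed=seed,
            exclusions=exclusions, read_filter=read_filter)
    return assemble_training_table(
        mm, matches, realised, seed=seed,
        provenance={"bam_paths": [str(p) for p in bam_paths]})


def train_validation_split(table: TrainingTable, val_fraction: float = 0.2,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Row indices for a train/validation split.

    Split by sample identifier when at least 3 distinct samples are present
    (so a model is never validated on data from a training sample); random
    rows otherwise.
    """
    df = table.df
    rng = np.random.default_rng(seed)
    samples = df["sample"].unique() if "sample" in df.columns else []
    if len(samples) >= 3:
        samples = np.sort(np.asarray(samples))
        n_val = max(1, int(round(val_fraction * len(samples))))
        val_samples = set(rng.choice(samples, size=n_val, replace=False).tolist())
        val_mask = df["sample"].isin(val_samples).to_numpy()
    else:
        val_mask = rng.random(len(df)) < val_fraction
        if not val_mask.any():
            val_mask[rng.integers(len(df))] = True
    idx = np.arange(len(df))
    return idx[~val_mask], idx[val_mask]
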