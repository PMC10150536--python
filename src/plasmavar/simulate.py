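"""Ground-truth-known synthetic data at three levels.

* :func:`simulate_site_data` — abstract per-site read observations drawn
  directly from the generative model (Z ~ Bernoulli(r); mutant fragments at
  rate f/2; observed alleles flipped at the given error rates), for testing
  the statistical layer against known truth.
* :func:`simulate_training_table` — feature-level error-model training data
  with a known (optionally feature-dependent) error-rate function and match
  downsampling, for testing model calibration and feature selection.
* :func:`simulate_alignments` — full FASTA + SAM fixtures with MD/cD/cE
  tags, fragment lengths from a nucleosomal mixture, feature-dependent
  errors and optional tumor alleles at catalog sites, plus a truth table of
  every resulting substitution, for testing the extraction path end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import pysam

from .alignment import OBSERVATION_COLUMNS
from .calling import CandidateSite, SiteReadData
from .features import TRINUCLEOTIDES
from .training import TrainingTable

NUC = np.array(list("ACGT"))


@dataclass
class FragmentLengthModel:
    """Mixture of mono- and di-nucleosomal fragment lengths (peaks near
    162 bp and 340 bp in plasma)."""

    means: tuple[float, ...] = (162.0, 340.0)
    sds: tuple[float, ...] = (15.0, 30.0)
    weights: tuple[float, ...] = (0.75, 0.25)

    def sample(self, rng: np.random.Generator, n: int,
               minimum: int = 50, maximum: int | None = None) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        lens = rng.normal(np.asarray(self.means)[comp],
                          np.asarray(self.sds)[comp])
        lens = np.clip(np.round(lens), minimum, maximum).astype(int)
        return lens


@dataclass
class ErrorProfile:
    """Feature-dependent per-position error rate.

    log rate is linear in proximity to the read ends plus a strand offset —
    a qualitative stand-in for the elevated error rates seen at read ends
    and the strand asymmetry of real consensus data.
    """

    base_rate: float = 1e-3
    end_coef: float = 0.0  # log-scale bump at read ends
    end_decay: float = 8.0  # cycles over which the bump decays
    reverse_log_offset: float = 0.0

    def rate(self, cycle: np.ndarray, read_len: int,
             is_reverse: np.ndarray | bool = False) -> np.ndarray:
        cycle = np.asarray(cycle, dtype=float)
        bump = (np.exp(-(cycle - 1) / self.end_decay)
                + np.exp(-(read_len - cycle) / self.end_decay))
        log_rate = (math.log(self.base_rate) + self.end_coef * bump
                    + self.reverse_log_offset * np.asarray(is_reverse, dtype=float))
        return np.clip(np.exp(log_rate), 0.0, 0.4)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_sites: int = 10  # K
    depth: int = 1000  # N_i (reads per site / coverage target)
    tumor_fraction: float = 0.0  # f
    presence_prob: float = 0.0  # r
    error_rate: float | tuple[float, float] | Callable = 1e-3
    error_rate_mr: float | tuple[float, float] | Callable | None = None
    read_length: int = 100
    fragment_model: FragmentLengthModel = field(default_factory=FragmentLengthModel)
    error_profile: ErrorProfile = field(default_factory=ErrorProfile)
    umi_mean_extra: float = 2.0  # group size = 1 + Poisson(mean)
    reference_length: int = 3000
    gc_content: float = 0.5
    n_fragments: int = 500
    catalog: list[CandidateSite] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor fraction must lie in [0, 1]")
        if not 0 <= self.presence_prob <= 1:
            raise ValueError("presence probability must lie in [0, 1]")


def _draw_rates(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(spec):
        rates = np.asarray(spec(rng, n), dtype=float)
    elif isinstance(spec, tuple):
        rates = rng.uniform(spec[0], spec[1], size=n)
    else:
        rates = np.full(n, float(spec))
    if np.any((rates < 0) | (rates >= 0.5)):
        raise ValueError("error rates must lie in [0, 0.5)")
    return rates


def simulate_site_data(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[list[SiteReadData], dict]:
    """Sample site read data directly from the generative model.

    Returns the per-site observations and a truth record with the latent
    mutation-presence indicators and true mutant-fragment counts.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    f, r = config.tumor_fraction, config.presence_prob
    z = rng.random(config.n_sites) < r
    sites: list[SiteReadData] = []
    n_mutant = np.zeros(config.n_sites, dtype=int)
    mr_spec = (config.error_rate_mr if config.error_rate_mr is not None
               else config.error_rate)
    for i in range(config.n_sites):
        n = config.depth
        e_rm = _draw_rates(config.error_rate, rng, n)
        e_mr = _draw_rates(mr_spec, rng, n)
        y_mut = (rng.random(n) < f / 2.0) if z[i] else np.zeros(n, dtype=bool)
        n_mutant[i] = y_mut.sum()
        flip = rng.random(n)
        # mutant fragments read as R with e(M->R); reference ones as M with e(R->M)
        x_alt = np.where(y_mut, flip >= e_mr, flip < e_rm)
        sites.append(SiteReadData(
            site=CandidateSite("chrS", 1000 + i, "A", "C"),
            is_alt=x_alt, e_rm=e_rm, e_mr=e_mr))
    return sites, {"z": z, "n_mutant": n_mutant, "f": f, "r": r}


def simulate_training_table(
    n_positions: int = 200_000,
    rate_fn: Callable[[pd.DataFrame], np.ndarray] | float = 1e-3,
    beta: float = 1.0,
    read_length: int = 100,
    extra_numeric: dict[str, Callable] | None = None,
    central_base: str | None = None,
    seed: int = 0,
) -> TrainingTable:
    """Feature-level training data with a known error-rate law.

    ``rate_fn`` maps the feature frame to per-row error probabilities (or is
    a constant).  Matches are thinned to fraction ``beta``; every mismatch is
    kept, mirroring how real training tables are assembled.  ``central_base``
    restricts positions to one reference base (a single-stratum table whose
    allele distribution is learnable without any context feature).
    """
    rng = np.random.default_rng(seed)
    n = n_positions
    frag = FragmentLengthModel().sample(rng, n, minimum=read_length)
    df = pd.DataFrame({
        "chrom": "chrS",
        "genomic_pos": rng.integers(100, 10_000, size=n),
        "read_position": rng.integers(1, read_length + 1, size=n),
        "strand": np.where(rng.random(n) < 0.5, "forward", "reverse"),
        "first_in_pair": rng.random(n) < 0.5,
        "fragment_size": frag,
        "seq_length": read_length,
        "umi_group_size": 1 + rng.poisson(2.0, size=n),
        "umi_errors": rng.poisson(0.2, size=n),
        "n_other_errors": rng.poisson(0.1, size=n),
        "n_insertions": rng.poisson(0.02, size=n),
        "n_deletions": rng.poisson(0.02, size=n),
        "trinucleotide": (rng.choice(TRINUCLEOTIDES, size=n)
                          if central_base is None else
                          np.char.add(np.char.add(
                              rng.choice(NUC, size=n), central_base),
                              rng.choice(NUC, size=n))),
        "gc_content": rng.integers(0, 12, size=n) / 11.0,
        "entropy_1mer": rng.uniform(0.5, 2.0, size=n),
        "entropy_2mer": rng.uniform(0.5, 3.3, size=n),
        "query_name": "",
        "sample": "sim",
    })
    for name, fn in (extra_numeric or {}).items():
        df[name] = fn(rng, n)
    df["ref_allele"] = df["trinucleotide"].str[1]
    rates = rate_fn(df) if callable(rate_fn) else np.full(n, float(rate_fn))
    rates = np.asarray(rates, dtype=float)
    if np.any((rates < 0) | (rates >= 0.5)):
        raise ValueError("error rates must lie in [0, 0.5)")
    is_err = rng.random(n) < rates
    ref_idx = df["ref_allele"].map({"A": 0, "C": 1, "G": 2, "T": 3}).to_numpy()
    shift = rng.integers(1, 4, size=n)
    obs_idx = np.where(is_err, (ref_idx + shift) % 4, ref_idx)
    df["obs_allele"] = NUC[obs_idx]
    df["genomic_pos"] = df["genomic_pos"].astype(int)

    keep = is_err | (rng.random(n) < beta)
    df = df[keep].reset_index(drop=True)
    order = [c for c in OBSERVATION_COLUMNS if c in df.columns]
    df = df[order + [c for c in df.columns if c not in order]]
    n_mm = int((df["obs_allele"] != df["ref_allele"]).sum())
    return TrainingTable(df=df, match_sampling_fraction=beta,
                         n_mismatches=n_mm, n_matches=len(df) - n_mm,
                         provenance={"generator": "simulate_training_table",
                                     "seed": seed})


# ---------------------------------------------------------------------------
# full SAM/FASTA fixtures
# ---------------------------------------------------------------------------

def random_reference(length: int, gc: float = 0.5,
                     rng: np.random.Generator | None = None,
                     chrom: str = "chrS") -> dict[str, str]:
    rng = rng or np.random.default_rng(0)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(NUC, size=length, p=p))
    return {chrom: seq}


def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def md_string(read_seq: str, ref_seq: str) -> str:
    """MD tag for a gapless alignment of read_seq against ref_seq."""
    out = []
    run = 0
    for rb, qb in zip(ref_seq, read_seq):
        if rb == qb:
            run += 1
        else:
            out.append(str(run))
            out.append(rb)
            run = 0
    out.append(str(run))
    return "".join(out)


def simulate_alignments(config: SimulationConfig,
                        reference: dict[str, str] | None = None,
                        out_sam: str | Path | None = None,
                        out_fasta: str | Path | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Paired consensus-style reads with MD/cD/cE tags and injected signal.

    Fragments are placed uniformly on the reference with nucleosomal-mixture
    lengths; each fragment yields a forward first-in-pair read at its start
    and, when the fragment is long enough after overlap trimming, a reverse
    second-in-pair read at its end.  Mutant fragments carry catalog alt
    alleles at per-fragment rate f/2 (for sites with Z=1 drawn at rate r);
    errors are injected per cycle from the feature-dependent error profile.

    Returns ``(reference, reads_df, truth_df)`` where ``truth_df`` lists
    every position at which an emitted read differs from the reference
    (origin 'error' or 'tumor').  Optionally writes SAM and FASTA files.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.read_length > config.reference_length:
        raise ValueError("read length exceeds reference length")
    if reference is None:
        reference = random_reference(config.reference_length, config.gc_content,
                                     rng)
    chrom = next(iter(reference))
    ref_seq = str(reference[chrom]).upper()
    L = config.read_length
    n_frag = config.n_fragments
    frag_len = config.fragment_model.sample(
        rng, n_frag, minimum=L, maximum=max(L, len(ref_seq) - 2))
    start = rng.integers(0, np.maximum(len(ref_seq) - frag_len, 1))  # 0-based

    z_by_site = {(s.chrom, s.pos): rng.random() < config.presence_prob
                 for s in config.catalog}
    site_by_pos = {(s.chrom, s.pos): s for s in config.catalog}

    reads = []
    truth_rows = []
    for k in range(n_frag):
        fs, fl = int(start[k]), int(frag_len[k])
        is_mutant = rng.random() < config.tumor_fraction / 2.0
        mutated_positions = {}
        if is_mutant:
            for (c, pos), site in site_by_pos.items():
                if c == chrom and fs < pos <= fs + fl and z_by_site[(c, pos)]:
                    mutated_positions[pos] = site.alt_allele

        r2_len = min(L, fl - L)  # overlap-trimmed second mate
        mates = [("r1", fs, L, False)]
        if r2_len > 0:
            mates.append(("r2", fs + fl - r2_len, r2_len, True))
        qname = f"frag{k}"
        for mate, m_start, m_len, is_rev in mates:
            seq = list(ref_seq[m_start:m_start + m_len])
            for pos, alt in mutated_positions.items():
                off = pos - 1 - m_start
                if 0 <= off < m_len:
                    seq[off] = alt
            cycles = (np.arange(m_len, 0, -1) if is_rev
                      else np.arange(1, m_len + 1))
            rates = config.error_profile.rate(cycles, m_len, is_rev)
            err = rng.random(m_len) < rates
            for off in np.flatnonzero(err):
                cur = seq[off]
                seq[off] = rng.choice([b for b in "ACGT" if b != cur])
            seq = "".join(seq)
            for off in range(m_len):
                gpos = m_start + off + 1
                if seq[off] != ref_seq[m_start + off]:
                    truth_rows.append({
                        "query_name": f"{qname}/{mate}", "chrom": chrom,
                        "pos": gpos, "ref": ref_seq[m_start + off],
                        "obs": seq[off],
                        "origin": ("tumor" if gpos in mutated_positions
                                   and seq[off] == mutated_positions[gpos]
                                   else "error"),
                    })
            flags = 0x1 | 0x2  # paired, proper
            flags |= 0x10 if is_rev else 0x20
            flags |= 0x40 if mate == "r1" else 0x80
            reads.append({
                "query_name": f"{qname}/{mate}", "flags": flags,
                "chrom": chrom, "pos": m_start + 1, "mapq": 60,
                "cigar": f"{m_len}M",
                "isize": fl if not is_rev else -fl,
                "seq": seq,
                "md": md_string(seq, ref_seq[m_start:m_start + m_len]),
                "cD": int(1 + rng.poisson(config.umi_mean_extra)),
                "cE": int(rng.poisson(0.3)),
            })
    reads_df = pd.DataFrame(reads)
    truth_df = pd.DataFrame(
        truth_rows, columns=["query_name", "chrom", "pos", "ref", "obs", "origin"])
    if out_fasta is not None:
        write_fasta(reference, out_fasta)
    if out_sam is not None:
        write_sam(reads_df, {chrom: len(ref_seq)}, out_sam)
    return reference, reads_df, truth_df


def write_sam(reads_df: pd.DataFrame, contig_lengths: dict[str, int],
              path: str | Path) -> None:
    """Write simulated reads as a SAM text file with MD/NM/cD/cE tags."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": int(n)} for c, n in contig_lengths.items()]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for row in reads_df.itertuples():
            a = pysam.AlignedSegment(fh.header)
            a.query_name = row.query_name
            a.flag = int(row.flags)
            a.reference_id = fh.header.get_tid(row.chrom)
            a.reference_start = int(row.pos) - 1
            a.mapping_quality = int(row.mapq)
            a.cigarstring = row.cigar
            a.template_length = int(row.isize)
            a.query_sequence = row.seq
            nm = sum(1 for t in row.md if t in "ACGTN")
            a.set_tags([("NM", nm, "i"), ("MD", row.md, "Z"),
                        ("cD", int(row.cD), "i"), ("cE", int(row.cE), "i")])
            fh.write(a)
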