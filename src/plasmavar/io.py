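"""Catalog / exclusion-list readers and result writers.

Catalogs are (chrom, pos, ref, alt) tables, either TSV with those columns or
VCF; germline exclusion sets come from VCF.  All positions are 1-based.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .calling import CallResult, CandidateSite


def read_catalog(path: str | Path) -> list[CandidateSite]:
    """Read a mutation catalog from TSV (chrom, pos, ref, alt) or VCF."""
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        out = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    if len(rec.ref) == 1 and len(alt) == 1:
                        out.append(CandidateSite(rec.chrom, rec.pos,
                                                 rec.ref.upper(), alt.upper()))
        return out
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return [CandidateSite(str(r.chrom), int(r.pos), str(r.ref).upper(),
                          str(r.alt).upper())
            for r in df.itertuples()]


def write_catalog(sites: Sequence[CandidateSite], path: str | Path) -> None:
    pd.DataFrame([{"chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele,
                   "alt": s.alt_allele} for s in sites]
                 ).to_csv(path, sep="\t", index=False)


def read_exclusions(vcf_path: str | Path) -> frozenset[tuple[str, int]]:
    """(chrom, pos) pairs of germline variants to exclude from training."""
    out = set()
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            out.add((rec.chrom, rec.pos))
    return frozenset(out)


def load_reference(fasta_path: str | Path):
    """A contig-name -> sequence mapping backed by an indexed FASTA."""
    import pyfaidx
    return pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)


def call_results_table(results: Sequence[tuple[CandidateSite, CallResult]]
                       ) -> pd.DataFrame:
    """One row per call with the estimate and test columns."""
    rows = []
    for site, res in results:
        rows.append({
            "chrom": site.chrom, "pos": site.pos, "ref": site.ref_allele,
            "alt": site.alt_allele, "n_reads": res.sites[0].n_reads,
            "n_alt": res.sites[0].n_alt, "f_hat": res.f_hat,
            "r_hat": res.r_hat, "Q": res.Q, "df": res.df,
            "p_value": res.p_value, "converged": res.converged,
        })
    return pd.DataFrame(rows)
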