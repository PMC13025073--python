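"""Variant ingestion and filtering ahead of evolutionary inference.

Reads somatic SNV calls from VCF 4.x (AD or DP+AF), MAF, or plain
tab-separated tables, restricts them to diploid genomic regions (the model
interprets VAF as half the cell fraction, which only holds at copy number
2), converts VAFs to cell fractions given tumor purity, and applies
sample-level analyzability gates (minimum mutation count, read support,
optional hypermutator cutoff).

Variant calls are carried as a pandas DataFrame with columns ``chrom``,
``pos`` (1-based), ``ref``, ``alt``, ``depth``, ``alt_reads``, ``vaf`` and,
after :func:`adjust_purity`, ``cell_fraction``.  Copy-number segments are a
DataFrame with columns ``chrom``, ``start``, ``end`` (half-open, 0-based)
and ``copy_number``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CALL_COLUMNS",
    "GateReport",
    "read_variants",
    "read_segments",
    "filter_diploid",
    "adjust_purity",
    "gate_sample",
]

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_reads", "vaf"]


def _finalize_calls(rows: list[dict], n_indels: int, n_skipped: int) -> pd.DataFrame:
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS[:-1])
    calls["pos"] = calls["pos"].astype(np.int64) if len(calls) else calls["pos"]
    calls["vaf"] = np.where(calls["depth"] > 0, calls["alt_reads"] / calls["depth"], 0.0)
    if n_indels:
        logger.info("dropped %d non-SNV records", n_indels)
    if n_skipped:
        logger.warning("skipped %d records lacking depth/alt support", n_skipped)
    calls.attrs["n_indels_dropped"] = n_indels
    calls.attrs["n_skipped"] = n_skipped
    return calls


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref != alt and alt != "*"


def _read_vcf(path, sample: str | None) -> pd.DataFrame:
    import pysam

    rows, n_indels, n_skipped = [], 0, 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        if sample is None:
            sample = samples[0]
        elif sample not in samples:
            raise ValueError(f"{path}: sample {sample!r} not in VCF ({samples})")
        for rec in vf:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            for i, alt in enumerate(rec.alts or ()):
                if not _is_snv(rec.ref, alt):
                    n_indels += 1
                    continue
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    alt_reads = int(ad[i + 1])
                    depth = int(dp) if dp is not None else int(sum(x or 0 for x in ad))
                elif dp is not None and fmt.get("AF") is not None:
                    af = fmt["AF"]
                    af_i = af[i] if isinstance(af, tuple) else af
                    depth = int(dp)
                    alt_reads = int(round(float(af_i) * depth))
                else:
                    n_skipped += 1
                    continue
                rows.append(
                    dict(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                         depth=depth, alt_reads=alt_reads)
                )
    return _finalize_calls(rows, n_indels, n_skipped)


def _read_maf(path, sample: str | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", low_memory=False)
    required = ["Chromosome", "Start_Position", "Reference_Allele",
                "Tumor_Seq_Allele2", "t_ref_count", "t_alt_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: MAF is missing columns {missing}")
    if sample is not None and "Tumor_Sample_Barcode" in df.columns:
        df = df[df["Tumor_Sample_Barcode"] == sample]
    n_skipped = int(df["t_ref_count"].isna().sum() + df["t_alt_count"].isna().sum())
    df = df.dropna(subset=["t_ref_count", "t_alt_count"])
    snv = df.apply(
        lambda r: _is_snv(str(r.Reference_Allele), str(r.Tumor_Seq_Allele2)), axis=1
    ) if len(df) else pd.Series(dtype=bool)
    n_indels = int((~snv).sum()) if len(df) else 0
    df = df[snv] if len(df) else df
    rows = [
        dict(chrom=str(r.Chromosome), pos=int(r.Start_Position),
             ref=str(r.Reference_Allele), alt=str(r.Tumor_Seq_Allele2),
             depth=int(r.t_ref_count) + int(r.t_alt_count),
             alt_reads=int(r.t_alt_count))
        for r in df.itertuples(index=False)
    ]
    return _finalize_calls(rows, n_indels, n_skipped)


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "alt_reads" not in cols:
        raise ValueError(f"{path}: TSV needs an alt_reads column")
    alt_reads = df[cols["alt_reads"]].astype(np.int64)
    if "depth" in cols:
        depth = df[cols["depth"]].astype(np.int64)
    elif "ref_reads" in cols:
        depth = df[cols["ref_reads"]].astype(np.int64) + alt_reads
    else:
        raise ValueError(f"{path}: TSV needs a depth or ref_reads column")
    rows_df = pd.DataFrame(
        {
            "chrom": df[cols["chrom"]].astype(str) if "chrom" in cols else "1",
            "pos": df[cols["pos"]].astype(np.int64) if "pos" in cols else np.arange(1, len(df) + 1),
            "ref": df[cols["ref"]].astype(str) if "ref" in cols else "N",
            "alt": df[cols["alt"]].astype(str) if "alt" in cols else "N",
            "depth": depth,
            "alt_reads": alt_reads,
        }
    )
    snv = rows_df.apply(lambda r: r.ref == "N" or _is_snv(r.ref, r.alt), axis=1) if len(rows_df) else pd.Series(dtype=bool)
    n_indels = int((~snv).sum()) if len(rows_df) else 0
    rows_df = rows_df[snv] if len(rows_df) else rows_df
    return _finalize_calls(rows_df.to_dict("records"), n_indels, 0)


def read_variants(path, format: str | None = None, sample: str | None = None) -> pd.DataFrame:
    """Read somatic SNV calls into the standard call table.

    ``format`` is one of ``vcf``, ``maf`` or ``tsv``; inferred from the file
    extension when omitted.  Multi-allelic VCF records are split into one
    call per alt allele; indels are dropped (counted in
    ``calls.attrs['n_indels_dropped']``); records without usable read
    support are skipped with a warning.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        if suffix == "gz":
            suffix = path.suffixes[-2].lower().lstrip(".")
        format = {"vcf": "vcf", "maf": "maf", "tsv": "tsv", "txt": "tsv"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from {path.name}; pass format=")
    if format == "vcf":
        return _read_vcf(path, sample)
    if format == "maf":
        return _read_maf(path, sample)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown variant format {format!r}")


def read_segments(path) -> pd.DataFrame:
    """Read a BED-like copy-number segment table.

    Expects tab-separated columns chrom, start, end, copy_number (header
    optional); coordinates are 0-based half-open, as in BED.
    """
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
    seg = pd.read_csv(
        path, sep="\t", header=0 if has_header else None,
        names=None if has_header else ["chrom", "start", "end", "copy_number"],
    )
    seg.columns = [str(c).lower() for c in seg.columns]
    rename = {"cn": "copy_number", "total_cn": "copy_number", "chromosome": "chrom"}
    seg = seg.rename(columns=rename)
    required = ["chrom", "start", "end", "copy_number"]
    missing = [c for c in required if c not in seg.columns]
    if missing:
        raise ValueError(f"{path}: segment table missing columns {missing}")
    seg = seg[required].copy()
    seg["chrom"] = seg["chrom"].astype(str)
    if (seg["start"] < 0).any() or (seg["end"] < seg["start"]).any():
        raise ValueError("segment coordinates must be non-negative with end >= start")
    return seg.sort_values(["chrom", "start"]).reset_index(drop=True)


def filter_diploid(
    calls: pd.DataFrame,
    segments: pd.DataFrame | None,
    mode: str = "keep_diploid",
) -> tuple[pd.DataFrame, int]:
    """Restrict calls to diploid regions; returns (kept calls, dropped count).

    With ``mode='keep_diploid'`` a call is kept iff it falls inside a
    segment with total copy number 2.  With ``mode='drop_aberrant'`` calls
    outside any listed segment are also kept (the segment file then lists
    only aberrant regions).  VCF positions are 1-based inclusive and
    segments half-open 0-based, so position ``pos`` lies in segment
    ``[start, end)`` iff ``start <= pos - 1 < end``.
    """
    if mode not in ("keep_diploid", "drop_aberrant"):
        raise ValueError(f"unknown mode {mode!r}")
    if segments is None:
        logger.info("no segment file: assuming all %d calls are diploid", len(calls))
        return calls.copy(), 0
    keep = np.zeros(len(calls), dtype=bool)
    pos0 = calls["pos"].to_numpy() - 1  # to 0-based
    for chrom, seg in segments.groupby("chrom"):
        in_chrom = (calls["chrom"].astype(str) == str(chrom)).to_numpy()
        if not in_chrom.any():
            continue
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        cns = seg["copy_number"].to_numpy()
        p = pos0[in_chrom]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        diploid = inside & (cns[np.clip(idx, 0, len(cns) - 1)] == 2)
        if mode == "keep_diploid":
            keep[in_chrom] = diploid
        else:
            keep[in_chrom] = diploid | ~inside
    if mode == "drop_aberrant":
        listed = calls["chrom"].astype(str).isin(segments["chrom"].astype(str).unique()).to_numpy()
        keep |= ~listed
    kept = calls[keep].reset_index(drop=True)
    dropped = int(len(calls) - len(kept))
    for key, val in calls.attrs.items():
        kept.attrs[key] = val
    return kept, dropped


def adjust_purity(calls: pd.DataFrame, purity: float) -> pd.DataFrame:
    """Convert VAFs to cell fractions: ``cell_fraction = min(2 * vaf / purity, 1)``.

    A heterozygous diploid mutation carried by a fraction ``f`` of tumor
    cells in a sample of purity ``rho`` has expected VAF ``rho * f / 2``.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    out = calls.copy()
    out["cell_fraction"] = np.minimum(2.0 * out["vaf"].to_numpy() / purity, 1.0)
    for key, val in calls.attrs.items():
        out.attrs[key] = val
    return out


@dataclass
class GateReport:
    """Outcome of the sample-level analyzability gates."""

    analyzable: bool
    reasons: list[str] = field(default_factory=list)
    n_input: int = 0
    n_kept: int = 0
    n_low_depth: int = 0
    n_low_support: int = 0
    rules: dict = field(default_factory=dict)


def gate_sample(
    calls: pd.DataFrame,
    min_mutations: int = 50,
    max_mutations: int | None = None,
    min_depth: int = 20,
    min_alt: int = 3,
) -> tuple[pd.DataFrame, GateReport]:
    """Apply read-support filters and sample-level exclusion gates.

    Calls with depth below ``min_depth`` or fewer than ``min_alt``
    supporting reads are dropped.  The sample is flagged non-analyzable
    (reason-coded, never raised) when fewer than ``min_mutations`` calls
    survive or, if ``max_mutations`` is set (the hypermutator cutoff,
    e.g. 10 mutations/Mb times the exome footprint), when more do.
    """
    n_input = len(calls)
    depth = calls["depth"].to_numpy() if n_input else np.zeros(0)
    alt = calls["alt_reads"].to_numpy() if n_input else np.zeros(0)
    low_depth = depth < min_depth
    low_support = ~low_depth & (alt < min_alt)
    kept = calls[~(low_depth | low_support)].reset_index(drop=True)
    for key, val in calls.attrs.items():
        kept.attrs[key] = val
    reasons = []
    if len(kept) < min_mutations:
        reasons.append("too_few_mutations")
    if max_mutations is not None and len(kept) > max_mutations:
        reasons.append("hypermutator")
    report = GateReport(
        analyzable=not reasons,
        reasons=reasons,
        n_input=n_input,
        n_kept=len(kept),
        n_low_depth=int(low_depth.sum()),
        n_low_support=int(low_support.sum()),
        rules={
            "min_mutations": min_mutations,
            "max_mutations": max_mutations,
            "min_depth": min_depth,
            "min_alt": min_alt,
        },
    )
    return kept, report
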