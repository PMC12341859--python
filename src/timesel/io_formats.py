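"""Readers and writers for the package's tabular formats and VCF input.

Formats
-------
Count table
    Tab-separated; ``#``-prefixed comment/metadata lines; a header line
    ``ID  t1  t1  t2  t2 ...`` repeating each sampling time once for the
    sample-size column and once for the derived-allele-count column; one row
    per locus.  Round-trips exactly with the simulator output.
Sample information table
    Tab-separated with header columns ``ID`` and ``time`` (sampling time in
    generations, forward from the analysis start) and an optional ``ploidy``
    column (``diploid`` or ``pseudo-haploid``).
VCF
    Standard VCF 4.x with GT fields, read through pysam.  The ALT allele is
    the focal allele ``A``; no ancestral-allele polarization is applied.
Result table
    Tab-separated with ``#key: value`` metadata headers recording run
    parameters; values print with 12 significant digits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .hmm import TemporalSamples
from .inference import LikelihoodSurface, interpolate_mle

logger = logging.getLogger("timesel")

__all__ = [
    "SampleInfo",
    "LocusRecord",
    "read_sample_info",
    "read_count_table",
    "write_count_table",
    "read_vcf",
    "filter_loci",
    "mle_table",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class SampleInfo:
    """Mapping from sample ID to sampling time, with optional ploidy overrides."""

    times: dict
    ploidy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, t in self.times.items():
            if not np.isfinite(t):
                raise ValueError(f"non-finite sampling time for sample {sid!r}")
        bad = set(self.ploidy.values()) - {"diploid", "pseudo-haploid"}
        if bad:
            raise ValueError(f"unknown ploidy values: {sorted(bad)}")


@dataclass(frozen=True)
class LocusRecord:
    """One biallelic SNP with per-time aggregated sample sizes and counts."""

    chrom: str
    pos: int  # 1-based, as in the source VCF
    id: str
    ref: str
    alt: str
    times: np.ndarray
    sizes: np.ndarray
    counts: np.ndarray

    def to_temporal_samples(self) -> TemporalSamples:
        return TemporalSamples(
            times=self.times, sizes=self.sizes, counts=self.counts, locus_id=self.id
        )

    @property
    def pooled_size(self) -> int:
        return int(self.sizes.sum())

    @property
    def pooled_count(self) -> int:
        return int(self.counts.sum())


def read_sample_info(path) -> SampleInfo:
    """Read a tab-separated sample-information table (columns ID, time[, ploidy])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ID": str})
    for col in ("ID", "time"):
        if col not in df.columns:
            raise ValueError(f"sample info file {path} lacks required column {col!r}")
    if df["ID"].duplicated().any():
        dup = df.loc[df["ID"].duplicated(), "ID"].iloc[0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    times = dict(zip(df["ID"], df["time"].astype(float)))
    ploidy = {}
    if "ploidy" in df.columns:
        ploidy = dict(zip(df["ID"], df["ploidy"].astype(str)))
    return SampleInfo(times=times, ploidy=ploidy)


def read_count_table(path) -> list[TemporalSamples]:
    """Parse an allele-count table into one :class:`TemporalSamples` per locus."""
    header = None
    loci: list[TemporalSamples] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                times = _parse_count_header(header, path, lineno)
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            vals = []
            for j, tok in enumerate(fields[1:], start=2):
                try:
                    vals.append(int(tok))
                except ValueError as err:
                    raise ValueError(
                        f"{path}:{lineno}: column {j} is not an integer: {tok!r}"
                    ) from err
            sizes = np.array(vals[0::2])
            counts = np.array(vals[1::2])
            bad = np.flatnonzero(counts > sizes)
            if len(bad):
                k = bad[0]
                raise ValueError(
                    f"{path}:{lineno}: count {counts[k]} exceeds size {sizes[k]} "
                    f"at time {times[k]:g}"
                )
            loci.append(
                TemporalSamples(
                    times=times, sizes=sizes, counts=counts, locus_id=fields[0]
                )
            )
    if header is None:
        raise ValueError(f"{path}: no header line found")
    return loci


def _parse_count_header(header, path, lineno) -> np.ndarray:
    if len(header) < 3 or (len(header) - 1) % 2 != 0:
        raise ValueError(
            f"{path}:{lineno}: header must be 'ID' plus (size, count) column "
            f"pairs per time, got {len(header)} columns"
        )
    try:
        ts = [float(t) for t in header[1:]]
    except ValueError as err:
        raise ValueError(f"{path}:{lineno}: non-numeric time in header") from err
    sizes_t, counts_t = ts[0::2], ts[1::2]
    if sizes_t != counts_t:
        raise ValueError(
            f"{path}:{lineno}: header times must repeat per (size, count) pair"
        )
    times = np.array(sizes_t)
    if np.any(np.diff(times) < 0):
        raise ValueError(f"{path}:{lineno}: sampling times are not sorted")
    return times


def write_count_table(path, loci: Sequence[TemporalSamples], metadata: dict | None = None) -> None:
    """Write loci (sharing a time schedule) in the count-table dialect."""
    if not loci:
        raise ValueError("no loci to write")
    times = loci[0].times
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}: {val}\n")
        cols = "\t".join(f"{t:g}\t{t:g}" for t in times)
        fh.write(f"ID\t{cols}\n")
        for i, loc in enumerate(loci):
            if not np.array_equal(loc.times, times):
                raise ValueError("all loci must share sampling times")
            lid = loc.locus_id if loc.locus_id is not None else f"locus{i}"
            cells = "\t".join(
                f"{n}\t{c}" for n, c in zip(loc.sizes, loc.counts)
            )
            fh.write(f"{lid}\t{cells}\n")


def read_vcf(
    path,
    info: SampleInfo,
    force_hap: Iterable[str] = (),
    force_dip: Iterable[str] = (),
) -> list[LocusRecord]:
    """Read biallelic SNPs from a VCF into per-time aggregated counts.

    Diploid genotypes contribute (size 2, count = number of ALT alleles);
    pseudo-haploid samples (in ``force_hap`` or flagged in ``info.ploidy``)
    contribute a single observation, with heterozygous genotypes rejected;
    genuinely haploid GT entries contribute size 1; missing genotypes
    contribute size 0.  Multi-allelic and non-SNP records are skipped with a
    logged count.
    """
    force_hap = set(force_hap)
    force_dip = set(force_dip)
    overlap = force_hap & force_dip
    if overlap:
        raise ValueError(f"samples in both force sets: {sorted(overlap)}")
    vcf = pysam.VariantFile(path)
    vcf_samples = list(vcf.header.samples)
    for sset, name in ((force_hap, "force_hap"), (force_dip, "force_dip")):
        missing = sset - set(vcf_samples)
        if missing:
            raise ValueError(f"{name} samples not in VCF: {sorted(missing)}")
    absent = [s for s in vcf_samples if s not in info.times]
    if absent:
        raise ValueError(
            f"VCF samples missing from sample info: {absent[:5]}"
            + ("..." if len(absent) > 5 else "")
        )
    pseudo = force_hap | {
        s for s, p in info.ploidy.items() if p == "pseudo-haploid" and s not in force_dip
    }
    times = np.array(sorted({info.times[s] for s in vcf_samples}))
    t_index = {t: k for k, t in enumerate(times)}
    records: list[LocusRecord] = []
    n_skipped = 0
    for rec in vcf:
        if (
            rec.alts is None
            or len(rec.alts) != 1
            or len(rec.ref) != 1
            or len(rec.alts[0]) != 1
            or rec.alts[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        sizes = np.zeros(len(times), dtype=int)
        counts = np.zeros(len(times), dtype=int)
        for sid in vcf_samples:
            gt = rec.samples[sid].get("GT")
            alleles = tuple(a for a in (gt or ()) if a is not None)
            if not alleles:
                continue
            k = t_index[info.times[sid]]
            if sid in pseudo:
                if len(set(alleles)) > 1:
                    raise ValueError(
                        f"pseudo-haploid sample {sid!r} is heterozygous at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                sizes[k] += 1
                counts[k] += int(alleles[0] > 0)
            else:
                sizes[k] += len(alleles)
                counts[k] += sum(a > 0 for a in alleles)
        records.append(
            LocusRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                id=rec.id or f"{rec.chrom}_{rec.pos}",
                ref=rec.ref,
                alt=rec.alts[0],
                times=times,
                sizes=sizes,
                counts=counts,
            )
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic or non-SNP records", n_skipped)
    return records


def filter_loci(
    records: Sequence[LocusRecord],
    min_pooled_maf: float = 0.0,
    subset: Iterable[str] | None = None,
    region: tuple | None = None,
) -> list[LocusRecord]:
    """Keep loci passing the pooled minor-allele-frequency threshold.

    ``subset`` restricts to the given locus IDs, ``region`` to a
    ``(chrom, start, end)`` window (1-based, inclusive); order is preserved.
    Loci with zero pooled sample size are dropped with a warning.
    """
    if not (0.0 <= min_pooled_maf <= 0.5):
        raise ValueError(f"min_pooled_maf must lie in [0, 0.5], got {min_pooled_maf}")
    ids = set(subset) if subset is not None else None
    kept = []
    for rec in records:
        if ids is not None and rec.id not in ids:
            continue
        if region is not None:
            chrom, start, end = region
            if rec.chrom != chrom or not (start <= rec.pos <= end):
                continue
        total = rec.pooled_size
        if total == 0:
            warnings.warn(f"locus {rec.id} has zero pooled sample size; dropped")
            continue
        f = rec.pooled_count / total
        if min(f, 1.0 - f) >= min_pooled_maf:
            kept.append(rec)
    return kept


def mle_table(surface: LikelihoodSurface) -> pd.DataFrame:
    """Per-locus MLE summary of a 1D likelihood surface as a DataFrame."""
    rows = []
    ids = surface.locus_ids or [f"locus{i}" for i in range(surface.n_loci)]
    for i in range(surface.n_loci):
        r = interpolate_mle(surface, i)
        rows.append(
            {
                "ID": ids[i],
                "ongrid_mle": r.ongrid_mle,
                "offgrid_mle": r.offgrid_mle,
                "max_loglik": r.max_loglik,
                "neutral_loglik": r.neutral_loglik,
                "lrt_stat": r.lrt_stat,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def write_results(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a result table with ``#key: value`` provenance headers."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"#{key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> tuple[pd.DataFrame, dict]:
    """Read back a result table and its metadata headers."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, meta
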