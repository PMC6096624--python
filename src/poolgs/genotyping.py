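"""Allele-frequency genotyping of pooled samples from VCF allele depths.

Pool-seq genotyping of outbred populations does not yield discrete genotype
calls: the information per variant is the pair of reference/alternate read
depths in the sample's AD field, whose ratio estimates the population allele
frequency.  This module reads AD fields into a :class:`ReadCountMatrix`,
applies the depth-based reliability filters, and converts depths into an
:class:`AlleleFrequencyMatrix` with low-depth calls re-coded as missing:

- a locus is dropped when more than ``max_low_fraction`` (default 50%) of the
  pools have total depth below ``min_depth`` (default 100 reads);
- an individual call is set to missing when its total depth is below
  ``min_call_depth`` (default 40 reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MIN_LOCUS_DEPTH = 100
DEFAULT_MAX_LOW_FRACTION = 0.5
DEFAULT_MIN_CALL_DEPTH = 40


class VCFFormatError(ValueError):
    """Raised when a VCF lacks the fields this pipeline requires."""


@dataclass
class ReadCountMatrix:
    """Per-population, per-locus reference/alternate read depths.

    ``loci`` identifiers follow the ``chrom:pos:ref:alt`` convention with
    1-based VCF coordinates.
    """

    populations: list[str]
    loci: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    n_skipped_records: int = 0

    def __post_init__(self):
        self.ref_depth = np.asarray(self.ref_depth)
        self.alt_depth = np.asarray(self.alt_depth)
        expected = (len(self.populations), len(self.loci))
        if self.ref_depth.shape != expected or self.alt_depth.shape != expected:
            raise ValueError(
                f"depth matrices must have shape {expected}, got "
                f"{self.ref_depth.shape} and {self.alt_depth.shape}"
            )
        if np.any(self.ref_depth < 0) or np.any(self.alt_depth < 0):
            raise ValueError("read depths must be non-negative")

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def subset_loci(self, mask_or_index) -> "ReadCountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ReadCountMatrix(
            populations=list(self.populations),
            loci=[self.loci[i] for i in idx],
            ref_depth=self.ref_depth[:, idx],
            alt_depth=self.alt_depth[:, idx],
            n_skipped_records=self.n_skipped_records,
        )


@dataclass
class AlleleFrequencyMatrix:
    """Populations x loci reference-allele frequencies in [0, 1].

    Missing calls are NaN; ``imputed`` flags entries filled in afterwards by
    :func:`poolgs.imputation.impute_ldknni` (observed entries stay False).
    """

    populations: list[str]
    loci: list[str]
    af: np.ndarray
    imputed: np.ndarray = field(default=None)

    def __post_init__(self):
        self.af = np.asarray(self.af, dtype=float)
        if self.af.shape != (len(self.populations), len(self.loci)):
            raise ValueError("af matrix shape does not match identifier lists")
        with np.errstate(invalid="ignore"):
            bad = (self.af < 0) | (self.af > 1)
        if np.any(bad):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.imputed is None:
            self.imputed = np.zeros(self.af.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.af)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def copy(self) -> "AlleleFrequencyMatrix":
        return AlleleFrequencyMatrix(
            populations=list(self.populations),
            loci=list(self.loci),
            af=self.af.copy(),
            imputed=self.imputed.copy(),
        )

    def population_index(self, ids) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.populations)}
        try:
            return np.array([lookup[p] for p in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown population {exc.args[0]!r}") from exc


def read_vcf_ad(vcf_path: str) -> ReadCountMatrix:
    """Read per-sample allele depths (FORMAT/AD) from a bi-allelic VCF.

    Multi-allelic records are skipped with a logged warning and counted in
    ``n_skipped_records``.  A sample with a missing AD value gets depths
    (0, 0), which downstream becomes a missing allele-frequency call.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VCFFormatError(f"cannot parse VCF {vcf_path!r}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VCFFormatError(f"VCF {vcf_path!r} has no samples")
    loci: list[str] = []
    ref_cols: list[np.ndarray] = []
    alt_cols: list[np.ndarray] = []
    n_skipped = 0
    saw_ad = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping non-bi-allelic record %s:%s (%s alt alleles)",
                var.CHROM,
                var.POS,
                len(var.ALT),
            )
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            ref = np.zeros(len(samples), dtype=np.int64)
            alt = np.zeros(len(samples), dtype=np.int64)
        else:
            saw_ad = True
            ad = np.asarray(ad)
            if ad.ndim == 1:
                ad = ad[:, None]
            ref = ad[:, 0].astype(np.int64)
            alt = ad[:, 1].astype(np.int64) if ad.shape[1] > 1 else np.zeros(len(samples), np.int64)
            # cyvcf2 encodes missing AD values as large negative sentinels
            missing = (ref < 0) | (alt < 0)
            ref[missing] = 0
            alt[missing] = 0
        loci.append(f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}")
        ref_cols.append(ref)
        alt_cols.append(alt)
    if loci and not saw_ad:
        raise VCFFormatError(f"VCF {vcf_path!r} has no usable FORMAT/AD field")
    if n_skipped:
        logger.warning("skipped %d non-bi-allelic records", n_skipped)
    ref_depth = np.column_stack(ref_cols) if loci else np.zeros((len(samples), 0), np.int64)
    alt_depth = np.column_stack(alt_cols) if loci else np.zeros((len(samples), 0), np.int64)
    return ReadCountMatrix(
        populations=samples,
        loci=loci,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        n_skipped_records=n_skipped,
    )


def write_vcf(rcm: ReadCountMatrix, path: str) -> None:
    """Write the read-count matrix as a minimal bi-allelic VCF with AD fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolgs\n")
        chroms = []
        for locus in rcm.loci:
            chrom = locus.split(":")[0]
            if chrom not in chroms:
                chroms.append(chrom)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(rcm.populations) + "\n")
        for j, locus in enumerate(rcm.loci):
            chrom, pos, ref, alt = locus.split(":")
            cells = [
                f"./.:{rcm.ref_depth[i, j]},{rcm.alt_depth[i, j]}"
                for i in range(len(rcm.populations))
            ]
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells) + "\n"
            )


def filter_low_depth_loci(
    rcm: ReadCountMatrix,
    min_depth: int = DEFAULT_MIN_LOCUS_DEPTH,
    max_low_fraction: float = DEFAULT_MAX_LOW_FRACTION,
) -> np.ndarray:
    """Keep-mask over loci for the unreliable-locus rule.

    A locus is dropped when *strictly more than* ``max_low_fraction`` of the
    pools have total depth (ref + alt) *strictly below* ``min_depth``.  Depth
    of evidence is counted over both alleles.
    """
    low = rcm.total_depth < min_depth
    frac_low = low.mean(axis=0)
    return frac_low <= max_low_fraction


def compute_allele_frequencies(
    rcm: ReadCountMatrix, min_call_depth: int = DEFAULT_MIN_CALL_DEPTH
) -> AlleleFrequencyMatrix:
    """Reference-allele frequencies with low-depth calls re-coded as missing.

    af = ref / (ref + alt) where total depth >= ``min_call_depth``; entries
    with fewer reads (including zero depth) are NaN.
    """
    total = rcm.total_depth.astype(float)
    callable_ = total >= min_call_depth
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(callable_, rcm.ref_depth / np.where(total > 0, total, 1.0), np.nan)
    return AlleleFrequencyMatrix(
        populations=list(rcm.populations), loci=list(rcm.loci), af=af
    )


def write_af_matrix(afm: AlleleFrequencyMatrix, path: str) -> None:
    """Write the AF matrix as a tab-separated table (populations x loci)."""
    import pandas as pd

    df = pd.DataFrame(afm.af, index=afm.populations, columns=afm.loci)
    df.index.name = "population"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_af_matrix(path: str) -> AlleleFrequencyMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return AlleleFrequencyMatrix(
        populations=[str(p) for p in df.index],
        loci=[str(c) for c in df.columns],
        af=df.to_numpy(dtype=float),
    )
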