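"""Two-region fragment counting and FPKM quantification for the NEAT1 locus.

The locus is modelled as two adjacent genomic intervals on chr11 (GRCh38):

* the *common* region, shared by both isoforms (default
  chr11:65,422,798-65,426,532, 3,735 bp — the NEAT1_1 transcript), and
* the NEAT1_2-*specific* region immediately downstream (default
  chr11:65,426,533-65,445,540, 19,008 bp).

Paired-end fragments are classified by their template footprint (outermost
span of the read pair, insert gap included).  A fragment overlapping both
regions covers the junction and is ambiguous between "NEAT1_1 3' end" and
"internal NEAT1_2"; such spanning fragments are excluded from both counts.
Counts are converted to FPKM = RMg * 1e9 / (RMt * L), where RMg is the
per-region fragment count, RMt the total mapped fragments in the library,
and L the region length in bp.  Samples with specific-region FPKM >= 1.0
carry appreciable NEAT1_2 and are filtered out when isolating
NEAT1_1-attributable expression.

Coordinates are 1-based inclusive throughout the API; BED I/O converts to
0-based half-open at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pysam

logger = logging.getLogger(__name__)

FragmentLabel = Literal["common", "specific", "spanning", "outside"]

#: Default NEAT1 locus coordinates (GRCh38, 1-based inclusive).
NEAT1_CHROM = "chr11"
NEAT1_COMMON_START = 65_422_798
NEAT1_COMMON_END = 65_426_532
NEAT1_SPECIFIC_START = 65_426_533
NEAT1_SPECIFIC_END = 65_445_540


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """>= 1 bp overlap with the closed interval [start, end]."""
        return chrom == self.chrom and start <= self.end and end >= self.start


@dataclass(frozen=True)
class RegionModel:
    """The two-region locus model: common + isoform-specific intervals.

    The regions must be adjacent on the same contig (``common.end + 1 ==
    specific.start``); the shared boundary is the junction used by the
    spanning-fragment exclusion rule.
    """

    common: GenomicRegion
    specific: GenomicRegion

    def __post_init__(self) -> None:
        if self.common.chrom != self.specific.chrom:
            raise ValueError("common and specific regions must share a contig")
        if self.common.end + 1 != self.specific.start:
            raise ValueError(
                "regions must be adjacent: common.end + 1 must equal "
                f"specific.start (got {self.common.end} + 1 != {self.specific.start})"
            )

    @property
    def chrom(self) -> str:
        return self.common.chrom

    @property
    def L_common(self) -> int:
        return self.common.length

    @property
    def L_specific(self) -> int:
        return self.specific.length

    @property
    def locus_length(self) -> int:
        return self.L_common + self.L_specific

    @property
    def junction(self) -> tuple[int, int]:
        """(last common base, first specific base)."""
        return self.common.end, self.specific.start

    @classmethod
    def default(cls) -> "RegionModel":
        """The NEAT1 locus model from the GRCh38 coordinates."""
        return cls(
            common=GenomicRegion(NEAT1_CHROM, NEAT1_COMMON_START, NEAT1_COMMON_END),
            specific=GenomicRegion(NEAT1_CHROM, NEAT1_SPECIFIC_START, NEAT1_SPECIFIC_END),
        )

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionModel":
        """Load a two-region model from a BED file.

        Expects records named ``common`` and ``specific`` (column 4); BED is
        0-based half-open on disk and converted to 1-based inclusive here.
        """
        regions: dict[str, GenomicRegion] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"BED record needs >= 4 columns: {line!r}")
                chrom, start0, end0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                regions[name] = GenomicRegion(chrom, start0 + 1, end0)
        missing = {"common", "specific"} - regions.keys()
        if missing:
            raise ValueError(f"BED file lacks region(s): {sorted(missing)}")
        return cls(common=regions["common"], specific=regions["specific"])

    def to_bed(self, path: str | Path) -> None:
        """Write the model as 6-column BED (0-based half-open)."""
        with open(path, "w") as fh:
            for name, region in (("common", self.common), ("specific", self.specific)):
                fh.write(
                    f"{region.chrom}\t{region.start - 1}\t{region.end}\t{name}\t0\t+\n"
                )


@dataclass(frozen=True)
class AlignedFragment:
    """One paired-end fragment's genomic footprint.

    ``span_start``/``span_end`` are the outermost template coordinates of
    the pair (1-based inclusive), i.e. the full insert including the
    unsequenced gap between mates.
    """

    chrom: str
    span_start: int
    span_end: int
    is_mapped: bool = True
    is_proper_pair: bool = True

    def __post_init__(self) -> None:
        if self.is_mapped and self.span_start > self.span_end:
            raise ValueError("span_start must be <= span_end for mapped fragments")

    @property
    def length(self) -> int:
        return self.span_end - self.span_start + 1


@dataclass
class RegionCounts:
    """Per-library fragment tallies for the two-region model."""

    rm_common: int = 0
    rm_specific: int = 0
    n_spanning_excluded: int = 0
    rm_total: int = 0
    n_outside: int = 0
    n_unmapped_skipped: int = 0

    def __post_init__(self) -> None:
        if min(self.rm_common, self.rm_specific, self.n_spanning_excluded, self.rm_total) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class SampleQuant:
    """Per-sample FPKM for both regions and the NEAT1_1 eligibility flag."""

    sample_id: str
    counts: RegionCounts
    fpkm_common: float
    fpkm_specific: float
    neat1_1_eligible: bool = field(init=False)

    def __post_init__(self) -> None:
        self.neat1_1_eligible = self.fpkm_specific < 1.0

    @property
    def neat1_1_fpkm(self) -> float:
        """Common-region FPKM, attributable to NEAT1_1 only when eligible."""
        if not self.neat1_1_eligible:
            raise ValueError(
                f"sample {self.sample_id}: specific-region FPKM "
                f"{self.fpkm_specific:.3g} >= 1.0; common-region signal is a "
                "NEAT1_1/NEAT1_2 mixture"
            )
        return self.fpkm_common


def classify_fragment(frag: AlignedFragment, model: RegionModel) -> FragmentLabel:
    """Assign a fragment to ``common``/``specific``/``spanning``/``outside``.

    A fragment overlapping (>= 1 bp, closed intervals) both regions covers
    the junction and is ``spanning``; exactly one region gives that region's
    label; neither (wrong contig or off-locus) gives ``outside``.
    """
    if not frag.is_mapped:
        raise ValueError("cannot classify an unmapped fragment; filter first")
    in_common = model.common.overlaps(frag.chrom, frag.span_start, frag.span_end)
    in_specific = model.specific.overlaps(frag.chrom, frag.span_start, frag.span_end)
    if in_common and in_specific:
        return "spanning"
    if in_common:
        return "common"
    if in_specific:
        return "specific"
    return "outside"


def count_fragments(
    frags: Iterable[AlignedFragment],
    model: RegionModel,
    require_proper_pairs: bool = False,
) -> RegionCounts:
    """Tally fragments per region with the spanning-exclusion rule.

    Every mapped fragment contributes 1 to ``rm_total`` (the library-wide
    RMt of the FPKM formula) regardless of where it maps; junction-spanning
    fragments are excluded from both region counts.  Unmapped fragments are
    skipped and tallied; non-proper pairs are counted unless
    ``require_proper_pairs``.
    """
    counts = RegionCounts()
    for frag in frags:
        if not frag.is_mapped:
            counts.n_unmapped_skipped += 1
            continue
        if require_proper_pairs and not frag.is_proper_pair:
            counts.n_unmapped_skipped += 1
            continue
        counts.rm_total += 1
        label = classify_fragment(frag, model)
        if label == "common":
            counts.rm_common += 1
        elif label == "specific":
            counts.rm_specific += 1
        elif label == "spanning":
            counts.n_spanning_excluded += 1
        else:
            counts.n_outside += 1
    if counts.n_unmapped_skipped:
        logger.info("skipped %d unmapped/filtered fragments", counts.n_unmapped_skipped)
    return counts


def fpkm(rm_g: int, rm_t: int, length_bp: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = RMg * 1e9 / (RMt * L).
    """
    if rm_t <= 0:
        raise ValueError("rm_t (total mapped fragments) must be > 0")
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if rm_g < 0:
        raise ValueError("rm_g must be >= 0")
    return rm_g * 1e9 / (rm_t * length_bp)


def quantify_sample(
    sample_id: str,
    frags: Iterable[AlignedFragment],
    model: RegionModel | None = None,
    require_proper_pairs: bool = False,
) -> SampleQuant:
    """Count fragments and compute both regions' FPKM for one sample."""
    if model is None:
        model = RegionModel.default()
    counts = count_fragments(frags, model, require_proper_pairs=require_proper_pairs)
    return SampleQuant(
        sample_id=sample_id,
        counts=counts,
        fpkm_common=fpkm(counts.rm_common, counts.rm_total, model.L_common),
        fpkm_specific=fpkm(counts.rm_specific, counts.rm_total, model.L_specific),
    )


def select_neat1_1_samples(quants: Sequence[SampleQuant]) -> list[SampleQuant]:
    """Keep samples whose specific-region FPKM < 1.0, preserving order.

    Samples at or above the threshold express NEAT1_2 appreciably, so their
    common-region signal cannot be attributed to NEAT1_1 alone.
    """
    retained = [q for q in quants if q.neat1_1_eligible]
    logger.info(
        "NEAT1_1 filter: retained %d / %d samples (removed %d with specific-region FPKM >= 1.0)",
        len(retained), len(quants), len(quants) - len(retained),
    )
    return retained


# ---------------------------------------------------------------------------
# SAM I/O


def fragments_from_sam(
    path: str | Path,
    min_mapq: int = 0,
) -> Iterator[AlignedFragment]:
    """Yield one fragment per read pair from a SAM/BAM file.

    The footprint is taken from the leftmost read of each pair as
    ``[pos, pos + tlen - 1]`` (template length semantics), so each properly
    formed pair yields exactly one fragment.  Reads without a positive
    template length (unpaired, mate unmapped, or rightmost mate) that are
    not the representative of a counted pair are yielded as single-end
    footprints only when their mate is unmapped.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for read in sam:
            if read.is_secondary or read.is_supplementary:
                continue
            if read.is_unmapped:
                yield AlignedFragment("*", 0, 0, is_mapped=False, is_proper_pair=False)
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_paired and not read.mate_is_unmapped:
                tlen = read.template_length
                if tlen <= 0:
                    # rightmost mate (or degenerate); the leftmost carries the pair
                    continue
                start = read.reference_start + 1  # 1-based
                yield AlignedFragment(
                    chrom=read.reference_name,
                    span_start=start,
                    span_end=start + tlen - 1,
                    is_proper_pair=read.is_proper_pair,
                )
            else:
                yield AlignedFragment(
                    chrom=read.reference_name,
                    span_start=read.reference_start + 1,
                    span_end=read.reference_end,
                    is_proper_pair=False,
                )


def quantify_sam(
    path: str | Path,
    sample_id: str | None = None,
    model: RegionModel | None = None,
    require_proper_pairs: bool = False,
) -> SampleQuant:
    """Quantify a SAM/BAM file end to end."""
    sid = sample_id if sample_id is not None else Path(path).stem
    return quantify_sample(
        sid, fragments_from_sam(path), model=model,
        require_proper_pairs=require_proper_pairs,
    )
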