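"""Synthetic data generators with ground truth for end-to-end validation.

Four generators emulate the data types the analysis modules consume:

* :func:`simulate_locus_fragments` — paired-end fragments from a
  two-isoform locus where the short isoform fully overlaps the long
  isoform's 5' end (a polyA-selected library: coordinates only, no bases).
* :func:`simulate_fish_stack` — two-channel confocal-like z-stacks with
  disc-shaped nuclei in the DAPI channel and punctate Gaussian foci in the
  signal channel.
* :func:`simulate_cohort` — patient tables with an ordinal 0-3 score drawn
  conditionally on clinical strata.
* :func:`simulate_qpcr_plate` — long-format Cq tables with a stable
  three-gene reference panel and known per-sample log2 fold changes.

Every generator takes an explicit seed, is bit-reproducible, and returns a
truth record carrying everything a recovery test needs.  No hidden global
random state is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import tifffile

from neatquant.isoform_quant import AlignedFragment, RegionModel

#: Sentinel contig for fragments mapping outside the modelled locus.  They
#: contribute to the total mapped count (RMt) only.
BACKGROUND_CONTIG = "background"
BACKGROUND_CONTIG_LENGTH = 1_000_000

REFERENCE_GENES = ("GAPDH", "B2M", "RPLP0")


# ---------------------------------------------------------------------------
# Paired-end locus fragments


@dataclass(frozen=True)
class ReadSimParams:
    """Library parameters for the two-isoform locus fragment simulator.

    Defaults follow a typical short-insert Illumina library: 2x48 bp reads,
    insert mean 300 bp, sd 50 bp.
    """

    n_fragments_short_isoform: int
    n_fragments_long_isoform: int
    n_background_fragments: int
    seed: int
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 50.0
    read_length: int = 48

    def __post_init__(self) -> None:
        counts = (
            self.n_fragments_short_isoform,
            self.n_fragments_long_isoform,
            self.n_background_fragments,
        )
        if min(counts) < 0:
            raise ValueError("fragment counts must be >= 0")
        if not (self.fragment_length_mean >= self.read_length >= 1):
            raise ValueError("need fragment_length_mean >= read_length >= 1")
        if self.fragment_length_sd < 0:
            raise ValueError("fragment_length_sd must be >= 0")


def _draw_fragment_lengths(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: int,
    hi: int,
) -> np.ndarray:
    """Truncated-normal insert sizes: redrawn until lo <= length <= hi."""
    out = np.empty(n, dtype=np.int64)
    remaining = np.arange(n)
    while remaining.size:
        draw = np.rint(rng.normal(mean, sd, remaining.size)).astype(np.int64)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def simulate_locus_fragments(
    params: ReadSimParams,
    model: RegionModel | None = None,
) -> tuple[list[AlignedFragment], dict]:
    """Simulate paired-end fragments from the two-isoform locus.

    Short-isoform fragments are placed uniformly (transcript coordinates)
    along the common region only; long-isoform fragments along the full
    contiguous locus (common + specific); background fragments go to a
    sentinel contig and only inflate the total mapped count.  The locus is
    treated as intronless, so transcript and genomic coordinates coincide
    up to the common-region offset.

    Returns the fragments (short, then long, then background — stable
    order) and a truth record with the input counts and seed.
    """
    if model is None:
        model = RegionModel.default()
    if (
        params.n_fragments_short_isoform > 0
        and params.fragment_length_mean > model.L_common
    ):
        raise ValueError(
            f"fragment_length_mean {params.fragment_length_mean} exceeds the "
            f"short-isoform (common-region) length {model.L_common}: "
            "impossible library"
        )
    rng = np.random.default_rng(params.seed)
    frags: list[AlignedFragment] = []

    def _place(n: int, transcript_length: int, genomic_offset: int) -> None:
        if n == 0:
            return
        lengths = _draw_fragment_lengths(
            rng, n, params.fragment_length_mean, params.fragment_length_sd,
            lo=params.read_length, hi=transcript_length,
        )
        # uniform start over all positions where the fragment fits
        starts = rng.integers(1, transcript_length - lengths + 2)
        for s, ln in zip(starts, lengths):
            g = genomic_offset + int(s) - 1
            frags.append(AlignedFragment(model.chrom, g, g + int(ln) - 1))

    _place(params.n_fragments_short_isoform, model.L_common, model.common.start)
    _place(params.n_fragments_long_isoform, model.locus_length, model.common.start)

    for _ in range(params.n_background_fragments):
        ln = int(
            _draw_fragment_lengths(
                rng, 1, params.fragment_length_mean, params.fragment_length_sd,
                lo=params.read_length, hi=BACKGROUND_CONTIG_LENGTH,
            )[0]
        )
        start = int(rng.integers(1, BACKGROUND_CONTIG_LENGTH - ln + 2))
        frags.append(AlignedFragment(BACKGROUND_CONTIG, start, start + ln - 1))

    truth = {
        "n_short": params.n_fragments_short_isoform,
        "n_long": params.n_fragments_long_isoform,
        "n_background": params.n_background_fragments,
        "seed": params.seed,
    }
    return frags, truth


def write_fragments_sam(
    frags: Sequence[AlignedFragment],
    path: str | Path,
    model: RegionModel | None = None,
    read_length: int = 48,
    coordinate_sorted: bool = True,
) -> None:
    """Serialize fragments as properly-paired SAM records.

    Each fragment becomes one read pair: the forward mate starts at the
    fragment's 5' end, the reverse mate ends at its 3' end, and the
    template length equals the fragment footprint.
    """
    if model is None:
        model = RegionModel.default()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if coordinate_sorted else "unsorted"},
        "SQ": [
            {"SN": model.chrom, "LN": model.specific.end + 10_000},
            {"SN": BACKGROUND_CONTIG, "LN": BACKGROUND_CONTIG_LENGTH},
        ],
    }
    records = []
    for i, frag in enumerate(frags):
        if not frag.is_mapped:
            continue
        rlen = min(read_length, frag.length)
        tlen = frag.length
        records.append(
            (frag.chrom, frag.span_start - 1, 99, frag.span_end - rlen, tlen, rlen, i)
        )
        records.append(
            (frag.chrom, frag.span_end - rlen, 147, frag.span_start - 1, -tlen, rlen, i)
        )
    if coordinate_sorted:
        order = {sq["SN"]: j for j, sq in enumerate(header["SQ"])}
        records.sort(key=lambda r: (order[r[0]], r[1]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for chrom, pos, flag, mpos, tlen, rlen, idx in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"frag{idx:07d}"
            a.reference_name = chrom
            a.reference_start = pos
            a.flag = flag
            a.mapping_quality = 60
            a.cigarstring = f"{rlen}M"
            a.next_reference_name = chrom
            a.next_reference_start = mpos
            a.template_length = tlen
            out.write(a)


# ---------------------------------------------------------------------------
# RNA-FISH image stacks


@dataclass(frozen=True)
class FishSimParams:
    """Parameters for the two-channel nuclei-plus-foci stack generator.

    Defaults emulate a 7-slice confocal z-stack of a field of cells at 40x
    (~0.2 um/px): disc-shaped nuclei of 18-26 px radius (~8-10 um
    diameter), diffraction-limited foci (sigma 1.5 px) well above
    background.
    """

    n_nuclei: int
    seed: int
    image_shape: tuple[int, int, int] = (7, 512, 512)
    nucleus_radius_range: tuple[float, float] = (18.0, 26.0)
    foci_per_nucleus: float | Sequence[int] = 4.0
    focus_amplitude: float = 200.0
    focus_sigma: float = 1.5
    dapi_amplitude: float = 150.0
    noise_sd: float = 10.0
    #: minimum center-to-center distance between foci of one nucleus, px.
    #: Closer foci would be indistinguishable in the image itself, leaving
    #: the truth record unrecoverable in principle.
    min_focus_separation: float = 5.0
    max_placement_attempts: int = 1000

    def __post_init__(self) -> None:
        z, y, x = self.image_shape
        if z < 1 or y < 1 or x < 1:
            raise ValueError("image_shape axes must all be >= 1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.focus_amplitude <= 0 or self.dapi_amplitude <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid nucleus_radius_range")


@dataclass
class FishTruth:
    """Ground truth for one simulated stack."""

    centers: list[tuple[float, float]]
    radii: list[float]
    foci_counts: list[int]
    label_mask: np.ndarray  # (y, x) int32, 0 = background, 1..K per nucleus

    def to_json_dict(self) -> dict:
        return {
            "centers": [list(c) for c in self.centers],
            "radii": self.radii,
            "foci_counts": self.foci_counts,
        }


def _place_nuclei(
    rng: np.random.Generator,
    n: int,
    shape_yx: tuple[int, int],
    radius_range: tuple[float, float],
    max_attempts: int,
) -> tuple[list[tuple[float, float]], list[float]]:
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    h, w = shape_yx
    for _ in range(n):
        for attempt in range(max_attempts):
            r = float(rng.uniform(*radius_range))
            cy = float(rng.uniform(r + 1, h - r - 1))
            cx = float(rng.uniform(r + 1, w - r - 1))
            # keep a 2 px guard band so segmentation sees separate objects
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad + 2.0) ** 2
                for (oy, ox), orad in zip(centers, radii)
            ):
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {len(centers) + 1}/{n} without "
                f"overlap in {max_attempts} attempts; reduce n_nuclei or radii"
            )
    return centers, radii


def simulate_fish_stack(params: FishSimParams) -> tuple[np.ndarray, np.ndarray, FishTruth]:
    """Simulate a two-channel (DAPI, signal) z-stack.

    The DAPI channel holds constant-amplitude discs replicated over z; the
    signal channel holds, inside each nucleus, its drawn number of 2-D
    Gaussian foci each confined to one random z slice.  Additive Gaussian
    noise (clipped at zero) is applied to both channels.

    Returns ``(dapi, signal, truth)`` with float32 arrays of shape (z, y, x).
    """
    rng = np.random.default_rng(params.seed)
    z, h, w = params.image_shape
    centers, radii = _place_nuclei(
        rng, params.n_nuclei, (h, w), params.nucleus_radius_range,
        params.max_placement_attempts,
    )

    yy, xx = np.mgrid[0:h, 0:w]
    label_mask = np.zeros((h, w), dtype=np.int32)
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        label_mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = k

    dapi2d = np.where(label_mask > 0, params.dapi_amplitude, 0.0).astype(np.float64)
    dapi = np.repeat(dapi2d[None], z, axis=0)
    signal = np.zeros((z, h, w), dtype=np.float64)

    if isinstance(params.foci_per_nucleus, (int, float)):
        foci_counts = rng.poisson(float(params.foci_per_nucleus), params.n_nuclei).tolist()
    else:
        if len(params.foci_per_nucleus) != params.n_nuclei:
            raise ValueError("explicit foci counts must have one entry per nucleus")
        foci_counts = [int(c) for c in params.foci_per_nucleus]

    for (cy, cx), r, n_foci in zip(centers, radii, foci_counts):
        placed: list[tuple[float, float]] = []
        for _ in range(n_foci):
            for attempt in range(params.max_placement_attempts):
                # foci stay inside the nucleus with a margin of 3 sigma
                rho = np.sqrt(rng.uniform()) * max(r - 3 * params.focus_sigma, 0.0)
                theta = rng.uniform(0, 2 * np.pi)
                fy, fx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
                if all(
                    (fy - py) ** 2 + (fx - px) ** 2 >= params.min_focus_separation**2
                    for py, px in placed
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_foci} foci at separation "
                    f"{params.min_focus_separation} px inside a radius-{r:.0f} nucleus"
                )
            placed.append((fy, fx))
            fz = int(rng.integers(0, z))
            g = params.focus_amplitude * np.exp(
                -((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * params.focus_sigma**2)
            )
            signal[fz] += g

    if params.noise_sd > 0:
        dapi = dapi + rng.normal(0, params.noise_sd, dapi.shape)
        signal = signal + rng.normal(0, params.noise_sd, signal.shape)
    dapi = np.clip(dapi, 0, None).astype(np.float32)
    signal = np.clip(signal, 0, None).astype(np.float32)

    truth = FishTruth(centers=centers, radii=radii, foci_counts=foci_counts,
                      label_mask=label_mask)
    return dapi, signal, truth


def write_fish_stack(
    dapi: np.ndarray,
    signal: np.ndarray,
    path: str | Path,
    truth: FishTruth | None = None,
) -> None:
    """Write a channel-major (2, z, y, x) multi-page TIFF plus JSON truth sidecar."""
    stack = np.stack([dapi, signal]).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")
    if truth is not None:
        sidecar = Path(path).with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truth.to_json_dict(), indent=1))


def read_fish_stack(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a channel-major two-channel TIFF back as (dapi, signal)."""
    stack = tifffile.imread(str(path))
    if stack.ndim != 4 or stack.shape[0] != 2:
        raise ValueError(f"expected a (2, z, y, x) stack, got shape {stack.shape}")
    return stack[0], stack[1]


# ---------------------------------------------------------------------------
# Cohorts


#: Default conditional score distributions: histologic-grade strata with
#: probabilities equal to the screening cohort's observed row proportions
#: (grade 1: n=18, grade 2: n=23, grade 3: n=33 of 74 patients).
GRADE_SCORE_PROBABILITIES: dict[str, Sequence[float]] = {
    "grade1": (10 / 18, 5 / 18, 3 / 18, 0 / 18),
    "grade2": (8 / 23, 9 / 23, 5 / 23, 1 / 23),
    "grade3": (7 / 33, 6 / 33, 15 / 33, 5 / 33),
}
GRADE_STRATUM_WEIGHTS: dict[str, float] = {
    "grade1": 18 / 74,
    "grade2": 23 / 74,
    "grade3": 33 / 74,
}


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters for the conditional-score cohort generator.

    ``conditional_score_probabilities`` maps each stratum label (e.g. a
    grade level or HER2 status) to a probability vector over scores 0-3;
    ``stratum_weights`` gives the marginal stratum distribution (uniform
    when omitted).
    """

    n_patients: int
    seed: int
    conditional_score_probabilities: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(GRADE_SCORE_PROBABILITIES)
    )
    stratum_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not self.conditional_score_probabilities:
            raise ValueError("need at least one stratum")
        for stratum, probs in self.conditional_score_probabilities.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (4,) or (p < 0).any():
                raise ValueError(f"stratum {stratum!r}: need 4 nonnegative probabilities")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"stratum {stratum!r}: probabilities must sum to 1")
        if self.stratum_weights is not None:
            unknown = set(self.stratum_weights) - set(self.conditional_score_probabilities)
            if unknown:
                raise KeyError(f"unknown stratum key(s): {sorted(unknown)}")


def simulate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Draw a patient table with scores conditional on stratum.

    Returns a DataFrame with columns ``patient_id``, ``stratum``, ``score``.
    """
    rng = np.random.default_rng(params.seed)
    strata = list(params.conditional_score_probabilities)
    if params.stratum_weights is None:
        weights = np.full(len(strata), 1 / len(strata))
    else:
        weights = np.array([params.stratum_weights.get(s, 0.0) for s in strata], dtype=float)
        weights = weights / weights.sum()
    assigned = rng.choice(len(strata), size=params.n_patients, p=weights)
    scores = np.empty(params.n_patients, dtype=np.int64)
    for i, s_idx in enumerate(assigned):
        p = np.asarray(params.conditional_score_probabilities[strata[s_idx]], dtype=float)
        scores[i] = rng.choice(4, p=p / p.sum())
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(params.n_patients)],
            "stratum": [strata[i] for i in assigned],
            "score": scores,
        }
    )


# ---------------------------------------------------------------------------
# qPCR plates


@dataclass(frozen=True)
class QpcrSimParams:
    """Parameters for the Cq-plate generator.

    ``true_log2_fold_changes`` maps sample name to its log2 fold change of
    the target gene relative to the calibrator sample (the calibrator is
    implicitly 0 and is always emitted).  Reference genes sit at stable
    per-gene Cq means.  Optional per-sample input-amount shifts are applied
    to every gene of a sample and should cancel under normalization.
    """

    true_log2_fold_changes: Mapping[str, float]
    seed: int
    calibrator: str = "MCF7"
    target_gene: str = "NEAT1_2"
    calibrator_target_cq: float = 28.0
    reference_cq_means: Mapping[str, float] = field(
        default_factory=lambda: {"GAPDH": 18.0, "B2M": 20.0, "RPLP0": 22.0}
    )
    cq_noise_sd: float = 0.0
    sample_shift_sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.cq_noise_sd < 0 or self.sample_shift_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.calibrator in self.true_log2_fold_changes:
            raise ValueError("the calibrator's fold change is fixed at 0; do not list it")


def simulate_qpcr_plate(params: QpcrSimParams) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format Cq table (sample, gene, replicate, cq).

    A target-gene Cq one cycle lower than the calibrator's means twice the
    expression, so Cq_target(sample) = Cq_target(calibrator) - log2 fold
    change (+ noise).  Returns the table and a truth record of the fold
    changes.
    """
    rng = np.random.default_rng(params.seed)
    samples = [params.calibrator] + list(params.true_log2_fold_changes)
    lfc = {params.calibrator: 0.0, **params.true_log2_fold_changes}
    rows = []
    for sample in samples:
        shift = rng.normal(0, params.sample_shift_sd) if params.sample_shift_sd else 0.0
        gene_cq = {params.target_gene: params.calibrator_target_cq - lfc[sample]}
        gene_cq.update(params.reference_cq_means)
        for gene, base in gene_cq.items():
            for rep in range(1, params.n_replicates + 1):
                noise = rng.normal(0, params.cq_noise_sd) if params.cq_noise_sd else 0.0
                rows.append((sample, gene, rep, base + shift + noise))
    table = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "cq"])
    truth = {
        "true_log2_fold_changes": dict(lfc),
        "calibrator": params.calibrator,
        "target_gene": params.target_gene,
        "seed": params.seed,
    }
    return table, truth
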