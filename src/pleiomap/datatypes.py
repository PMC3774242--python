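"""Shared containers for maps, panels, scan profiles and result records.

Genotypes in biparental RIL panels are coded ``1.0`` for the parent-A
homozygote, ``0.0`` for the parent-B homozygote and ``nan`` for missing.
Accession-panel SNPs are haploid-coded ``0/1`` (inbred accessions) with
``nan`` for missing calls.  Map positions are chromosome-local cM;
physical coordinates are 1-based bp (VCF convention).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class PleiomapError(ValueError):
    """Base class for input/configuration errors raised by this package."""


# ---------------------------------------------------------------------------
# linkage map / RIL containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: per chromosome, marker names and increasing cM."""

    chrom_names: tuple[str, ...]
    marker_names: tuple[tuple[str, ...], ...]
    positions_cM: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if not (len(self.chrom_names) == len(self.marker_names) == len(self.positions_cM)):
            raise PleiomapError("chromosome/marker/position lists differ in length")
        for c, names, pos in zip(self.chrom_names, self.marker_names, self.positions_cM):
            if len(names) != len(pos) or len(names) == 0:
                raise PleiomapError(f"chromosome {c}: empty or mismatched marker list")
            d = np.diff(pos)
            if len(d) and not np.all(d > 0):
                bad = int(np.argmax(d <= 0)) + 1
                raise PleiomapError(
                    f"chromosome {c}: positions not strictly increasing at marker "
                    f"{names[bad]!r} ({pos[bad]} cM)"
                )

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_names)

    @property
    def n_markers(self) -> int:
        return sum(len(m) for m in self.marker_names)

    def chrom_slices(self) -> dict[str, slice]:
        """Column slice of the flat marker axis for each chromosome."""
        out, start = {}, 0
        for c, names in zip(self.chrom_names, self.marker_names):
            out[c] = slice(start, start + len(names))
            start += len(names)
        return out


@dataclass
class RILPanel:
    """Line × marker genotype matrix plus line-keyed phenotypes."""

    line_ids: list[str]
    genotypes: np.ndarray            # n_lines × n_markers, values {0., 1., nan}
    gmap: GeneticMap
    phenotypes: pd.DataFrame         # indexed by line id

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.line_ids):
            raise PleiomapError("genotype rows != number of line ids")
        if m != self.gmap.n_markers:
            raise PleiomapError("genotype columns != number of map markers")
        vals = self.genotypes[~np.isnan(self.genotypes)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise PleiomapError("RIL genotypes must be coded 0/1/nan")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


@dataclass
class PseudoMarkerGrid:
    """Even scan grid covering every chromosome, retaining all true markers."""

    chrom: np.ndarray        # chromosome label per grid position
    pos: np.ndarray          # cM, chromosome-local
    is_marker: np.ndarray    # bool: grid point is a genotyped marker
    marker_col: np.ndarray   # flat marker-column index, -1 at pseudo-markers
    chrom_names: tuple[str, ...]

    @property
    def n_positions(self) -> int:
        return self.pos.size

    def chrom_index(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == name)


@dataclass
class GenotypeProbabilities:
    """P(parent-A homozygote) per line at every grid position."""

    grid: PseudoMarkerGrid
    probs: np.ndarray        # n_lines × n_positions, in [0, 1]
    n_uninformative: int = 0  # (line, chromosome) pairs that fell back to 0.5


@dataclass
class LODProfile:
    """Per-position LOD scores for one trait on a pseudo-marker grid."""

    trait: str
    grid: PseudoMarkerGrid
    lod: np.ndarray
    n_lines: int

    @property
    def max_lod(self) -> float:
        return float(self.lod.max()) if self.lod.size else 0.0

    @property
    def argmax(self) -> tuple[str, float]:
        i = int(np.argmax(self.lod))          # first occurrence = lowest (chrom, pos)
        return str(self.grid.chrom[i]), float(self.grid.pos[i])


@dataclass
class QTL:
    chrom: str
    pos_cM: float
    effect: float = float("nan")       # parent-A allele substitution, trait units
    pve: float = float("nan")          # percent variance explained, [0, 100]
    drop_one_lod: float = float("nan")


@dataclass
class QTLModel:
    qtls: list[QTL]
    model_lod: float = 0.0
    penalized_lod: float = 0.0
    model_pve: float = 0.0
    penalty: float = 0.0

    @property
    def size(self) -> int:
        return len(self.qtls)


@dataclass
class BivariateProfile:
    """Summed standardized two-trait LOD profile with joint peak/interval."""

    grid: PseudoMarkerGrid
    traits: tuple[str, str]
    stand_lod: np.ndarray            # 2 × n_positions, each row max = 1
    raw_lod: np.ndarray              # 2 × n_positions (kept for the literal rule)
    summed: np.ndarray               # S(x) in [0, n_traits]
    peak_index: int
    interval: tuple[str, float, float] | None = None
    interval_rule: str | None = None

    @property
    def peak(self) -> tuple[str, float]:
        return (str(self.grid.chrom[self.peak_index]),
                float(self.grid.pos[self.peak_index]))


# ---------------------------------------------------------------------------
# accession panel containers
# ---------------------------------------------------------------------------

LABEL_FUNCTIONAL = 1
LABEL_NULL = 0
LABEL_UNKNOWN = -1


@dataclass
class SNPPanel:
    """Accession × SNP biallelic panel with class labels and geography."""

    accession_ids: list[str]
    chrom: np.ndarray                # per SNP
    pos: np.ndarray                  # per SNP, 1-based bp
    genotypes: np.ndarray            # n_accessions × n_snps, {0., 1., nan}
    labels: np.ndarray               # per accession: 1 functional, 0 null, -1 unknown
    clusters: np.ndarray | None = None   # geographic cluster id per accession
    coords: np.ndarray | None = None     # n_accessions × 2 (lat, lon)
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.accession_ids):
            raise PleiomapError("genotype rows != accession ids")
        if m != self.chrom.size or m != self.pos.size:
            raise PleiomapError("SNP metadata length != genotype columns")
        if self.labels.size != n:
            raise PleiomapError("labels length != accessions")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and np.any(np.diff(p) < 0):
                raise PleiomapError(f"chromosome {c}: SNP positions not sorted")
        if self.snp_ids is None:
            self.snp_ids = np.array(
                [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return self.pos.size

    def subset_snps(self, idx: np.ndarray) -> "SNPPanel":
        return SNPPanel(
            accession_ids=self.accession_ids,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            genotypes=self.genotypes[:, idx],
            labels=self.labels,
            clusters=self.clusters,
            coords=self.coords,
            snp_ids=None if self.snp_ids is None else self.snp_ids[idx],
        )

    def subset_accessions(self, idx: np.ndarray) -> "SNPPanel":
        return SNPPanel(
            accession_ids=[self.accession_ids[i] for i in np.atleast_1d(idx)],
            chrom=self.chrom,
            pos=self.pos,
            genotypes=self.genotypes[idx],
            labels=self.labels[idx],
            clusters=None if self.clusters is None else self.clusters[idx],
            coords=None if self.coords is None else self.coords[idx],
            snp_ids=self.snp_ids,
        )


@dataclass
class ClimateTable:
    """Per-accession climate variables plus the focal class label."""

    values: pd.DataFrame             # indexed by accession id, one column per variable
    labels: np.ndarray               # aligned with values.index

    def __post_init__(self) -> None:
        if len(self.values) != self.labels.size:
            raise PleiomapError("climate rows != labels")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    per_snp: np.ndarray              # raw per-SNP FST (negatives kept)
    mean_fst: float
    estimator: str
    n_snps_used: int
    n_snps_skipped: int
    meta: dict = field(default_factory=dict)


@dataclass
class ResamplingNull:
    """Observed statistic against K resampled statistics.

    p-value uses the (1 + #{resample >= observed}) / (K + 1) convention,
    so it is never zero.
    """

    observed: float
    resamples: np.ndarray
    seed: int
    statistic: str = "mean_fst"

    @property
    def K(self) -> int:
        return self.resamples.size

    @property
    def p_value(self) -> float:
        b = int(np.sum(self.resamples >= self.observed))
        return (1 + b) / (self.K + 1)


@dataclass
class FeatureWindow:
    """SNP features within a window around the focal locus."""

    focal_chrom: str
    focal_pos: int
    half_span_bp: int
    snp_ids: np.ndarray
    snp_pos: np.ndarray
    X: np.ndarray                    # n_accessions × n_window_snps, missing filled
    accession_ids: list[str]
    n_missing_filled: int = 0
    all_missing_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class CVReport:
    protocol: str
    fold_accuracies: list[float]
    mean_accuracy: float
    n: int
    repeats: int
    seed: int
    details: dict = field(default_factory=dict)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    pve: float                       # percent, R^2 x 100


# ---------------------------------------------------------------------------
# ground truth for simulated data
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth emitted alongside every simulated dataset."""

    kind: str                                  # "ril" | "panel"
    seed: int
    qtls: list[dict] = field(default_factory=list)
    focal_labels: list[int] = field(default_factory=list)
    differentiated_snps: list[int] = field(default_factory=list)
    truncated_snps: list[int] = field(default_factory=list)
    climate_shifts: list[float] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


def _as_float_array(x: Sequence[float]) -> np.ndarray:
    return np.asarray(x, dtype=float)
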