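"""Synthetic data generators with known ground truth.

Two generators cover the pipeline's inputs:

* :func:`simulate_ril_panel` — a biparental recombinant-inbred-line (RIL)
  population segregating a pleiotropic QTL plus trait-specific QTLs.
  Genotypes are simulated directly at the RIL scale as a two-state Markov
  chain along each chromosome: for adjacent loci d cM apart the meiotic
  recombination fraction is the inverse Haldane value
  r = (1 - exp(-2 d / 100)) / 2 and the chain switches parental state with
  the map-expanded probability R = 2 r / (1 + 2 r), the fixed point of
  recurrent selfing.  This is marginally equivalent to simulating the
  selfing generations explicitly and has closed-form oracles.

* :func:`simulate_accession_panel` — a panel of inbred natural accessions
  with a biallelic functionality locus, tag SNPs in tunable LD inside a
  window around the locus, genome-wide SNPs whose class-specific
  frequencies are calibrated to a target Nei FST, geographic clusters and
  climate variables shifted between classes.

Every generator returns a :class:`~pleiomap.datatypes.TruthRecord` so that
downstream stages can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ClimateTable,
    GeneticMap,
    PleiomapError,
    RILPanel,
    SNPPanel,
    TruthRecord,
)

__all__ = [
    "RILSimConfig",
    "PanelSimConfig",
    "simulate_ril_panel",
    "simulate_accession_panel",
    "additive_effect_for_pve",
    "haldane_r",
    "ril_recombination_fraction",
]


def haldane_r(d_cM: float | np.ndarray) -> np.ndarray:
    """Meiotic recombination fraction for a Haldane (no-interference) map."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ril_recombination_fraction(d_cM: float | np.ndarray) -> np.ndarray:
    """Observed recombination fraction between RILs at meiotic distance d.

    Map expansion under recurrent selfing: R = 2r / (1 + 2r).
    """
    r = haldane_r(d_cM)
    return 2.0 * r / (1.0 + 2.0 * r)


def additive_effect_for_pve(pve: float, background_var: float = 1.0) -> float:
    """Allele-substitution effect giving a target variance fraction.

    A biallelic locus at frequency 1/2 with substitution effect ``a``
    contributes variance a^2/4; solving a^2/4 / (a^2/4 + V_bg) = pve gives
    ``a = 2 sqrt(pve/(1-pve) * V_bg)``.
    """
    if not 0 <= pve < 1:
        raise PleiomapError(f"pve must be in [0, 1), got {pve}")
    return 2.0 * math.sqrt(pve / (1.0 - pve) * background_var)


# effects for the default cross: shared QTL explaining ~25%/15% of the two
# traits plus one smaller specific QTL per trait (~8%)
_SHARED_T1 = additive_effect_for_pve(0.25)
_SHARED_T2 = additive_effect_for_pve(0.15)
_SPECIFIC = additive_effect_for_pve(0.08)


@dataclass
class RILSimConfig:
    """Configuration of the synthetic biparental RIL cross.

    Defaults emulate a 343-line F9 population genotyped at 166 markers on
    five ~85 cM chromosomes, segregating one pleiotropic QTL (near the top
    of chromosome 4, affecting both traits) and one specific QTL per trait.
    Effects are expressed as parent-A allele substitution in phenotype
    units; with unit residual SD the defaults give the shared locus ~25%
    and ~15% of the two traits' variance.
    """

    n_lines: int = 343
    chromosome_lengths_cM: tuple[float, ...] = (85.0, 85.0, 85.0, 85.0, 85.0)
    n_markers_per_chrom: tuple[int, ...] = (34, 33, 33, 33, 33)
    # (chromosome name, position cM, effect trait1, effect trait2)
    qtl_specs: tuple[tuple[str, float, float, float], ...] = (
        ("4", 4.0, _SHARED_T1, _SHARED_T2),
        ("1", 50.0, _SPECIFIC, 0.0),
        ("2", 30.0, 0.0, _SPECIFIC),
    )
    residual_sd: tuple[float, float] = (1.0, 1.0)
    # correlation between the two traits' residuals: shared physiology not
    # attributable to the simulated QTLs.  The default, combined with the
    # default QTL effects, puts the line-mean trait correlation near 0.37
    # (r^2 ~ 0.14), typical of water-use-efficiency/flowering-time RILs.
    residual_correlation: float = 0.25
    polygenic_sd: tuple[float, float] = (0.0, 0.0)
    missing_rate: float = 0.0        # residual-heterozygosity calls, set missing
    trait_names: tuple[str, str] = ("WUE", "FT")
    # leaf-area phenotypes for the growth-rate stage
    leaf_area_days: tuple[float, float] = (14.0, 21.0)
    growth_rate_qtl_effect: float = -0.01   # parent-A effect on GR_la (per day)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2:
            raise PleiomapError("n_lines must be >= 2")
        if len(self.chromosome_lengths_cM) != len(self.n_markers_per_chrom):
            raise PleiomapError("chromosome length / marker count mismatch")
        if any(L <= 0 for L in self.chromosome_lengths_cM):
            raise PleiomapError("chromosome lengths must be positive")
        if any(m < 1 for m in self.n_markers_per_chrom):
            raise PleiomapError("each chromosome needs >= 1 marker")
        chrom_names = [str(i + 1) for i in range(len(self.chromosome_lengths_cM))]
        for c, p, e1, e2 in self.qtl_specs:
            if str(c) not in chrom_names:
                raise PleiomapError(f"QTL chromosome {c!r} not in map")
            L = self.chromosome_lengths_cM[chrom_names.index(str(c))]
            if not 0 <= p <= L:
                raise PleiomapError(f"QTL position {p} outside chromosome {c} (0..{L})")
            if not (np.isfinite(e1) and np.isfinite(e2)):
                raise PleiomapError("QTL effects must be finite")
        for v in (*self.residual_sd, *self.polygenic_sd):
            if not np.isfinite(v) or v < 0:
                raise PleiomapError("residual/polygenic SDs must be finite and >= 0")
        if not -1 <= self.residual_correlation <= 1:
            raise PleiomapError("residual_correlation must be in [-1, 1]")
        if not 0 <= self.missing_rate < 1:
            raise PleiomapError("missing_rate must be in [0, 1)")


def _simulate_chain(rng: np.random.Generator, n_lines: int,
                    positions: np.ndarray) -> np.ndarray:
    """RIL genotypes along one chromosome (two-state Markov chain)."""
    n_loci = positions.size
    g = np.empty((n_lines, n_loci), dtype=float)
    g[:, 0] = rng.random(n_lines) < 0.5
    if n_loci > 1:
        R = ril_recombination_fraction(np.diff(positions))
        switch = rng.random((n_lines, n_loci - 1)) < R[None, :]
        # cumulative XOR of switches propagates the initial state
        flips = np.cumsum(switch, axis=1) % 2
        g[:, 1:] = np.abs(g[:, [0]] - flips)
    return g


def simulate_ril_panel(config: RILSimConfig) -> tuple[GeneticMap, RILPanel, TruthRecord]:
    """Simulate a biparental RIL population with known QTLs.

    Phenotype for each trait = sum of QTL substitution effects applied to
    centered genotypes + optional polygenic term + Gaussian residual.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = tuple(str(i + 1) for i in range(len(config.chromosome_lengths_cM)))

    marker_names, marker_pos = [], []
    geno_cols = []
    qtl_geno = {}            # (chrom, pos) -> genotype vector
    for c, (L, m) in zip(chrom_names,
                         zip(config.chromosome_lengths_cM, config.n_markers_per_chrom)):
        mpos = np.linspace(0.0, L, m) if m > 1 else np.array([L / 2.0])
        qpos = sorted({p for (qc, p, *_e) in config.qtl_specs if str(qc) == c})
        all_pos = np.unique(np.concatenate([mpos, np.asarray(qpos, dtype=float)]))
        g = _simulate_chain(rng, config.n_lines, all_pos)
        is_marker = np.isin(all_pos, mpos)
        geno_cols.append(g[:, is_marker])
        for p in qpos:
            qtl_geno[(c, float(p))] = g[:, np.searchsorted(all_pos, p)]
        marker_names.append(tuple(f"m{c}_{k + 1}" for k in range(m)))
        marker_pos.append(tuple(float(p) for p in mpos))

    gmap = GeneticMap(chrom_names, tuple(marker_names), tuple(marker_pos))
    G = np.concatenate(geno_cols, axis=1)

    # phenotypes: QTL effects on centered genotype + polygenic + residual
    n = config.n_lines
    traits = np.zeros((n, 2))
    for qc, qp, e1, e2 in config.qtl_specs:
        g = qtl_geno[(str(qc), float(qp))] - 0.5
        traits[:, 0] += e1 * g
        traits[:, 1] += e2 * g
    for t in range(2):
        if config.polygenic_sd[t] > 0:
            w = rng.normal(size=G.shape[1])
            z = (G - 0.5) @ w
            sd = z.std()
            if sd > 0:
                traits[:, t] += config.polygenic_sd[t] * z / sd
    rho = config.residual_correlation
    e = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    traits += e * np.asarray(config.residual_sd)[None, :]

    # leaf areas consistent with a growth-rate phenotype sharing the main QTL
    t1, t2 = config.leaf_area_days
    shared = config.qtl_specs[0] if config.qtl_specs else None
    gr = np.full(n, 0.10)
    if shared is not None:
        gr += config.growth_rate_qtl_effect * (qtl_geno[(str(shared[0]), float(shared[1]))] - 0.5)
    gr += rng.normal(scale=0.005, size=n)
    la1 = np.exp(rng.normal(loc=0.0, scale=0.1, size=n))
    la2 = la1 * np.exp(gr * (t2 - t1))

    if config.missing_rate > 0:
        # residual F9 heterozygosity: called het, then set missing
        miss = rng.random(G.shape) < config.missing_rate
        G = G.copy()
        G[miss] = np.nan

    line_ids = [f"RIL{i + 1:03d}" for i in range(n)]
    phen = pd.DataFrame(
        {
            config.trait_names[0]: traits[:, 0],
            config.trait_names[1]: traits[:, 1],
            "LA_t1": la1,
            "LA_t2": la2,
        },
        index=pd.Index(line_ids, name="id"),
    )
    panel = RILPanel(line_ids, G, gmap, phen)
    truth = TruthRecord(
        kind="ril",
        seed=config.seed,
        qtls=[
            {"chrom": str(c), "pos_cM": float(p),
             "effect_trait1": float(e1), "effect_trait2": float(e2)}
            for c, p, e1, e2 in config.qtl_specs
        ],
        extra={"trait_names": list(config.trait_names),
               "leaf_area_days": list(config.leaf_area_days),
               "growth_rate_qtl_effect": config.growth_rate_qtl_effect},
    )
    return gmap, panel, truth


# ---------------------------------------------------------------------------
# accession panel
# ---------------------------------------------------------------------------

@dataclass
class PanelSimConfig:
    """Configuration of the synthetic natural-accession panel.

    Defaults emulate a few-hundred-accession inbred panel: a biallelic
    functionality locus at ~270 kb on chromosome 4, 50 tag SNPs within
    ±100 kb of it at per-SNP r² = 0.5 with the functionality label
    (routed through a shared latent haplotype, so window classifiers
    saturate near the haplotype fidelity rather than at 100%),
    genome-wide SNPs whose class frequencies are calibrated to a target
    Nei FST of 0.05, 11 geographic clusters and 19 climate variables
    shifted by half a standard deviation between classes.
    """

    n_accessions: int = 317
    focal_allele_frequency: float = 0.5      # P(functional)
    focal_chrom: str = "4"
    focal_pos_bp: int = 270_000
    n_window_snps: int = 50
    window_span_bp: int = 100_000
    tag_ld_r2: float = 0.5                   # per-SNP r² with the focal label
    n_genome_snps: int = 10_000
    snp_spacing_bp: int = 1_000
    fst_between_classes: float = 0.05
    base_freq_range: tuple[float, float] = (0.25, 0.75)
    n_chromosomes: int = 5
    n_geo_clusters: int = 11
    n_climate_vars: int = 19
    climate_effect: float = 0.5              # class mean shift, SD units
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 4:
            raise PleiomapError("n_accessions must be >= 4")
        if not 0 < self.focal_allele_frequency < 1:
            raise PleiomapError("focal_allele_frequency must be in (0, 1)")
        if not 0 <= self.tag_ld_r2 <= 1:
            raise PleiomapError(
                f"tag_ld_r2 must be in [0, 1], got {self.tag_ld_r2}"
            )
        if not 0 <= self.fst_between_classes < 1:
            raise PleiomapError(
                "fst_between_classes must be in [0, 1); the symmetric "
                "frequency split cannot exceed FST = 1"
            )
        lo, hi = self.base_freq_range
        if not 0 < lo <= hi < 1:
            raise PleiomapError("base_freq_range must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.missing_rate < 1:
            raise PleiomapError("missing_rate must be in [0, 1)")
        for name in ("n_window_snps", "window_span_bp", "n_genome_snps",
                     "snp_spacing_bp", "n_geo_clusters", "n_climate_vars"):
            if getattr(self, name) < 0:
                raise PleiomapError(f"{name} must be non-negative")


def fst_frequency_split(p: np.ndarray, fst: float) -> tuple[np.ndarray, np.ndarray]:
    """Class frequencies (p + delta, p - delta) hitting a target Nei FST.

    For the symmetric split, Ht = 2 p (1 - p), Hs = Ht - 2 delta², so
    FST = delta² / (p (1 - p)) and delta = sqrt(FST p (1 - p)).  SNPs where
    p ± delta leaves [0, 1] are truncated to the boundary and flagged.

    Returns (p1, p2) and stores nothing; truncation is detectable as
    delta_effective < delta_requested.
    """
    p = np.asarray(p, dtype=float)
    delta = np.sqrt(fst * p * (1.0 - p))
    return np.clip(p + delta, 0.0, 1.0), np.clip(p - delta, 0.0, 1.0)


def simulate_accession_panel(
    config: PanelSimConfig,
) -> tuple[SNPPanel, ClimateTable, TruthRecord]:
    """Simulate an accession panel, its climate table and the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions

    # focal functionality label (guarantee both classes occupied)
    y = (rng.random(n) < config.focal_allele_frequency).astype(int)
    if y.sum() == 0:
        y[rng.integers(n)] = 1
    elif y.sum() == n:
        y[rng.integers(n)] = 0

    # --- window SNPs tag the focal allele through a shared haplotype:
    # a latent haplotype h copies the label with prob b, and each window
    # SNP copies h with prob a (otherwise an independent draw at the focal
    # frequency, which preserves allele frequencies).  corr(snp, label) =
    # a·b, so a = b = tag_ld_r2**(1/4) gives each SNP the requested r²
    # while capping the information any number of window SNPs can carry at
    # the haplotype→label fidelity — as in real LD blocks, where tags share
    # one recombination history rather than informing independently.
    ab = config.tag_ld_r2 ** 0.25
    m_w = config.n_window_snps
    f = config.focal_allele_frequency
    copy_h = rng.random(n) < ab
    h = np.where(copy_h, y.astype(float), (rng.random(n) < f).astype(float))
    copy_s = rng.random((n, m_w)) < ab
    indep = (rng.random((n, m_w)) < f).astype(float)
    Gw = np.where(copy_s, h[:, None], indep)
    lo = max(1, config.focal_pos_bp - config.window_span_bp)
    hi = config.focal_pos_bp + config.window_span_bp
    wpos = np.sort(rng.choice(np.arange(lo, hi + 1), size=m_w, replace=False)) if m_w else np.array([], dtype=int)

    # --- genome SNPs with class-differentiated frequencies
    m_g = config.n_genome_snps
    p_base = rng.uniform(*config.base_freq_range, size=m_g)
    p1, p2 = fst_frequency_split(p_base, config.fst_between_classes)
    delta_req = np.sqrt(config.fst_between_classes * p_base * (1 - p_base))
    truncated = np.flatnonzero(
        (p_base + delta_req > 1 + 1e-12) | (p_base - delta_req < -1e-12)
    )
    pm = np.where(y[:, None] == 1, p1[None, :], p2[None, :])
    Gg = (rng.random((n, m_g)) < pm).astype(float)
    # spread genome SNPs over chromosomes, spacing ~ Exponential(mean spacing)
    per_chrom = np.array_split(np.arange(m_g), max(config.n_chromosomes, 1))
    gchrom = np.empty(m_g, dtype=object)
    gpos = np.empty(m_g, dtype=int)
    for ci, idx in enumerate(per_chrom):
        gchrom[idx] = str(ci + 1)
        gaps = rng.exponential(scale=max(config.snp_spacing_bp, 1), size=idx.size)
        gpos[idx] = 1_000_000 + np.cumsum(np.maximum(gaps, 1.0)).astype(int)

    chrom = np.concatenate([np.full(m_w, config.focal_chrom, dtype=object), gchrom])
    pos = np.concatenate([wpos, gpos])
    G = np.concatenate([Gw, Gg], axis=1)

    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G = G.copy()
        G[miss] = np.nan

    # sort SNPs by (chromosome, position)
    order = np.lexsort((pos, chrom.astype(str)))
    chrom, pos, G = chrom[order], pos[order], G[:, order]
    window_idx = np.flatnonzero(np.isin(order, np.arange(m_w)))
    genome_idx = np.flatnonzero(order >= m_w)
    trunc_sorted = np.flatnonzero(np.isin(order, truncated + m_w))

    # geographic clusters and coordinates
    k = max(config.n_geo_clusters, 1)
    clusters = rng.integers(k, size=n)
    centers = np.column_stack([rng.uniform(35, 60, size=k), rng.uniform(-10, 30, size=k)])
    coords = centers[clusters] + rng.normal(scale=1.0, size=(n, 2))

    # climate: independent Gaussians given class, common shift between classes
    shifts = np.full(config.n_climate_vars, config.climate_effect)
    clim = rng.normal(size=(n, config.n_climate_vars)) + shifts[None, :] * y[:, None]
    acc_ids = [f"acc{i + 1:04d}" for i in range(n)]
    climate = ClimateTable(
        values=pd.DataFrame(
            clim,
            index=pd.Index(acc_ids, name="id"),
            columns=[f"bio{j + 1}" for j in range(config.n_climate_vars)],
        ),
        labels=y.copy(),
    )

    panel = SNPPanel(
        accession_ids=acc_ids,
        chrom=chrom,
        pos=pos,
        genotypes=G,
        labels=y.copy(),
        clusters=clusters,
        coords=coords,
    )
    truth = TruthRecord(
        kind="panel",
        seed=config.seed,
        focal_labels=[int(v) for v in y],
        differentiated_snps=[int(i) for i in genome_idx] if config.fst_between_classes > 0 else [],
        truncated_snps=[int(i) for i in trunc_sorted],
        climate_shifts=[float(s) for s in shifts],
        extra={
            "window_snps": [int(i) for i in window_idx],
            "focal_chrom": config.focal_chrom,
            "focal_pos_bp": int(config.focal_pos_bp),
            "target_fst": config.fst_between_classes,
            "tag_ld_r2": config.tag_ld_r2,
        },
    )
    return panel, climate, truth
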