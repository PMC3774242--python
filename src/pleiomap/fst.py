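"""Class-contrast genome-wide and regional FST with resampling nulls.

Accessions are inbred, so genotypes are haploid-coded 0/1 allele calls.
Two per-SNP estimators are provided:

* ``nei`` — heterozygosity-based: FST = (Ht - Hs) / Ht with
  Ht = 2 p̄ (1 - p̄) at the pooled-sample frequency and Hs the *unweighted*
  mean of 2 p_k (1 - p_k) over the two classes.  Raw values are recorded;
  unequal class sizes can push the value slightly negative.
* ``wc`` — Weir–Cockerham-style variance components for haploid samples:
  θ = (MSA - MSW) / (MSA + (nc - 1) MSW), the two-population analogue of
  the estimator used by population-genetics toolkits; genome-wide
  aggregation is ratio-of-sums by default, mean-of-ratios optional.

Resampling nulls follow the "random divisions at the class frequency"
design (:func:`permutation_null`) and the frequency-matched SNP-partition
bootstrap (:func:`frequency_matched_bootstrap`).  Empirical p-values use
the (1 + b) / (1 + K) convention and are therefore never zero.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FstResult, PleiomapError, ResamplingNull, SNPPanel

__all__ = [
    "per_snp_fst",
    "genomewide_fst",
    "permutation_null",
    "thin_snps",
    "thin_indices",
    "regional_fst",
    "frequency_matched_bootstrap",
]

_MAX_MISSING = 0.20   # SNPs with a larger missing fraction are skipped


def _genotypes(panel_or_geno) -> np.ndarray:
    if isinstance(panel_or_geno, SNPPanel):
        return panel_or_geno.genotypes
    return np.asarray(panel_or_geno, dtype=float)


def _class_counts(G: np.ndarray, member: np.ndarray):
    """Allele counts and sample sizes per SNP for one class (bool mask)."""
    V = ~np.isnan(G[member])
    n = V.sum(axis=0).astype(float)
    c = np.nansum(G[member], axis=0)
    return n, c


def _nei_components(n1, c1, n0, c0):
    """(Ht, Hs, valid) from per-class counts; invalid where a class < 2."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = c1 / n1
        p0 = c0 / n0
        pbar = (c1 + c0) / (n1 + n0)
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p0 * (1.0 - p0)) / 2.0
    valid = (n1 >= 2) & (n0 >= 2) & (ht > 0)
    return ht, hs, valid


def _wc_components(n1, c1, n0, c0):
    """Haploid two-population variance components (MSA, MSW, nc, valid)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = c1 / n1
        p0 = c0 / n0
        nt = n1 + n0
        pw = (c1 + c0) / nt
        msa = n1 * (p1 - pw) ** 2 + n0 * (p0 - pw) ** 2   # r - 1 = 1
        msw = (n1 * p1 * (1 - p1) + n0 * p0 * (1 - p0)) / (nt - 2)
        nc = nt - (n1 ** 2 + n0 ** 2) / nt                 # / (r - 1) = 1
        pooled_het = pw * (1 - pw)
    valid = (n1 >= 2) & (n0 >= 2) & (pooled_het > 0)
    return msa, msw, nc, valid


def per_snp_fst(panel, labels: np.ndarray, estimator: str = "nei",
                max_missing: float = _MAX_MISSING) -> FstResult:
    """Per-SNP FST between the two label classes (1 vs 0).

    Accessions labeled other than 0/1 are excluded.  SNPs are skipped
    (and counted) when monomorphic in the pooled sample, when either
    class has fewer than two called accessions, or when the missing
    fraction among labeled accessions exceeds ``max_missing``.
    """
    G = _genotypes(panel)
    labels = np.asarray(labels)
    m1 = labels == 1
    m0 = labels == 0
    if m1.sum() < 2 or m0.sum() < 2:
        raise PleiomapError("need >= 2 accessions per class")
    n1, c1 = _class_counts(G, m1)
    n0, c0 = _class_counts(G, m0)
    n_labeled = m1.sum() + m0.sum()
    miss_frac = 1.0 - (n1 + n0) / n_labeled
    base_valid = miss_frac <= max_missing

    fst = np.full(G.shape[1], np.nan)
    if estimator == "nei":
        ht, hs, valid = _nei_components(n1, c1, n0, c0)
        valid &= base_valid
        fst[valid] = (ht[valid] - hs[valid]) / ht[valid]
        meta = {"hs_weighting": "unweighted"}
    elif estimator == "wc":
        msa, msw, nc, valid = _wc_components(n1, c1, n0, c0)
        valid &= base_valid
        denom = msa + (nc - 1.0) * msw
        valid &= denom > 0
        fst[valid] = (msa[valid] - msw[valid]) / denom[valid]
        meta = {"a": msa - msw, "d": msa + (nc - 1.0) * msw, "valid": valid}
    else:
        raise PleiomapError(f"unknown estimator {estimator!r}")

    used = int(np.sum(~np.isnan(fst)))
    mean = float(np.nanmean(fst)) if used else float("nan")
    return FstResult(per_snp=fst, mean_fst=mean, estimator=estimator,
                     n_snps_used=used, n_snps_skipped=G.shape[1] - used,
                     meta=meta)


def genomewide_fst(panel, labels: np.ndarray, estimator: str = "nei",
                   wc_aggregation: str = "ratio_of_sums") -> float:
    """Genome-wide FST between label classes.

    ``nei``: unweighted mean of per-SNP values over non-skipped SNPs.
    ``wc``: ratio-of-sums of the variance components by default
    (``wc_aggregation="mean_of_ratios"`` averages per-SNP θ instead).
    """
    res = per_snp_fst(panel, labels, estimator=estimator)
    if res.n_snps_used == 0:
        raise PleiomapError("no usable SNPs for genome-wide FST")
    if estimator == "wc" and wc_aggregation == "ratio_of_sums":
        v = res.meta["valid"]
        return float(res.meta["a"][v].sum() / res.meta["d"][v].sum())
    return res.mean_fst


def _mean_fst_for_partitions(G: np.ndarray, M1: np.ndarray, M0: np.ndarray,
                             exclude: np.ndarray | None = None,
                             chunk: int = 256) -> np.ndarray:
    """Mean Nei FST for K accession partitions at once.

    ``M1``/``M0`` are n_accessions × K boolean membership matrices.  SNPs
    in ``exclude`` (bool per SNP × K, optional) are dropped per partition.
    """
    V = (~np.isnan(G)).astype(float)
    Gz = np.nan_to_num(G, nan=0.0)
    K = M1.shape[1]
    out = np.empty(K)
    for s in range(0, K, chunk):
        m1 = M1[:, s:s + chunk].astype(float)
        m0 = M0[:, s:s + chunk].astype(float)
        n1 = V.T @ m1
        c1 = Gz.T @ m1
        n0 = V.T @ m0
        c0 = Gz.T @ m0
        ht, hs, valid = _nei_components(n1, c1, n0, c0)
        if exclude is not None:
            valid &= ~exclude[:, s:s + chunk]
        fst = np.where(valid, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
        with np.errstate(invalid="ignore"):
            out[s:s + chunk] = np.nanmean(fst, axis=0)
    return out


def permutation_null(panel, labels: np.ndarray, K: int = 5000,
                     seed: int = 0) -> ResamplingNull:
    """Null for the genome-wide mean FST from random class divisions.

    Each resample relabels the labeled accessions uniformly at random
    while preserving the exact class counts (divisions "at the same
    frequency" as the observed classes), then recomputes the genome-wide
    mean Nei FST.
    """
    if K < 100:
        raise PleiomapError("K must be >= 100")
    G = _genotypes(panel)
    labels = np.asarray(labels)
    labeled = np.flatnonzero((labels == 0) | (labels == 1))
    n_func = int(np.sum(labels[labeled] == 1))
    rng = np.random.default_rng(seed)

    obs1 = (labels[labeled] == 1)[:, None]
    observed = float(_mean_fst_for_partitions(G[labeled], obs1, ~obs1)[0])
    M1 = np.zeros((labeled.size, K), dtype=bool)
    for k in range(K):
        M1[rng.permutation(labeled.size)[:n_func], k] = True
    resamples = _mean_fst_for_partitions(G[labeled], M1, ~M1)
    return ResamplingNull(observed=observed, resamples=resamples, seed=seed)


def thin_indices(chrom: np.ndarray, pos: np.ndarray,
                 interval_bp: int = 50_000) -> np.ndarray:
    """Greedy left-to-right SNP thinning per chromosome.

    Keeps the first SNP, then the next SNP at least ``interval_bp``
    downstream of the last kept one, and so on.  Duplicated positions:
    the first is kept, the rest fall inside the exclusion interval.
    """
    keep = []
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        last = -np.inf
        for i in idx:
            if pos[i] - last >= interval_bp or not np.isfinite(last):
                keep.append(i)
                last = pos[i]
    return np.asarray(sorted(keep), dtype=int)


def thin_snps(panel: SNPPanel, interval_bp: int = 50_000) -> SNPPanel:
    """Panel restricted to SNPs at least ``interval_bp`` apart."""
    return panel.subset_snps(thin_indices(panel.chrom, panel.pos, interval_bp))


def regional_fst(panel: SNPPanel, labels: np.ndarray,
                 clusters: np.ndarray | None = None,
                 interval_bp: int = 50_000) -> dict:
    """Within-cluster Ht/Hs FST on thinned SNPs.

    Within each geographic cluster: SNPs are thinned to ``interval_bp``
    spacing, the pooled expected heterozygosity Ht and the class-mean
    expected heterozygosity Hs are averaged over SNPs, and the cluster
    FST is (mean Ht - mean Hs) / mean Ht.  Clusters missing a class (< 2
    called accessions in either) are skipped and reported.
    """
    if clusters is None:
        clusters = panel.clusters
    if clusters is None:
        raise PleiomapError("no cluster assignment available")
    labels = np.asarray(labels)
    thin = thin_indices(panel.chrom, panel.pos, interval_bp)
    G = panel.genotypes[:, thin]
    results: dict = {"clusters": {}, "skipped": []}
    for c in np.unique(clusters):
        acc = np.flatnonzero(clusters == c)
        lab = labels[acc]
        if np.sum(lab == 1) < 2 or np.sum(lab == 0) < 2:
            results["skipped"].append(c)
            continue
        n1, c1 = _class_counts(G[acc], lab == 1)
        n0, c0 = _class_counts(G[acc], lab == 0)
        ht, hs, valid = _nei_components(n1, c1, n0, c0)
        if not valid.any():
            results["skipped"].append(c)
            continue
        mean_ht = float(ht[valid].mean())
        mean_hs = float(hs[valid].mean())
        per_snp = np.full(G.shape[1], np.nan)
        per_snp[valid] = (ht[valid] - hs[valid]) / ht[valid]
        results["clusters"][c] = FstResult(
            per_snp=per_snp,
            mean_fst=(mean_ht - mean_hs) / mean_ht,
            estimator="nei_ht_hs_ratio_of_means",
            n_snps_used=int(valid.sum()),
            n_snps_skipped=int((~valid).sum()),
            meta={"mean_ht": mean_ht, "mean_hs": mean_hs,
                  "interval_bp": interval_bp},
        )
    return results


def frequency_matched_bootstrap(panel, labels: np.ndarray,
                                n_snps: int = 5000, tolerance: float = 0.02,
                                K: int | None = None,
                                seed: int = 0) -> ResamplingNull:
    """Null from partitions at frequency-matched SNPs.

    Candidate SNPs are those whose minor-allele frequency lies within
    ``tolerance`` of the focal class frequency (folded).  A random subset
    of ``n_snps`` candidates is drawn; each resample partitions the
    accessions by one such SNP's alleles and recomputes the genome-wide
    mean Nei FST (the partitioning SNP itself is left out of the mean).
    ``K`` defaults to ``n_snps`` (each selected SNP used once).
    """
    G = _genotypes(panel)
    labels = np.asarray(labels)
    labeled = (labels == 0) | (labels == 1)
    n_lab = int(labeled.sum())
    if n_lab < 4:
        raise PleiomapError("need >= 4 labeled accessions")
    f = float(np.sum(labels[labeled] == 1)) / n_lab
    f_maf = min(f, 1.0 - f)

    with np.errstate(invalid="ignore"):
        p = np.nanmean(G, axis=0)
    maf = np.minimum(p, 1.0 - p)
    candidates = np.flatnonzero(
        np.isfinite(maf) & (maf > 0) & (np.abs(maf - f_maf) <= tolerance))
    if candidates.size < n_snps:
        raise PleiomapError(
            f"only {candidates.size} SNPs within ±{tolerance} of the focal "
            f"frequency {f_maf:.3f}; {n_snps} required")
    rng = np.random.default_rng(seed)
    subset = rng.choice(candidates, size=n_snps, replace=False)
    if K is None:
        K = n_snps
    picks = subset[:K] if K <= n_snps else rng.choice(subset, size=K, replace=True)

    obs1 = np.zeros((G.shape[0], 1), dtype=bool)
    obs1[np.flatnonzero(labeled)[labels[labeled] == 1]] = True
    obs0 = np.zeros((G.shape[0], 1), dtype=bool)
    obs0[np.flatnonzero(labeled)[labels[labeled] == 0]] = True
    observed = float(_mean_fst_for_partitions(G, obs1, obs0)[0])
    M1 = G[:, picks] == 1.0
    M0 = G[:, picks] == 0.0
    exclude = np.zeros((G.shape[1], K), dtype=bool)
    exclude[picks, np.arange(K)] = True
    resamples = _mean_fst_for_partitions(G, M1, M0, exclude=exclude)
    null = ResamplingNull(observed=observed, resamples=resamples, seed=seed)
    null.statistic = "mean_fst_frequency_matched"
    return null
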