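"""Two-trait co-localization on summed standardized LOD profiles.

Each trait's LOD profile is standardized by its genome-wide maximum
(stand. LOD, so the peak of every trait is exactly 1), the standardized
profiles are summed position-wise into S(x), and the joint peak is the
argmax of S.  A bivariate support interval around the joint peak is cut
where S falls below a threshold; two threshold rules are provided (see
:func:`bivariate_interval`).
"""

from __future__ import annotations

import numpy as np

from .datatypes import BivariateProfile, LODProfile, PleiomapError

__all__ = ["standardize_profile", "sum_profiles", "bivariate_interval"]


def standardize_profile(profile: LODProfile) -> LODProfile:
    """Divide a LOD profile by its genome-wide maximum (peak becomes 1)."""
    m = profile.max_lod
    if m <= 0:
        raise PleiomapError(
            f"trait {profile.trait!r}: all-zero LOD profile, "
            "standardization undefined")
    return LODProfile(profile.trait, profile.grid, profile.lod / m,
                      profile.n_lines)


def sum_profiles(p1: LODProfile, p2: LODProfile) -> BivariateProfile:
    """Sum two standardized profiles; joint peak = argmax of the sum.

    Inputs may be raw or pre-standardized profiles on the same grid; each
    is (re-)standardized here, which makes the result invariant to
    positive rescaling of either trait's LODs.  Argmax ties resolve to the
    lowest (chromosome, position).
    """
    if p1.grid.n_positions != p2.grid.n_positions or \
            not np.array_equal(p1.grid.pos, p2.grid.pos) or \
            not np.array_equal(p1.grid.chrom, p2.grid.chrom):
        raise PleiomapError("profiles are on different grids")
    s1 = standardize_profile(p1)
    s2 = standardize_profile(p2)
    stand = np.vstack([s1.lod, s2.lod])
    summed = stand.sum(axis=0)
    return BivariateProfile(
        grid=p1.grid,
        traits=(p1.trait, p2.trait),
        stand_lod=stand,
        raw_lod=np.vstack([p1.lod, p2.lod]),
        summed=summed,
        peak_index=int(np.argmax(summed)),
    )


def _contiguous_run(above: np.ndarray, idx_in_chrom: int) -> tuple[int, int]:
    """Endpoints of the contiguous True run containing ``idx_in_chrom``."""
    lo = idx_in_chrom
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = idx_in_chrom
    while hi + 1 < above.size and above[hi + 1]:
        hi += 1
    return lo, hi


def bivariate_interval(bp: BivariateProfile, rule: str = "peak_fraction",
                       param: float = 0.5) -> BivariateProfile:
    """Cut a support interval around the joint peak.

    ``peak_fraction`` (default): the interval is the contiguous run of
    grid positions around the peak where S(x) >= param * S(peak); the
    boundaries sit where S first falls below that fraction of the summit.
    param -> 1 shrinks the interval to the peak grid point.

    ``literal``: the position-wise average of the two *unstandardized*
    LOD profiles, rescaled so that its maximum matches the summed
    profile's maximum, serves as the crossing threshold; the interval is
    the run around the peak where S(x) stays at or above it.  Because
    S(x) is itself an average-like combination, this rule is typically
    very permissive and is retained only as a documented alternative.

    The interval is confined to the peak's chromosome and always contains
    the joint peak.
    """
    chrom, _ = bp.peak
    cidx = bp.grid.chrom_index(chrom)
    S = bp.summed[cidx]
    peak_local = int(np.flatnonzero(cidx == bp.peak_index)[0])

    if rule == "peak_fraction":
        if not 0 < param < 1:
            raise PleiomapError("peak_fraction param must be in (0, 1)")
        thresh = param * bp.summed[bp.peak_index]
        above = S >= thresh - 1e-12
    elif rule == "literal":
        avg = bp.raw_lod.mean(axis=0)[cidx]
        m = avg.max()
        if m <= 0:
            raise PleiomapError("literal rule undefined for all-zero profiles")
        thresh_curve = avg / m * bp.summed.max()
        above = S >= thresh_curve - 1e-12
    else:
        raise PleiomapError(f"unknown interval rule {rule!r}")

    lo, hi = _contiguous_run(above, peak_local)
    interval = (chrom, float(bp.grid.pos[cidx[lo]]), float(bp.grid.pos[cidx[hi]]))
    return BivariateProfile(
        grid=bp.grid, traits=bp.traits, stand_lod=bp.stand_lod,
        raw_lod=bp.raw_lod, summed=bp.summed, peak_index=bp.peak_index,
        interval=interval, interval_rule=rule,
    )
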