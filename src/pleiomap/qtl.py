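"""Single-trait genome scans on RIL populations.

Pipeline: an even pseudo-marker grid over the linkage map
(:func:`build_grid`), exact conditional genotype probabilities from the
two-state RIL Markov chain (:func:`genotype_probabilities`), Haley–Knott
regression LOD profiles (:func:`scan_trait`), experiment-wise permutation
thresholds (:func:`permutation_threshold`), forward/backward additive
model selection (:func:`stepwise_additive`), iterative position
refinement (:func:`refine_positions`) and the final joint fit
(:func:`fit_model`).

The LOD score at a position x is the Gaussian-regression form

    LOD(x) = (n / 2) * log10(RSS0 / RSS1(x)),

regressing the phenotype on the expected parent-A dosage at x.  Scanning
on conditional expectations (Haley–Knott) rather than multiple imputation
is deterministic and admits an exact least-squares oracle; an optional
multiple-imputation scan (:func:`scan_trait_imputed`) is provided for
comparison, with the caveat that its LODs differ slightly.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

from .datatypes import (
    GeneticMap,
    GenotypeProbabilities,
    LODProfile,
    PleiomapError,
    PseudoMarkerGrid,
    QTL,
    QTLModel,
    RILPanel,
)
from .simulate import haldane_r, ril_recombination_fraction

logger = logging.getLogger(__name__)

# floor on RSS1 relative to RSS0: caps the LOD on degenerate perfect fits
_RSS_FLOOR = 1e-12


def _recomb_fraction(d_cM: np.ndarray, map_scale: str) -> np.ndarray:
    """Chain switch probability over d cM under the chosen map scale.

    ``ril``: input distances are already on the expanded RIL map, so the
    inverse Haldane value is the observed RIL recombination fraction (and
    the kernel composes exactly along the chromosome).  ``meiotic``: apply
    the map expansion R = 2r/(1+2r) on top of the inverse Haldane r.
    """
    if map_scale == "ril":
        return haldane_r(d_cM)
    if map_scale == "meiotic":
        return ril_recombination_fraction(d_cM)
    raise PleiomapError(f"unknown map_scale {map_scale!r}")


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def build_grid(gmap: GeneticMap, step_cM: float = 2.0) -> PseudoMarkerGrid:
    """Even pseudo-marker grid retaining every true marker.

    Each inter-marker gap g is subdivided into ceil(g / step) equal pieces,
    so no two grid points are more than ``step_cM`` apart and all true
    marker positions are kept exactly.
    """
    if step_cM <= 0:
        raise PleiomapError("step_cM must be positive")
    chroms, positions, is_marker, marker_col = [], [], [], []
    flat = 0
    for c, pos in zip(gmap.chrom_names, gmap.positions_cM):
        pos = np.asarray(pos, dtype=float)
        for i, p in enumerate(pos):
            chroms.append(c)
            positions.append(p)
            is_marker.append(True)
            marker_col.append(flat + i)
            if i + 1 < pos.size:
                gap = pos[i + 1] - p
                n_sub = max(1, math.ceil(gap / step_cM - 1e-9))
                for k in range(1, n_sub):
                    chroms.append(c)
                    positions.append(p + gap * k / n_sub)
                    is_marker.append(False)
                    marker_col.append(-1)
        flat += pos.size
    return PseudoMarkerGrid(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=float),
        is_marker=np.asarray(is_marker, dtype=bool),
        marker_col=np.asarray(marker_col, dtype=int),
        chrom_names=gmap.chrom_names,
    )


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------

def _interval_probs(gl: np.ndarray, gr: np.ndarray, dl: float, dr: float,
                    map_scale: str) -> np.ndarray:
    """P(A at x | flanking genotypes) on the two-state chain.

    ``gl``/``gr`` are 0/1 genotypes of the nearest informative flanking
    markers at distances dl, dr (cM).  Exact forward–backward on a 2-state
    chain: weight for state A is T(gl->A, dl) * T(A->gr, dr), normalized.
    """
    Rl = float(_recomb_fraction(np.asarray(dl), map_scale))
    Rr = float(_recomb_fraction(np.asarray(dr), map_scale))
    tA_l = np.where(gl == 1.0, 1 - Rl, Rl)      # T(gl -> A)
    tB_l = np.where(gl == 1.0, Rl, 1 - Rl)
    tA_r = np.where(gr == 1.0, 1 - Rr, Rr)      # T(A -> gr)
    tB_r = np.where(gr == 1.0, Rr, 1 - Rr)
    wA = tA_l * tA_r
    wB = tB_l * tB_r
    return wA / (wA + wB)


def genotype_probabilities(panel: RILPanel, grid: PseudoMarkerGrid,
                           map_scale: str = "ril") -> GenotypeProbabilities:
    """P(parent-A homozygote) per line at every grid position.

    Conditions on the nearest informative flanking markers; beyond the
    terminal informative marker the single-flank transition applies.  A
    line with no informative marker on a chromosome falls back to the
    marginal 0.5 with a logged warning.
    """
    n = panel.n_lines
    probs = np.empty((n, grid.n_positions))
    n_uninformative = 0
    slices = panel.gmap.chrom_slices()
    for ci, c in enumerate(panel.gmap.chrom_names):
        gidx = grid.chrom_index(c)
        x = grid.pos[gidx]
        mpos = np.asarray(panel.gmap.positions_cM[ci], dtype=float)
        G = panel.genotypes[:, slices[c]]
        full = ~np.isnan(G).any(axis=1)

        if full.any():
            probs[np.ix_(full, gidx)] = _chrom_probs(
                G[full], mpos, x, map_scale)
        for li in np.flatnonzero(~full):
            row = G[li]
            obs = np.flatnonzero(~np.isnan(row))
            if obs.size == 0:
                probs[li, gidx] = 0.5
                n_uninformative += 1
                continue
            probs[li, gidx] = _chrom_probs(
                row[None, obs], mpos[obs], x, map_scale)[0]
    if n_uninformative:
        logger.warning(
            "%d line/chromosome pairs had no informative markers; "
            "probabilities fell back to 0.5", n_uninformative)
    return GenotypeProbabilities(grid=grid, probs=probs,
                                 n_uninformative=n_uninformative)


def _chrom_probs(G: np.ndarray, mpos: np.ndarray, x: np.ndarray,
                 map_scale: str) -> np.ndarray:
    """Probabilities for lines sharing the same informative marker set."""
    out = np.empty((G.shape[0], x.size))
    left = np.searchsorted(mpos, x, side="right") - 1
    for j, xp in enumerate(x):
        l = left[j]
        if l >= 0 and abs(mpos[l] - xp) < 1e-9:
            out[:, j] = G[:, l]
        elif l < 0:                        # before the first marker
            R = float(_recomb_fraction(np.asarray(mpos[0] - xp), map_scale))
            out[:, j] = np.where(G[:, 0] == 1.0, 1 - R, R)
        elif l == mpos.size - 1:           # past the last marker
            R = float(_recomb_fraction(np.asarray(xp - mpos[l]), map_scale))
            out[:, j] = np.where(G[:, l] == 1.0, 1 - R, R)
        else:
            out[:, j] = _interval_probs(
                G[:, l], G[:, l + 1], xp - mpos[l], mpos[l + 1] - xp, map_scale)
    return out


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _prepare_scan(probs: GenotypeProbabilities, phenotype: np.ndarray):
    """Drop missing phenotypes; return (D, y, mask)."""
    y = np.asarray(phenotype, dtype=float)
    if y.size != probs.probs.shape[0]:
        raise PleiomapError("phenotype length != number of lines")
    mask = ~np.isnan(y)
    return probs.probs[mask], y[mask], mask


def _lod_from_corr2(r2: np.ndarray, n: int) -> np.ndarray:
    """LOD = (n/2) log10(RSS0/RSS1) = -(n/2) log10(1 - r^2)."""
    r2 = np.clip(r2, 0.0, 1.0 - _RSS_FLOOR)
    return -(n / 2.0) * np.log10(1.0 - r2)


def _normalized_columns(M: np.ndarray) -> np.ndarray:
    """Center columns and scale to unit norm; constant columns become 0."""
    Mc = M - M.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(Mc, axis=0)
    norm[norm == 0] = np.inf
    return Mc / norm


def scan_trait(probs: GenotypeProbabilities, phenotype: np.ndarray,
               trait: str = "trait") -> LODProfile:
    """Haley–Knott regression LOD profile over the grid."""
    D, y, _ = _prepare_scan(probs, phenotype)
    n = y.size
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0 or n < 3:
        warnings.warn(f"trait {trait!r}: zero phenotypic variance; LOD = 0")
        return LODProfile(trait, probs.grid, np.zeros(probs.grid.n_positions), n)
    Dn = _normalized_columns(D)
    r = Dn.T @ (yc / math.sqrt(syy))
    return LODProfile(trait, probs.grid, _lod_from_corr2(r * r, n), n)


def scan_trait_imputed(probs: GenotypeProbabilities, phenotype: np.ndarray,
                       trait: str = "trait", n_draws: int = 256,
                       seed: int = 0) -> LODProfile:
    """Multiple-imputation scan: average RSS over genotype draws.

    Provided for fidelity to imputation-based mapping engines; draws
    genotypes independently per position from the conditional
    probabilities, which preserves the marginal dosage but not the joint
    chain, so LODs differ slightly from :func:`scan_trait`.
    """
    D, y, _ = _prepare_scan(probs, phenotype)
    n = y.size
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0 or n < 3:
        return LODProfile(trait, probs.grid, np.zeros(probs.grid.n_positions), n)
    rng = np.random.default_rng(seed)
    lods = np.zeros(D.shape[1])
    for _ in range(n_draws):
        Gd = (rng.random(D.shape) < D).astype(float)
        r = _normalized_columns(Gd).T @ (yc / math.sqrt(syy))
        lods += _lod_from_corr2(r * r, n)
    return LODProfile(trait, probs.grid, lods / n_draws, n)


def permutation_threshold(probs: GenotypeProbabilities, phenotype: np.ndarray,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0) -> float:
    """Experiment-wise LOD threshold from phenotype permutations.

    The threshold is the empirical (1 - alpha) quantile of the genome-wide
    maximum LOD over ``n_perm`` random phenotype permutations.
    """
    if not 0 < alpha <= 1:
        raise PleiomapError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise PleiomapError("n_perm must be >= 100")
    D, y, _ = _prepare_scan(probs, phenotype)
    n = y.size
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    Dn = _normalized_columns(D)
    yn = yc / math.sqrt(syy)
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = yn[rng.permutation(n)]
    r = Dn.T @ perms                         # positions × permutations
    max_r2 = np.max(r * r, axis=0)
    max_lods = _lod_from_corr2(max_r2, n)
    return float(np.quantile(max_lods, 1.0 - alpha))


# ---------------------------------------------------------------------------
# model selection and fitting
# ---------------------------------------------------------------------------

def _model_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rss.size:
        return float(rss[0])
    return float(np.sum((y - X @ coef) ** 2))


def _design(D: np.ndarray, cols: list[int]) -> np.ndarray:
    return np.column_stack([np.ones(D.shape[0])] + [D[:, j] for j in cols])


def _model_lod(rss0: float, rss: float, n: int) -> float:
    rss = max(rss, _RSS_FLOOR * rss0)
    return (n / 2.0) * math.log10(rss0 / rss)


def _best_additional(D: np.ndarray, y: np.ndarray, cols: list[int]) -> tuple[int, float]:
    """Best single column to add: returns (index, model RSS with it added).

    Residualizes y and all candidate columns against the current design and
    picks the candidate with the largest squared residual correlation.
    First occurrence wins ties, i.e. the lowest (chromosome, position).
    """
    X = _design(D, cols)
    Q, _ = np.linalg.qr(X)
    ry = y - Q @ (Q.T @ y)
    RD = D - Q @ (Q.T @ D)
    rss_cur = float(ry @ ry)
    norms = np.linalg.norm(RD, axis=0)
    ok = norms > 1e-10 * math.sqrt(max(D.shape[0], 1))
    score = np.zeros(D.shape[1])
    score[ok] = (RD[:, ok].T @ ry) ** 2 / norms[ok] ** 2
    j = int(np.argmax(score))
    return j, rss_cur - float(score[j])


def stepwise_additive(probs: GenotypeProbabilities, phenotype: np.ndarray,
                      penalty: float, max_qtl: int = 10,
                      trait: str = "trait") -> QTLModel:
    """Forward/backward additive QTL selection under a penalized LOD.

    The criterion is pLOD = model LOD - penalty * n_QTL.  Forward steps add
    the grid position with the largest LOD gain while pLOD increases;
    backward steps drop any QTL whose removal increases pLOD.  The returned
    model is position-refined and fitted.
    """
    if penalty <= 0:
        raise PleiomapError("penalty must be positive")
    D, y, _ = _prepare_scan(probs, phenotype)
    n = y.size
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0:
        return QTLModel([], penalty=penalty)

    cols: list[int] = []
    plod = 0.0
    while len(cols) < max_qtl:
        j, rss_new = _best_additional(D, y, cols)
        lod_new = _model_lod(rss0, rss_new, n)
        plod_new = lod_new - penalty * (len(cols) + 1)
        if plod_new <= plod + 1e-9 or not math.isfinite(plod_new):
            break
        cols.append(j)
        plod = plod_new
        # backward pruning
        improved = True
        while improved and len(cols) > 1:
            improved = False
            best_drop, best_plod = -1, plod
            for q in range(len(cols)):
                sub = cols[:q] + cols[q + 1:]
                lod_sub = _model_lod(rss0, _model_rss(_design(D, sub), y), n)
                plod_sub = lod_sub - penalty * len(sub)
                if plod_sub > best_plod + 1e-9:
                    best_drop, best_plod = q, plod_sub
            if best_drop >= 0:
                cols.pop(best_drop)
                plod = best_plod
                improved = True

    model = QTLModel(
        [QTL(str(probs.grid.chrom[j]), float(probs.grid.pos[j])) for j in cols],
        penalty=penalty,
    )
    if model.size:
        model = refine_positions(model, probs, phenotype)
    return fit_model(model, probs, phenotype)


def _grid_cols(grid: PseudoMarkerGrid, qtls: list[QTL]) -> list[int]:
    cols = []
    for q in qtls:
        hit = np.flatnonzero((grid.chrom == q.chrom) &
                             (np.abs(grid.pos - q.pos_cM) < 1e-9))
        if hit.size == 0:
            raise PleiomapError(f"QTL position ({q.chrom}, {q.pos_cM}) not on grid")
        cols.append(int(hit[0]))
    return cols


def refine_positions(model: QTLModel, probs: GenotypeProbabilities,
                     phenotype: np.ndarray, max_iter: int = 20) -> QTLModel:
    """Iterative single-QTL position refinement.

    Holds all but one QTL fixed, moves the focal QTL to the grid position
    maximizing the model LOD, and cycles until no move improves it.  The
    model LOD is non-decreasing across iterations by construction.
    """
    if model.size == 0:
        return model
    D, y, _ = _prepare_scan(probs, phenotype)
    n = y.size
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    cols = _grid_cols(probs.grid, model.qtls)

    def lod_of(cs: list[int]) -> float:
        return _model_lod(rss0, _model_rss(_design(D, cs), y), n)

    cur = lod_of(cols)
    for _ in range(max_iter):
        moved = False
        for q in range(len(cols)):
            others = cols[:q] + cols[q + 1:]
            j, rss_new = _best_additional(D, y, others)
            lod_new = _model_lod(rss0, rss_new, n)
            if lod_new > cur + 1e-9 and j not in others:
                cols[q] = j
                cur = lod_new
                moved = True
        if not moved:
            break
    refined = QTLModel(
        [QTL(str(probs.grid.chrom[j]), float(probs.grid.pos[j])) for j in cols],
        penalty=model.penalty,
    )
    return refined


def fit_model(model: QTLModel, probs: GenotypeProbabilities,
              phenotype: np.ndarray) -> QTLModel:
    """Joint additive fit: effects, percent variance explained, drop-one LOD.

    PVE of QTL q is (RSS_without_q - RSS_full) / SST * 100; the drop-one
    LOD is (n/2) log10(RSS_without_q / RSS_full).  Collinear dosage columns
    yield a drop-one LOD of 0 with a warning.
    """
    D, y, _ = _prepare_scan(probs, phenotype)
    n = y.size
    yc = y - y.mean()
    sst = float(yc @ yc)
    if model.size == 0 or sst == 0:
        return QTLModel([], model_lod=0.0, penalized_lod=0.0,
                        model_pve=0.0, penalty=model.penalty)
    cols = _grid_cols(probs.grid, model.qtls)
    X = _design(D, cols)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ coef) ** 2))
    if rank < X.shape[1]:
        warnings.warn("collinear dosage columns in QTL model fit")
    model_lod = _model_lod(sst, rss_full, n)
    qtls = []
    for q, (qt, j) in enumerate(zip(model.qtls, cols)):
        sub = cols[:q] + cols[q + 1:]
        rss_wo = _model_rss(_design(D, sub), y)
        d1 = max(rss_wo - rss_full, 0.0)
        pve = float(np.clip(d1 / sst * 100.0, 0.0, 100.0))
        drop_lod = _model_lod(rss_wo, rss_full, n) if rss_wo > rss_full else 0.0
        if drop_lod == 0.0 and rss_wo <= rss_full + 1e-12:
            warnings.warn(f"QTL ({qt.chrom}, {qt.pos_cM}) adds nothing "
                          "(collinear); drop-one LOD set to 0")
        qtls.append(QTL(qt.chrom, qt.pos_cM, effect=float(coef[1 + q]),
                        pve=pve, drop_one_lod=drop_lod))
    return QTLModel(
        qtls,
        model_lod=model_lod,
        penalized_lod=model_lod - model.penalty * len(qtls),
        model_pve=float(np.clip((sst - rss_full) / sst * 100.0, 0.0, 100.0)),
        penalty=model.penalty,
    )
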