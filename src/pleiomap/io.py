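"""Readers and writers for the interchange formats.

Conventions: comma-separated UTF-8 CSV with ``.`` decimal and ``NA`` for
missing; genotype tables use the classic cross layout with three header
rows (marker name, chromosome, cM position); SNP panels are minimal VCF
(CHROM POS ID REF ALT QUAL FILTER INFO FORMAT GT, haploid-coded
homozygotes) or a delimited 0/1 matrix; results, ground truth and
manifests are JSON.  bp coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .datatypes import (
    ClimateTable,
    GeneticMap,
    PleiomapError,
    RILPanel,
    SNPPanel,
    TruthRecord,
)

logger = logging.getLogger(__name__)

_GENO_CODE = {1.0: "A", 0.0: "B"}
_CODE_GENO = {"A": 1.0, "B": 0.0, "NA": np.nan}
_LABEL_STR = {1: "functional", 0: "null", -1: "unknown"}
_STR_LABEL = {v: k for k, v in _LABEL_STR.items()}


# ---------------------------------------------------------------------------
# RIL cross
# ---------------------------------------------------------------------------

def write_cross(panel: RILPanel, genotype_csv, phenotype_csv) -> None:
    """Write the cross-layout genotype CSV and the phenotype CSV."""
    gmap = panel.gmap
    names, chroms, pos = ["id"], [""], [""]
    for c, mnames, mpos in zip(gmap.chrom_names, gmap.marker_names,
                               gmap.positions_cM):
        names.extend(mnames)
        chroms.extend([c] * len(mnames))
        pos.extend(repr(float(p)) for p in mpos)
    lines = [",".join(names), ",".join(chroms), ",".join(pos)]
    for i, lid in enumerate(panel.line_ids):
        row = [lid] + ["NA" if np.isnan(g) else _GENO_CODE[g]
                       for g in panel.genotypes[i]]
        lines.append(",".join(row))
    Path(genotype_csv).write_text("\n".join(lines) + "\n")
    panel.phenotypes.to_csv(phenotype_csv, na_rep="NA")


def read_cross(genotype_csv, phenotype_csv) -> tuple[GeneticMap, RILPanel]:
    """Read a three-header-row genotype CSV and id-joined phenotypes."""
    raw = Path(genotype_csv).read_text().strip().split("\n")
    if len(raw) < 4:
        raise PleiomapError("genotype CSV needs 3 header rows and >= 1 line")
    names = raw[0].split(",")[1:]
    chroms = raw[1].split(",")[1:]
    pos = [float(x) for x in raw[2].split(",")[1:]]
    if not (len(names) == len(chroms) == len(pos)):
        raise PleiomapError("header rows differ in length")

    chrom_names, marker_names, positions = [], [], []
    for nm, c, p in zip(names, chroms, pos):
        if not chrom_names or c != chrom_names[-1]:
            if c in chrom_names:
                raise PleiomapError(f"chromosome {c!r} appears in two blocks")
            chrom_names.append(c)
            marker_names.append([])
            positions.append([])
        marker_names[-1].append(nm)
        positions[-1].append(p)
    gmap = GeneticMap(tuple(chrom_names),
                      tuple(tuple(m) for m in marker_names),
                      tuple(tuple(p) for p in positions))

    line_ids, rows = [], []
    for ln in raw[3:]:
        parts = ln.split(",")
        lid = parts[0]
        if lid in line_ids:
            raise PleiomapError(f"duplicated line id {lid!r}")
        line_ids.append(lid)
        try:
            rows.append([_CODE_GENO[g] for g in parts[1:]])
        except KeyError as e:
            raise PleiomapError(
                f"unknown genotype code {e.args[0]!r} in line {lid!r}") from None
    G = np.asarray(rows, dtype=float)

    phen = pd.read_csv(phenotype_csv, index_col=0, na_values=["NA"])
    missing = set(line_ids) - set(phen.index.astype(str))
    if missing:
        logger.warning("%d lines have no phenotype row", len(missing))
    phen = phen.reindex(line_ids)
    return gmap, RILPanel(line_ids, G, gmap, phen)


# ---------------------------------------------------------------------------
# SNP panel: minimal VCF or delimited matrix + accession metadata
# ---------------------------------------------------------------------------

def write_snp_panel_vcf(panel: SNPPanel, path) -> None:
    """Write a minimal VCF with haploid-coded homozygous GT calls."""
    out = ["##fileformat=VCFv4.2", "##source=pleiomap"]
    for c in sorted(set(str(x) for x in panel.chrom)):
        out.append(f"##contig=<ID={c}>")
    out.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    out.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
               + "\t".join(panel.accession_ids))
    for j in range(panel.n_snps):
        calls = ["." if np.isnan(g) else str(int(g))
                 for g in panel.genotypes[:, j]]
        out.append("\t".join([
            str(panel.chrom[j]), str(int(panel.pos[j])),
            str(panel.snp_ids[j]), "A", "T", ".", "PASS", ".", "GT",
            *calls]))
    Path(path).write_text("\n".join(out) + "\n")


def write_snp_panel_csv(panel: SNPPanel, path) -> None:
    """Delimited 0/1 matrix: one row per SNP, accession columns."""
    df = pd.DataFrame(panel.genotypes.T, columns=panel.accession_ids)
    df.insert(0, "chrom", [str(c) for c in panel.chrom])
    df.insert(1, "pos", panel.pos)
    df.insert(2, "id", [str(s) for s in panel.snp_ids])
    df.to_csv(path, index=False, na_rep="NA")


def write_accession_metadata(panel: SNPPanel, path) -> None:
    """Per-accession labels, geographic clusters and coordinates."""
    df = pd.DataFrame({"id": panel.accession_ids})
    df["label"] = [_LABEL_STR[int(v)] for v in panel.labels]
    df["cluster"] = panel.clusters if panel.clusters is not None else "NA"
    if panel.coords is not None:
        df["lat"] = panel.coords[:, 0]
        df["lon"] = panel.coords[:, 1]
    df.to_csv(path, index=False, na_rep="NA")


def _read_vcf_matrix(path):
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    chroms, positions, ids, rows = [], [], [], []
    n_multi = n_het = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        calls = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT", (None,))
            alleles = [a for a in gt if a is not None]
            if not alleles:
                continue
            if len(set(alleles)) > 1:        # heterozygote in an inbred panel
                n_het += 1
                continue
            calls[i] = float(alleles[0])
        chroms.append(str(rec.chrom))
        positions.append(int(rec.pos))
        ids.append(rec.id or f"{rec.chrom}_{rec.pos}")
        rows.append(calls)
    if n_multi:
        logger.warning("skipped %d multi-allelic records", n_multi)
    if n_het:
        warnings.warn(f"{n_het} heterozygous calls set to missing "
                      "(inbred panel)")
    return samples, chroms, positions, ids, rows, {"n_multiallelic": n_multi,
                                                   "n_het_to_missing": n_het}


def _read_csv_matrix(path):
    df = pd.read_csv(path, na_values=["NA"])
    for col in ("chrom", "pos", "id"):
        if col not in df.columns:
            raise PleiomapError(f"delimited SNP matrix lacks column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "pos", "id")]
    G = df[samples].to_numpy(dtype=float)
    het = ~np.isnan(G) & ~np.isin(G, (0.0, 1.0))
    if het.any():
        warnings.warn(f"{int(het.sum())} non-binary calls set to missing")
        G[het] = np.nan
    return (samples, [str(c) for c in df["chrom"]], list(df["pos"].astype(int)),
            list(df["id"].astype(str)), list(G),
            {"n_multiallelic": 0, "n_het_to_missing": int(het.sum())})


def read_snp_panel(path, metadata_csv=None) -> SNPPanel:
    """Read a SNP panel from minimal VCF (``.vcf``) or delimited matrix.

    The optional metadata CSV (columns id, label[, cluster, lat, lon])
    supplies class labels and geography; without it all accessions are
    labeled unknown.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        samples, chroms, positions, ids, rows, meta = _read_vcf_matrix(path)
        G = np.asarray(rows, dtype=float).T
    else:
        samples, chroms, positions, ids, rows, meta = _read_csv_matrix(path)
        G = np.asarray(rows, dtype=float).T

    order = np.lexsort((np.asarray(positions), np.asarray(chroms, dtype=str)))
    chrom = np.asarray(chroms, dtype=object)[order]
    pos = np.asarray(positions, dtype=int)[order]
    snp_ids = np.asarray(ids, dtype=object)[order]
    G = G[:, order]

    labels = np.full(len(samples), -1, dtype=int)
    clusters = coords = None
    if metadata_csv is not None:
        # keep_default_na: the class label "null" must not parse as NaN
        md = pd.read_csv(metadata_csv, na_values=["NA"],
                         keep_default_na=False).set_index("id")
        md = md.reindex(samples)
        labels = np.asarray([_STR_LABEL.get(str(v), -1) for v in md["label"]])
        if "cluster" in md.columns and md["cluster"].notna().all():
            clusters = md["cluster"].to_numpy(dtype=int)
        if {"lat", "lon"} <= set(md.columns):
            coords = md[["lat", "lon"]].to_numpy(dtype=float)
    return SNPPanel(accession_ids=samples, chrom=chrom, pos=pos, genotypes=G,
                    labels=labels, clusters=clusters, coords=coords,
                    snp_ids=snp_ids)


# ---------------------------------------------------------------------------
# climate, truth, json
# ---------------------------------------------------------------------------

def write_climate(climate: ClimateTable, path) -> None:
    df = climate.values.copy()
    df.insert(0, "label", [_LABEL_STR[int(v)] for v in climate.labels])
    df.to_csv(path, na_rep="NA")


def read_climate(path) -> ClimateTable:
    # keep_default_na: the class label "null" must not parse as NaN
    df = pd.read_csv(path, index_col=0, na_values=["NA"],
                     keep_default_na=False)
    if "label" not in df.columns:
        raise PleiomapError("climate CSV lacks a 'label' column")
    labels = np.asarray([_STR_LABEL.get(str(v), -1) for v in df["label"]])
    return ClimateTable(values=df.drop(columns=["label"]), labels=labels)


def write_truth(truth: TruthRecord, path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path) -> TruthRecord:
    return TruthRecord.from_json(Path(path).read_text())


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
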