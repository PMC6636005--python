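"""Genotype/map/phenotype data model, file I/O, QC filters and map projection.

Genotypes of inbred lines are stored as allelic doses: 0 and 1 for the two
homozygotes, 0.5 for a residual heterozygote, NaN for a missing call.  All
physical coordinates are 1-based and intervals are closed ``[start, end]``;
the only place the 0-based half-open convention appears is the BED export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

MISSING = np.nan
DOSE_ALPHABET = (0.0, 0.5, 1.0)

#: technology tags for marker provenance
ARRAY_LOW = "ARRAY_LOW"    # low-density array (50 K-like)
ARRAY_HIGH = "ARRAY_HIGH"  # high-density array (600 K-like)
SEQ = "SEQ"                # sequencing-based genotyping (GBS-like)
TECH_TAGS = (ARRAY_LOW, ARRAY_HIGH, SEQ)

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cM", "allele_labels", "tech_tags"]


class DataError(ValueError):
    """Raised when an input violates a structural precondition."""


@dataclass
class GenotypeMatrix:
    """Lines x markers allelic-dose matrix with marker metadata.

    ``markers`` is a DataFrame with columns ``marker_id, chrom, pos_bp,
    pos_cM, allele_labels, tech_tags`` sorted by (chrom, pos_bp);
    ``tech_tags`` holds a comma-joined subset of :data:`TECH_TAGS`.
    """

    line_ids: list[str]
    markers: pd.DataFrame
    dose: np.ndarray  # (N, L) float, entries in {0, 0.5, 1, nan}

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.dose = np.asarray(self.dose, dtype=float)
        n, l = self.dose.shape
        if n != len(self.line_ids) or l != len(self.markers):
            raise DataError(
                f"dose shape {self.dose.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        m = self.markers
        key = m[["chrom", "pos_bp"]]
        if key.duplicated().any():
            dup = m.loc[key.duplicated(keep=False), ["chrom", "pos_bp"]]
            raise DataError(f"duplicate (chrom, pos_bp):\n{dup.drop_duplicates()}")
        order = np.lexsort((m["pos_bp"].to_numpy(), m["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(m))):
            raise DataError("markers not sorted by (chrom, pos_bp)")
        if "pos_cM" in m and m["pos_cM"].notna().any():
            for _, grp in m.groupby("chrom", sort=False):
                cm = grp["pos_cM"].to_numpy(float)
                if np.any(np.diff(cm) < 0):
                    raise DataError("pos_cM decreasing within a chromosome")
        vals = self.dose[~np.isnan(self.dose)]
        if vals.size and not np.isin(vals, DOSE_ALPHABET).all():
            bad = np.unique(vals[~np.isin(vals, DOSE_ALPHABET)])
            raise DataError(f"doses outside {{0, 0.5, 1, missing}}: {bad[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list[int]:
        return sorted(self.markers["chrom"].unique().tolist())

    def take_markers(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            list(self.line_ids), self.markers.iloc[index], self.dose[:, index]
        )

    def take_lines(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.line_ids[i] for i in index], self.markers, self.dose[index]
        )

    def marker_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dose).mean(axis=0)

    def marker_het_rate(self) -> np.ndarray:
        """Heterozygote rate among non-missing calls, per marker."""
        called = ~np.isnan(self.dose)
        het = self.dose == 0.5
        with np.errstate(invalid="ignore"):
            return np.where(called.sum(0) > 0, het.sum(0) / np.maximum(called.sum(0), 1), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency on non-missing calls (het contributes 0.5)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dose, axis=0)
        return np.minimum(p, 1.0 - p)


@dataclass
class GeneticMap:
    """Anchor-based genetic map, one strictly monotone curve per chromosome."""

    anchors: pd.DataFrame  # columns chrom, pos_bp, pos_cM
    chrom_length_bp: dict[int, int] = field(default_factory=dict)
    chrom_length_cM: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.anchors = self.anchors.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
        self._interp: dict[int, PchipInterpolator] = {}
        for c, grp in self.anchors.groupby("chrom"):
            bp = grp["pos_bp"].to_numpy(float)
            cm = grp["pos_cM"].to_numpy(float)
            if len(bp) < 2:
                raise DataError(f"chromosome {c}: need >= 2 anchors")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise DataError(f"chromosome {c}: anchors not strictly increasing")
            self._interp[int(c)] = PchipInterpolator(bp, cm, extrapolate=False)
            self.chrom_length_bp.setdefault(int(c), int(bp[-1]))
            self.chrom_length_cM.setdefault(int(c), float(cm[-1]))

    @property
    def chroms(self) -> list[int]:
        return sorted(self._interp)

    def _bounds(self, chrom: int) -> tuple[np.ndarray, np.ndarray]:
        grp = self.anchors[self.anchors["chrom"] == chrom]
        return grp["pos_bp"].to_numpy(float), grp["pos_cM"].to_numpy(float)


@dataclass
class PhenotypeTable:
    """Per-line adjusted means (BLUEs), one record per (line, environment, trait)."""

    records: pd.DataFrame  # columns line_id, environment, trait, adjusted_mean

    def __post_init__(self) -> None:
        key = self.records[["line_id", "environment", "trait"]]
        if key.duplicated().any():
            raise DataError("duplicate (line, environment, trait) phenotype record")

    def vector(self, trait: str, environment: str) -> pd.Series:
        sub = self.records[
            (self.records["trait"] == trait) & (self.records["environment"] == environment)
        ]
        return pd.Series(sub["adjusted_mean"].to_numpy(), index=sub["line_id"].tolist())

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique().tolist())

    def environments(self, trait: str) -> list[str]:
        return sorted(self.records.loc[self.records["trait"] == trait, "environment"].unique())


@dataclass
class RecombProfile:
    """Non-overlapping recombination-rate windows classifying the genome into
    high (> threshold) and low recombinogenic regions."""

    windows: pd.DataFrame  # chrom, start_bp, end_bp, rate_cM_per_Mbp, region_class
    threshold: float = 0.5

    def class_at(self, chrom: int, pos_bp: np.ndarray | int) -> np.ndarray:
        """Region class (HIGH/LOW) of positions on one chromosome."""
        w = self.windows[self.windows["chrom"] == chrom]
        starts = w["start_bp"].to_numpy()
        pos = np.atleast_1d(np.asarray(pos_bp))
        idx = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(w) - 1)
        return w["region_class"].to_numpy()[idx]

    def segments(self, chrom: int) -> pd.DataFrame:
        """Maximal runs of same-class windows as (start_bp, end_bp, region_class)."""
        w = self.windows[self.windows["chrom"] == chrom].reset_index(drop=True)
        out = []
        for _, grp in w.groupby((w["region_class"] != w["region_class"].shift()).cumsum()):
            out.append(
                (chrom, int(grp["start_bp"].iloc[0]), int(grp["end_bp"].iloc[-1]),
                 grp["region_class"].iloc[0])
            )
        return pd.DataFrame(out, columns=["chrom", "start_bp", "end_bp", "region_class"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_VCF_DOSE = {(0, 0): 0.0, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 1.0}


def read_genotypes(path, format: str = "vcf", tech_tag: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a TSV dose table.

    VCF records must be diploid biallelic SNPs; multiallelic sites are
    skipped with a warning count, duplicated (chrom, pos) are rejected.
    Dose tables follow the dialect written by :func:`write_dose_table`.
    """
    if format == "vcf":
        return _read_vcf(path, tech_tag)
    if format == "dose_table":
        return read_dose_table(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path, tech_tag: str | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, doses = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.genotypes)[:, :2]
        d = np.where((gt < 0).any(axis=1), np.nan, gt.clip(min=0).sum(axis=1) / 2.0)
        chrom = int(str(var.CHROM).lstrip("chr"))
        rows.append(
            (var.ID or f"{chrom}_{var.POS}", chrom, int(var.POS), np.nan,
             f"{var.REF}/{var.ALT[0]}", tech_tag or "")
        )
        doses.append(d)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic site(s)")
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    dose = np.asarray(doses).T if doses else np.empty((len(line_ids), 0))
    dup = markers[["chrom", "pos_bp"]].duplicated(keep=False)
    if dup.any():
        raise DataError(
            "duplicated (chrom, pos) in VCF: "
            + ", ".join(f"{c}:{p}" for c, p in markers.loc[dup, ["chrom", "pos_bp"]].values)
        )
    order = np.lexsort((markers["pos_bp"], markers["chrom"]))
    return GenotypeMatrix(line_ids, markers.iloc[order], dose[:, order])


def write_dose_table(G: GenotypeMatrix, dose_path, markers_path) -> None:
    """Write the TSV dose dialect: lines in rows, marker-id header, NA missing,
    plus a sidecar marker table."""
    df = pd.DataFrame(G.dose, index=G.line_ids, columns=G.markers["marker_id"])
    df.to_csv(dose_path, sep="\t", na_rep="NA", index_label="line_id")
    G.markers.to_csv(markers_path, sep="\t", index=False)


def read_dose_table(dose_path, markers_path=None) -> GenotypeMatrix:
    if markers_path is None:
        markers_path = str(dose_path).replace(".dose.tsv", ".markers.tsv")
    df = pd.read_csv(dose_path, sep="\t", index_col="line_id", na_values="NA")
    markers = pd.read_csv(markers_path, sep="\t")
    markers["tech_tags"] = markers.get("tech_tags", "").fillna("")
    if list(df.columns) != markers["marker_id"].astype(str).tolist():
        raise DataError("dose table columns do not match the marker sidecar")
    return GenotypeMatrix([str(i) for i in df.index], markers, df.to_numpy(float))


def read_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t")[["chrom", "pos_bp", "pos_cM"]])


def write_map(gmap: GeneticMap, path) -> None:
    gmap.anchors.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


def write_phenotypes(ph: PhenotypeTable, path) -> None:
    ph.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_markers(
    G: GenotypeMatrix,
    max_het: float = 0.15,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Retain markers with het rate <= max_het, missing rate <= max_missing and
    MAF >= min_maf (computed on non-missing calls); order preserved."""
    for t in (max_het, max_missing, min_maf):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        keep = (
            (G.marker_het_rate() <= max_het)
            & (G.marker_missing_rate() <= max_missing)
            & (G.maf() >= min_maf)
        )
    keep = np.nan_to_num(keep, nan=False).astype(bool)
    if not keep.any():
        warnings.warn("marker filter removed every marker")
    return G.take_markers(np.flatnonzero(keep))


def filter_individuals(
    G: GenotypeMatrix, max_het: float = 0.06, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Row-wise analogue of :func:`filter_markers` (panel hygiene)."""
    called = ~np.isnan(G.dose)
    n_called = called.sum(axis=1)
    het = (G.dose == 0.5).sum(axis=1) / np.maximum(n_called, 1)
    miss = 1.0 - n_called / G.n_markers
    keep = (het <= max_het) & (miss <= max_missing)
    if not keep.any():
        warnings.warn("individual filter removed every line")
    return G.take_lines(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Genetic <-> physical projection
# ---------------------------------------------------------------------------

def project_position(gmap: GeneticMap, chrom: int, value, direction: str = "bp_to_cM"):
    """Project positions through the monotone (PCHIP) map curve.

    ``direction`` is ``bp_to_cM`` or ``cM_to_bp``; the inverse direction
    inverts the same curve by bracketed root search, so round trips are
    exact to the root tolerance.  Out-of-range queries are extrapolated
    with the boundary slope.
    """
    if chrom not in gmap._interp:
        raise DataError(f"chromosome {chrom} absent from map")
    f = gmap._interp[chrom]
    bp, cm = gmap._bounds(chrom)
    value = np.asarray(value, dtype=float)
    scalar = value.ndim == 0
    v = np.atleast_1d(value)

    # boundary slopes for clamped linear extrapolation (fall back to the
    # secant of the end interval if the spline derivative vanishes)
    def _slope(side: int) -> float:
        d = float(f.derivative()(bp[side]))
        if d <= 0:
            d = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2]) if side else (cm[1] - cm[0]) / (bp[1] - bp[0])
        return d

    if direction == "bp_to_cM":
        out = np.empty_like(v)
        inside = (v >= bp[0]) & (v <= bp[-1])
        out[inside] = f(v[inside])
        out[v < bp[0]] = cm[0] + (v[v < bp[0]] - bp[0]) * _slope(0)
        out[v > bp[-1]] = cm[-1] + (v[v > bp[-1]] - bp[-1]) * _slope(-1)
    elif direction == "cM_to_bp":
        out = np.empty_like(v)
        for i, q in enumerate(v):
            if q <= cm[0]:
                out[i] = bp[0] + (q - cm[0]) / _slope(0)
            elif q >= cm[-1]:
                out[i] = bp[-1] + (q - cm[-1]) / _slope(-1)
            else:
                out[i] = brentq(lambda x: float(f(x)) - q, bp[0], bp[-1], xtol=1e-3)
    else:
        raise ValueError("direction must be 'bp_to_cM' or 'cM_to_bp'")
    return float(out[0]) if scalar else out


def recomb_profile(
    gmap: GeneticMap, window_bp: int = 2_000_000, threshold: float = 0.5
) -> RecombProfile:
    """Classify non-overlapping windows into HIGH (> threshold cM/Mbp) and LOW."""
    rows = []
    for c in gmap.chroms:
        length = gmap.chrom_length_bp[c]
        starts = np.arange(1, length + 1, window_bp)
        for s in starts:
            e = min(s + window_bp - 1, length)
            cm_s = project_position(gmap, c, float(s), "bp_to_cM")
            cm_e = project_position(gmap, c, float(e), "bp_to_cM")
            rate = (cm_e - cm_s) / ((e - s + 1) / 1e6)
            rows.append((c, int(s), int(e), rate, "HIGH" if rate > threshold else "LOW"))
    return RecombProfile(
        pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "rate_cM_per_Mbp",
                                    "region_class"]),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Panel merging
# ---------------------------------------------------------------------------

def merge_panels(panels: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Union of markers over panels restricted to the common line set.

    Duplicates at identical (chrom, pos) keep the copy with the lowest
    missing rate (technology tags unioned); duplicates whose allele labels
    conflict are dropped and reported via a warning.
    """
    if not panels:
        raise ValueError("no panels to merge")
    lines = set(panels[0].line_ids)
    for p in panels[1:]:
        lines &= set(p.line_ids)
    if not lines:
        raise DataError("no common lines across panels")
    lines = sorted(lines)

    frames = []
    for p in panels:
        idx = [p.line_ids.index(l) for l in lines]
        m = p.markers.copy()
        m["_missing"] = np.isnan(p.dose[idx]).mean(axis=0)
        m["_dose"] = list(p.dose[idx].T)
        frames.append(m)
    allm = pd.concat(frames, ignore_index=True)

    kept_rows, dropped = [], []
    for (c, pos), grp in allm.groupby(["chrom", "pos_bp"], sort=True):
        labels = set(grp["allele_labels"].astype(str))
        if len(labels) > 1:
            dropped.append((c, pos))
            continue
        best = grp.sort_values("_missing").iloc[0].copy()
        tags = sorted({t for ts in grp["tech_tags"] for t in str(ts).split(",") if t})
        best["tech_tags"] = ",".join(tags)
        kept_rows.append(best)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} marker(s) with conflicting allele labels")
    if not kept_rows:
        empty = pd.DataFrame(columns=MARKER_COLUMNS)
        return GenotypeMatrix(lines, empty, np.empty((len(lines), 0)))
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)
    dose = np.column_stack(list(kept["_dose"]))
    markers = kept[MARKER_COLUMNS].reset_index(drop=True)
    return GenotypeMatrix(lines, markers, dose)
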