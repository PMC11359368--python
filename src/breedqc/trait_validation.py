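"""Phenotype derivations and trait-linked marker validation.

Covers the phenotyping formulas (root dry matter content, carotenoid content
from a portable photometer reading), descriptive statistics and trait
correlations, marker segregation tables, Kruskal-Wallis tests of phenotype
differences between genotype classes, and the false-positive / false-negative
rates of trait-linked markers against binary phenotype classes.

FPR is the percentage of phenotype-negative (QTL-) samples that the marker
calls QTL+ (carrying the favorable allele under the marker's effect model);
FNR is the converse: phenotype-positive samples the marker calls QTL-.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from breedqc.genotype_io import MISSING, GenotypeMatrix, TraitMarkerDef
from breedqc._util import round_half_up

#: Default phenotype thresholds for the QTL+/- classification.
#: CMD: mean severity <= 2.0 counts as resistant (QTL+);
#: TCC: iCheck >= 15 ug/g (color chart >= 4 when iCheck is absent);
#: DMC: >= 30 percent dry matter.
DEFAULT_THRESHOLDS = {"CMD": 2.0, "TCC": 15.0, "TCC_CHART": 4, "DMC": 30.0}


@dataclass
class GenotypeClassCounts:
    """Diploid genotype-class counts and report percentages for one marker."""

    marker_id: str
    n_hom_minor: int
    n_het: int
    n_hom_major: int
    n_total: int
    pct_hom_minor: float
    pct_het: float
    pct_hom_major: float
    pct_favorable_carriers: float

    def __post_init__(self) -> None:
        if self.n_hom_minor + self.n_het + self.n_hom_major != self.n_total:
            raise ValueError("genotype class counts must sum to n_total")


@dataclass
class MarkerQuality:
    """False-positive / false-negative rate of a trait-linked marker."""

    marker_id: str
    fpr_pct: float | None
    fnr_pct: float | None
    n_evaluated: int


# ---------------------------------------------------------------------------
# Phenotype formulas
# ---------------------------------------------------------------------------


def rdmc(dry_weight_g: float, fresh_weight_g: float) -> float:
    """Root dry matter content: 100 * dry / fresh (percent)."""
    if fresh_weight_g <= 0:
        raise ValueError("fresh weight must be positive")
    if dry_weight_g < 0 or dry_weight_g > fresh_weight_g:
        raise ValueError("dry weight must lie in [0, fresh weight]")
    return 100.0 * dry_weight_g / fresh_weight_g


def tcc_from_icheck(
    device_reading: float, sample_weight_g: float, slurry_volume_ml: float
) -> float:
    """Total carotenoid content in ug/g from a photometer reading.

    TCC = DF * reading with dilution factor DF = sample weight / slurry volume.
    """
    if slurry_volume_ml <= 0:
        raise ValueError("slurry volume must be positive")
    return (sample_weight_g / slurry_volume_ml) * device_reading


# ---------------------------------------------------------------------------
# Descriptives & correlations
# ---------------------------------------------------------------------------


def describe_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-trait n, mean, SD, CV, and Shapiro-Wilk normality p-value.

    CV = SD/mean; undefined (NaN, flagged) when the mean is zero.
    """
    rows = {}
    for col in pheno.columns:
        vals = pd.to_numeric(pheno[col], errors="coerce").dropna().to_numpy(float)
        if len(vals) < 3:
            raise ValueError(f"trait {col!r} needs >= 3 values")
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        cv = sd / mean if mean != 0 else np.nan
        if sd == 0:
            sw_p = np.nan  # constant trait: normality test undefined
            cv = 0.0 if mean != 0 else np.nan
        else:
            sw_p = float(stats.shapiro(vals).pvalue)
        rows[col] = {"n": len(vals), "mean": mean, "sd": sd, "cv": cv,
                     "shapiro_p": sw_p}
    return pd.DataFrame(rows).T


def trait_correlations(pheno: pd.DataFrame, alpha: float = 0.05):
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Returns ``(r, p, significant)`` DataFrames; cells with p >= alpha are
    flagged non-significant (the blank-cell convention of correlation plots).
    Constant columns yield NaN r.
    """
    cols = list(pheno.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = pheno[[cols[i], cols[j]]].apply(pd.to_numeric, errors="coerce").dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return rdf, pdf, pdf < alpha


# ---------------------------------------------------------------------------
# Marker segregation
# ---------------------------------------------------------------------------


def tabulate_marker(
    G: GenotypeMatrix, marker_id: str, definition: TraitMarkerDef
) -> GenotypeClassCounts:
    """Genotype-class counts and percentages for one trait-linked marker."""
    j = G.marker_index(marker_id)
    col = G.dosages[:, j]
    col = col[col != MISSING]
    marker = G.markers[j]
    counted = marker.counted_allele
    n_counted2 = int((col == 2).sum())
    n_het = int((col == 1).sum())
    n_counted0 = int((col == 0).sum())
    # allele frequencies decide minor vs major
    n_total = len(col)
    counted_freq = (2 * n_counted2 + n_het) / (2 * n_total) if n_total else 0.0
    if counted_freq <= 0.5:
        n_hom_minor, n_hom_major = n_counted2, n_counted0
        minor_allele = counted
    else:
        n_hom_minor, n_hom_major = n_counted0, n_counted2
        minor_allele = marker.alleles[1 - marker.counted_allele_index]
    return tabulate_counts(
        marker_id,
        n_hom_minor=n_hom_minor,
        n_het=n_het,
        n_hom_major=n_hom_major,
        favorable_is_minor=(definition.favorable_allele == minor_allele),
    )


def tabulate_counts(
    marker_id: str,
    n_hom_minor: int,
    n_het: int,
    n_hom_major: int,
    favorable_is_minor: bool,
) -> GenotypeClassCounts:
    """Build a segregation row from raw genotype-class counts.

    Percentages are rounded half-up to 2 decimals for reporting; the
    favorable-carrier percentage is the sum of the two rounded class
    percentages (heterozygotes plus favorable homozygotes), matching how
    printed segregation tables are totalled.
    """
    n_total = n_hom_minor + n_het + n_hom_major
    if n_total == 0:
        raise ValueError(f"marker {marker_id!r}: no classed samples")
    pct_minor = round_half_up(100.0 * n_hom_minor / n_total)
    pct_het = round_half_up(100.0 * n_het / n_total)
    pct_major = round_half_up(100.0 * n_hom_major / n_total)
    pct_hom_fav = pct_minor if favorable_is_minor else pct_major
    carriers = round_half_up(pct_het + pct_hom_fav)
    return GenotypeClassCounts(
        marker_id=marker_id,
        n_hom_minor=n_hom_minor,
        n_het=n_het,
        n_hom_major=n_hom_major,
        n_total=n_total,
        pct_hom_minor=pct_minor,
        pct_het=pct_het,
        pct_hom_major=pct_major,
        pct_favorable_carriers=carriers,
    )


def kruskal_wallis(
    phenotype_values: np.ndarray | list[float],
    genotype_classes: np.ndarray | list,
) -> tuple[float, float, str]:
    """Kruskal-Wallis H (tie-corrected) across genotype classes.

    Returns ``(H, p, stars)`` with significance stars at the conventional
    thresholds: ``****`` p <= 1e-4, ``***`` p <= 1e-3, ``*`` p <= 0.05,
    ``ns`` otherwise.
    """
    vals = np.asarray(phenotype_values, dtype=float)
    classes = np.asarray(genotype_classes)
    groups = [vals[classes == c] for c in np.unique(classes)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty genotype classes")
    if all(np.all(g == groups[0][0]) for g in groups):
        return 0.0, 1.0, "ns"
    h, p = stats.kruskal(*groups)
    if p <= 1e-4:
        stars = "****"
    elif p <= 1e-3:
        stars = "***"
    elif p <= 0.05:
        stars = "*"
    else:
        stars = "ns"
    return float(h), float(p), stars


# ---------------------------------------------------------------------------
# QTL classification & marker quality
# ---------------------------------------------------------------------------


def classify_qtl(
    pheno: pd.DataFrame,
    trait: str,
    thresholds: dict[str, float] | None = None,
) -> pd.Series:
    """Binary phenotype classification (True = QTL+) per sample.

    CMD: mean severity <= threshold (resistant); TCC: iCheck reading >=
    threshold, falling back to the color chart when iCheck is absent;
    DMC: percent >= threshold.  Boundary values are inclusive.  Samples
    missing the trait are excluded (absent from the returned Series).
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    def col(name: str) -> pd.Series:
        if name in pheno.columns:
            return pd.to_numeric(pheno[name], errors="coerce")
        return pd.Series(np.nan, index=pheno.index, dtype=float)

    if trait == "CMD":
        vals = col("cmd_severity")
        calls = vals <= th["CMD"]
    elif trait == "DMC":
        vals = col("dmc")
        calls = vals >= th["DMC"]
    elif trait == "TCC":
        icheck = col("tcc_icheck")
        chart = col("tcc_chart")
        calls = pd.Series(np.nan, index=pheno.index, dtype=object)
        use_icheck = icheck.notna()
        calls[use_icheck] = icheck[use_icheck] >= th["TCC"]
        fallback = ~use_icheck & chart.notna()
        calls[fallback] = chart[fallback] >= th["TCC_CHART"]
        vals = icheck.where(use_icheck, chart)
    else:
        raise ValueError(f"unknown trait {trait!r}")
    return calls[vals.notna()].astype(bool)


def marker_calls(
    G: GenotypeMatrix, definition: TraitMarkerDef
) -> pd.Series:
    """Marker-side QTL+ call per sample (True = favorable prediction).

    Dominant model: >= 1 favorable allele; additive model: homozygous
    favorable only.  Samples with a missing call are excluded.
    """
    j = G.marker_index(definition.marker_id)
    marker = G.markers[j]
    if definition.favorable_allele == marker.counted_allele:
        fav_dosage = G.dosages[:, j]
    elif definition.favorable_allele == marker.alleles[1 - marker.counted_allele_index]:
        fav_dosage = np.where(G.dosages[:, j] == MISSING, MISSING, 2 - G.dosages[:, j])
    else:
        raise ValueError(
            f"favorable allele {definition.favorable_allele!r} is not one of "
            f"marker {marker.id}'s alleles {marker.alleles}"
        )
    need = 1 if definition.effect_model == "dominant" else 2
    ok = fav_dosage != MISSING
    return pd.Series(
        (fav_dosage >= need)[ok], index=np.asarray(G.sample_ids)[ok]
    )


def marker_quality(
    phenotype_calls: pd.Series, marker_qtl_calls: pd.Series, marker_id: str = ""
) -> MarkerQuality:
    """FPR/FNR of a marker's QTL calls against phenotype classes.

    Evaluated on samples with both calls.  FPR% = share of phenotype-QTL-
    samples the marker calls QTL+; FNR% = share of phenotype-QTL+ samples
    the marker calls QTL-.  A rate with an empty phenotype class is
    undefined and reported as None.
    """
    joint = pd.DataFrame(
        {"pheno": phenotype_calls, "marker": marker_qtl_calls}
    ).dropna()
    n = len(joint)
    neg = joint[~joint["pheno"].astype(bool)]
    pos = joint[joint["pheno"].astype(bool)]
    fpr = (
        round_half_up(100.0 * neg["marker"].astype(bool).sum() / len(neg))
        if len(neg)
        else None
    )
    fnr = (
        round_half_up(100.0 * (~pos["marker"].astype(bool)).sum() / len(pos))
        if len(pos)
        else None
    )
    return MarkerQuality(marker_id=marker_id, fpr_pct=fpr, fnr_pct=fnr, n_evaluated=n)


def validate_trait_markers(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    definitions: list[TraitMarkerDef],
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Segregation counts plus FPR/FNR for every trait-linked marker."""
    rows = []
    for defn in definitions:
        counts = tabulate_marker(G, defn.marker_id, defn)
        pheno_calls = classify_qtl(pheno, defn.trait, thresholds)
        quality = marker_quality(pheno_calls, marker_calls(G, defn), defn.marker_id)
        rows.append(
            {
                "trait": defn.trait,
                "marker_id": defn.marker_id,
                "favorable_allele": defn.favorable_allele,
                "n_hom_minor": counts.n_hom_minor,
                "n_het": counts.n_het,
                "n_hom_major": counts.n_hom_major,
                "n_total": counts.n_total,
                "pct_hom_minor": counts.pct_hom_minor,
                "pct_het": counts.pct_het,
                "pct_hom_major": counts.pct_hom_major,
                "pct_favorable_carriers": counts.pct_favorable_carriers,
                "fpr_pct": quality.fpr_pct,
                "fnr_pct": quality.fnr_pct,
                "n_evaluated": quality.n_evaluated,
            }
        )
    return pd.DataFrame(rows)
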