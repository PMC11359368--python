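"""Diversity statistics, beta-FST with bootstrap CIs, hierarchical AMOVA.

Per-population diversity follows the basic-statistics conventions for
codominant biallelic data: observed heterozygosity Ho is the heterozygote
fraction among non-missing calls; gene diversity Hs uses Nei's unbiased
estimator with the heterozygote correction,

    Hs_l = n/(n-1) * (1 - sum_a p_a^2 - Ho_l / (2n)),

and Fis = 1 - mean(Ho)/mean(Hs) over polymorphic loci.  Allelic richness is
rarefied to a common gene-copy count g by the hypergeometric expectation
Ar = sum_a [1 - C(N - N_a, g)/C(N, g)].

Population differentiation uses the allele-matching beta estimator: with
M_ii the within-population probability that two distinct gene copies match
and M_B the between-population matching probability,
beta_i = (M_ii - M_B) / (1 - M_B); the pairwise beta for (i, j) replaces
M_ii with (M_ii + M_jj)/2 and M_B with M_ij.  Matching probabilities are
averaged over loci before the ratio; confidence intervals come from a
percentile bootstrap over loci.

AMOVA partitions copy-level variation into among-groups, among-individuals-
within-groups, and within-individuals strata, with moment estimators using
the unequal-group-size coefficient n'' = 2(N - sum_g n_g^2 / N)/(G - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from breedqc.genotype_io import MISSING, GenotypeMatrix
from breedqc._util import round_half_up


@dataclass
class DiversityStats:
    """Per-population diversity summary (one Table-1-style row)."""

    population: str
    ho: float
    he: float
    fis: float
    ar: float | None = None
    fst_specific: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class AmovaTable:
    """Hierarchical AMOVA rows: df, SS, MS, variance components, % variation."""

    strata: list[str]
    df: np.ndarray
    ss: np.ndarray
    ms: np.ndarray
    sigma2: np.ndarray
    pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "df": self.df,
                "SS": self.ss,
                "MS": self.ms,
                "sigma2": self.sigma2,
                "pct_variation": self.pct,
            },
            index=self.strata,
        )
        total = pd.DataFrame(
            {
                "df": [self.df.sum()],
                "SS": [self.ss.sum()],
                "MS": [self.ss.sum() / self.df.sum()],
                "sigma2": [self.sigma2.sum()],
                "pct_variation": [self.pct.sum()],
            },
            index=["Total"],
        )
        return pd.concat([rows, total])


def _pop_arrays(G: GenotypeMatrix, pop_labels: dict[str, str] | list[str]):
    if isinstance(pop_labels, dict):
        labels = [pop_labels[s] for s in G.sample_ids]
    else:
        labels = list(pop_labels)
        if len(labels) != G.n_samples:
            raise ValueError("pop_labels length must match sample count")
    pops = sorted(set(labels))
    idx = {p: np.array([i for i, l in enumerate(labels) if l == p]) for p in pops}
    return pops, idx


# ---------------------------------------------------------------------------
# Heterozygosity / Fis
# ---------------------------------------------------------------------------


def heterozygosity(
    G: GenotypeMatrix, pop_labels: dict[str, str] | list[str]
) -> dict[str, DiversityStats]:
    """Per-population Ho, Nei's unbiased Hs (He), and Fis.

    Population means are taken over loci polymorphic in that population
    (Hs > 0); fixed loci contribute nothing to the Fis ratio.
    """
    pops, idx = _pop_arrays(G, pop_labels)
    out: dict[str, DiversityStats] = {}
    for p in pops:
        sub = G.dosages[idx[p]]
        if len(idx[p]) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
        ho_l, hs_l = _per_locus_ho_hs(sub)
        eligible = hs_l > 0
        if not eligible.any():
            out[p] = DiversityStats(population=p, ho=0.0, he=0.0, fis=np.nan)
            continue
        mean_ho = float(ho_l[eligible].mean())
        mean_hs = float(hs_l[eligible].mean())
        out[p] = DiversityStats(
            population=p, ho=mean_ho, he=mean_hs, fis=1.0 - mean_ho / mean_hs
        )
    return out


def _per_locus_ho_hs(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    obs = d != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = np.where(obs, d == 1, False).sum(axis=0)
        ho = np.where(n > 0, het / n, np.nan)
        p = np.where(obs, d, 0).sum(axis=0) / (2.0 * np.maximum(n, 1))
        sum_p2 = p**2 + (1.0 - p) ** 2
        hs = np.where(
            n > 1, n / (n - 1.0) * (1.0 - sum_p2 - ho / (2.0 * np.maximum(n, 1))), np.nan
        )
    return np.nan_to_num(ho, nan=0.0), np.clip(np.nan_to_num(hs, nan=0.0), 0.0, None)


# ---------------------------------------------------------------------------
# Allelic richness
# ---------------------------------------------------------------------------


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(
    G: GenotypeMatrix, pop_labels: dict[str, str] | list[str], g: int | None = None
) -> dict[str, float]:
    """Mean rarefied allele count per population (biallelic: Ar in [1, 2]).

    Rarefaction size ``g`` defaults to twice the smallest per-population,
    per-locus non-missing sample count, so every population/locus can be
    rarefied to the same number of gene copies.
    """
    pops, idx = _pop_arrays(G, pop_labels)
    if g is None:
        min_n = min(
            int((G.dosages[idx[p]] != MISSING).sum(axis=0).min()) for p in pops
        )
        g = 2 * min_n
    if g < 2:
        raise ValueError(f"rarefaction size g={g} too small (need >= 2)")
    out: dict[str, float] = {}
    for p in pops:
        sub = G.dosages[idx[p]]
        obs = sub != MISSING
        n_copies = 2.0 * obs.sum(axis=0)  # N gene copies per locus
        counted = np.where(obs, sub, 0).sum(axis=0).astype(float)  # N_a
        other = n_copies - counted
        ar_l = np.zeros(sub.shape[1])
        for counts in (counted, other):
            # P(allele absent from a subsample of g copies) = C(N-N_a, g)/C(N, g)
            with np.errstate(invalid="ignore"):
                log_absent = _log_comb(n_copies - counts, g) - _log_comb(n_copies, g)
            absent = np.where(n_copies - counts >= g, np.exp(log_absent), 0.0)
            ar_l += 1.0 - absent
        valid = n_copies >= g
        if not valid.any():
            raise ValueError(f"population {p!r} has no locus with >= {g} gene copies")
        out[p] = float(ar_l[valid].mean())
    return out


# ---------------------------------------------------------------------------
# beta-FST
# ---------------------------------------------------------------------------


def _matching_components(
    d: np.ndarray, pop_idx: dict[str, np.ndarray], pops: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus within- and between-population allele-matching probabilities.

    Returns (Mw, Mb): Mw is n_pops x L with the probability that two distinct
    gene copies from the population match; Mb is n_pops x n_pops x L with the
    cross-population matching probability sum_a p_ai p_aj.
    """
    P = len(pops)
    L = d.shape[1]
    Mw = np.full((P, L), np.nan)
    freqs = np.full((P, L), np.nan)
    for pi, p in enumerate(pops):
        sub = d[pop_idx[p]]
        obs = sub != MISSING
        n = 2.0 * obs.sum(axis=0)
        c1 = np.where(obs, sub, 0).sum(axis=0).astype(float)
        c0 = n - c1
        with np.errstate(divide="ignore", invalid="ignore"):
            Mw[pi] = np.where(
                n > 1, (c1 * (c1 - 1) + c0 * (c0 - 1)) / (n * (n - 1)), np.nan
            )
            freqs[pi] = np.where(n > 0, c1 / n, np.nan)
    Mb = (
        freqs[:, None, :] * freqs[None, :, :]
        + (1 - freqs[:, None, :]) * (1 - freqs[None, :, :])
    )
    return Mw, Mb


def beta_fst(
    G: GenotypeMatrix,
    pop_labels: dict[str, str] | list[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Allele-matching beta-FST: pairwise matrix, per-population betas, CIs.

    Matching probabilities are averaged over loci before forming the ratios.
    CIs (2.5%/97.5%) come from a percentile bootstrap over loci, seeded.
    Raises on a monomorphic panel (the ratio is 0/0).
    """
    pops, idx = _pop_arrays(G, pop_labels)
    if len(pops) < 2:
        raise ValueError("beta-FST needs at least 2 populations")
    Mw, Mb = _matching_components(G.dosages, idx, pops)
    P = len(pops)

    def estimates(locus_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        mw = np.nanmean(Mw[:, locus_idx], axis=1)  # per-pop within matching
        mb = np.nanmean(Mb[:, :, locus_idx], axis=2)  # pairwise between matching
        off = ~np.eye(P, dtype=bool)
        m_between = mb[off].mean()
        if m_between >= 1.0 - 1e-12:
            raise ValueError("monomorphic panel: beta-FST undefined (0/0)")
        beta_pop = (mw - m_between) / (1.0 - m_between)
        pairwise = np.zeros((P, P))
        for i in range(P):
            for j in range(i + 1, P):
                denom = 1.0 - mb[i, j]
                pairwise[i, j] = pairwise[j, i] = (
                    ((mw[i] + mw[j]) / 2.0 - mb[i, j]) / denom if denom > 1e-12 else np.nan
                )
        overall = float(beta_pop.mean())
        return beta_pop, pairwise, overall

    all_loci = np.arange(G.n_markers)
    beta_pop, pairwise, overall = estimates(all_loci)

    rng = np.random.default_rng(seed)
    boot_pop = np.empty((n_boot, P))
    boot_overall = np.empty(n_boot)
    for b in range(n_boot):
        sel = rng.integers(0, G.n_markers, size=G.n_markers)
        bp, _, bo = estimates(sel)
        boot_pop[b] = bp
        boot_overall[b] = bo
    ci_low = np.percentile(boot_pop, 2.5, axis=0)
    ci_high = np.percentile(boot_pop, 97.5, axis=0)
    return {
        "populations": pops,
        "beta_by_pop": dict(zip(pops, beta_pop.tolist())),
        "pairwise": pd.DataFrame(pairwise, index=pops, columns=pops),
        "overall": overall,
        "ci_low": dict(zip(pops, ci_low.tolist())),
        "ci_high": dict(zip(pops, ci_high.tolist())),
        "overall_ci": (
            float(np.percentile(boot_overall, 2.5)),
            float(np.percentile(boot_overall, 97.5)),
        ),
    }


def classify_fst(value: float) -> str:
    """Differentiation label: < 0.05 low, 0.05-0.15 moderate, > 0.15 considerable.

    Boundaries 0.05 and 0.15 fall in the moderate band.
    """
    if not np.isfinite(value):
        raise ValueError("FST value must be finite")
    if value < 0.05:
        return "low"
    if value <= 0.15:
        return "moderate"
    return "considerable"


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

_STRATA = ["between_groups", "between_individuals_within_groups", "within_individuals"]


def amova(G: GenotypeMatrix, group_labels: dict[str, str] | list[str]) -> AmovaTable:
    """Three-stratum AMOVA on gene copies.

    Each diploid sample contributes two allele values per locus (heterozygotes
    split 0/1); sums of squares from squared allele differences are
    partitioned into among-groups / among-individuals-within-groups /
    within-individuals, accumulated over loci with missing calls excluded
    locus-wise.  Degrees of freedom come from the design (G-1, N-G, N).
    Negative variance components are reported as-is with a warning.
    """
    pops, idx = _pop_arrays(G, group_labels)
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    for p in pops:
        if len(idx[p]) < 2:
            raise ValueError(f"group {p!r} has fewer than 2 individuals")
    d = G.dosages
    N = G.n_samples
    Gn = len(pops)
    group_of = np.empty(N, dtype=int)
    for gi, p in enumerate(pops):
        group_of[idx[p]] = gi
    n_g = np.array([len(idx[p]) for p in pops], dtype=float)

    ss_a = ss_b = ss_c = 0.0
    obs = d != MISSING
    dosage = np.where(obs, d, 0).astype(float)
    for l in range(G.n_markers):
        ok = obs[:, l]
        if ok.sum() < 2:
            continue
        g_l = dosage[ok, l]
        grp = group_of[ok]
        ind_mean = g_l / 2.0  # mean of the two copies
        grand = g_l.sum() / (2.0 * len(g_l))
        # within individuals: copies are (1,1)/(1,0)/(0,0); SS = 0.5 per het
        ss_c += float(((g_l == 1) * 0.5).sum())
        for gi in range(Gn):
            sel = grp == gi
            if not sel.any():
                continue
            gm = ind_mean[sel].mean()
            ss_b += float(2.0 * ((ind_mean[sel] - gm) ** 2).sum())
            ss_a += float(2.0 * sel.sum() * (gm - grand) ** 2)

    df = np.array([Gn - 1, N - Gn, N], dtype=float)
    ss = np.array([ss_a, ss_b, ss_c])
    ms = ss / df
    sigma2, pct = _solve_components(ms, n_g, N, Gn)
    return AmovaTable(strata=list(_STRATA), df=df, ss=ss, ms=ms, sigma2=sigma2, pct=pct)


def _solve_components(
    ms: np.ndarray, n_g: np.ndarray, N: float, Gn: int
) -> tuple[np.ndarray, np.ndarray]:
    sigma_c = ms[2]
    sigma_b = (ms[1] - sigma_c) / 2.0
    n_pp = 2.0 * (N - float((n_g**2).sum()) / N) / (Gn - 1)
    sigma_a = (ms[0] - sigma_c - 2.0 * sigma_b) / n_pp
    sigma2 = np.array([sigma_a, sigma_b, sigma_c])
    if (sigma2 < 0).any():
        warnings.warn(
            "negative variance component(s) reported as-is; percentages may "
            "fall outside [0, 100]",
            stacklevel=3,
        )
    pct = 100.0 * sigma2 / sigma2.sum()
    return sigma2, pct


def amova_from_ms(
    ms_values: np.ndarray | list[float],
    df: np.ndarray | list[float],
    group_sizes: np.ndarray | list[float],
) -> AmovaTable:
    """Back-solve AMOVA variance components from reported mean squares.

    Applies only the moment equations and the percentage step to externally
    supplied mean squares (ordered among-groups, among-individuals-within-
    groups, within-individuals) with the matching degrees of freedom and
    group sizes.
    """
    ms = np.asarray(ms_values, dtype=float)
    df = np.asarray(df, dtype=float)
    n_g = np.asarray(group_sizes, dtype=float)
    if ms.shape != (3,) or df.shape != (3,):
        raise ValueError("expected exactly three strata (ms and df of length 3)")
    N = float(n_g.sum())
    Gn = len(n_g)
    if Gn < 2:
        raise ValueError("need at least two group sizes")
    sigma2, pct = _solve_components(ms, n_g, N, Gn)
    return AmovaTable(
        strata=list(_STRATA), df=df, ss=ms * df, ms=ms, sigma2=sigma2, pct=pct
    )


def amova_report(table: AmovaTable, ndigits: int = 2) -> pd.DataFrame:
    """Rounded (half-up) AMOVA table for printing."""
    frame = table.to_frame()
    return frame.map(lambda v: round_half_up(v, ndigits))
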