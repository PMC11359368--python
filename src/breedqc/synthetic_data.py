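"""Synthetic genotype/phenotype panels with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a multi-origin admixed diploid breeding population genotyped on a
dense (DArTseq-style) and a sparse (KASP-style) SNP panel, with planted
duplicate pairs and trait-linked loci.

Genotypes follow the Balding-Nichols drift model: ancestral frequencies
p_l ~ Uniform(0.05, 0.95); population frequencies f_kl ~ Beta(p(1-F)/F,
(1-p)(1-F)/F) for a target differentiation F; individual allele frequency
p_il = sum_k q_ik f_kl; dosage ~ Binomial(2, p_il).  Loci are independent
(no linkage disequilibrium) and there is no pedigree structure — planted
duplicates are the only relatedness.

Binary trait views carry planted penetrance/phenocopy rates so marker
false-positive/false-negative rates have closed-form expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from breedqc.genotype_io import (
    MISSING,
    GenotypeMatrix,
    MarkerMeta,
    SampleMeta,
    TraitMarkerDef,
)

#: Trait-wise (threshold, legal range) used to place QTL+/- phenotype values.
_TRAIT_SCALES = {
    "CMD": (2.0, (1.0, 5.0), "cmd_severity", True),   # QTL+ below threshold
    "DMC": (30.0, (5.0, 60.0), "dmc", False),          # QTL+ above threshold
    "TCC": (15.0, (0.5, 40.0), "tcc_icheck", False),   # QTL+ above threshold
}


#: Default QTL+/- class-center separation per trait, in trait units
#: (CMD severity points, DMC percentage points, TCC ug/g).
_DEFAULT_EFFECT = {"CMD": 2.0, "DMC": 10.0, "TCC": 10.0}


@dataclass
class TraitArchitecture:
    """One planted trait locus: marker index, effect model, and binary view."""

    marker_index: int
    trait: str  # CMD / DMC / TCC
    effect_size: float | None = None  # QTL class-center separation, trait units
    model: str = "dominant"
    penetrance: float = 0.9  # P(QTL+ phenotype | marker carrier)
    phenocopy: float = 0.1  # P(QTL+ phenotype | non-carrier)

    def __post_init__(self) -> None:
        if self.effect_size is None:
            self.effect_size = _DEFAULT_EFFECT[self.trait]


@dataclass
class SimConfig:
    """Study-shaped defaults: 4 ancestral pops, 92 dense-panel samples,
    6602 dense / 36 sparse markers, 5% missingness, 1% genotyping error,
    12 planted duplicate pairs."""

    seed: int
    n_pops: int = 4
    fst_target: float | list[float] = 0.15
    n_samples_per_pop: int | list[int] = 23
    admixture_alpha: float = 0.0  # 0 = unadmixed; else symmetric Dirichlet
    n_markers_dense: int = 6602
    n_markers_sparse: int = 36
    missing_rate: float = 0.05
    genotype_error_rate: float = 0.01
    n_duplicate_pairs: int = 12
    trait_arch: list[TraitArchitecture] = field(default_factory=list)
    noise_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fst = self.fst_target if isinstance(self.fst_target, list) else [
            self.fst_target
        ] * self.n_pops
        if any(not 0.0 < f < 1.0 for f in fst):
            raise ValueError("fst_target values must lie in (0, 1)")
        for r in (self.missing_rate, self.genotype_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def fst_per_pop(self) -> list[float]:
        f = self.fst_target
        return list(f) if isinstance(f, list) else [f] * self.n_pops

    @property
    def samples_per_pop(self) -> list[int]:
        n = self.n_samples_per_pop
        return list(n) if isinstance(n, list) else [n] * self.n_pops


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic panels."""

    Q: np.ndarray  # (n_samples_total x n_pops) true ancestry
    pop_freqs: np.ndarray  # (n_pops x n_markers_dense)
    pop_labels: list[str]
    duplicate_pairs: list[tuple[str, str]]
    qtl_status: dict[str, pd.Series]  # trait -> True/False per sample id
    trait_defs: list[TraitMarkerDef]


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate (dense panel, sparse panel, phenotypes, truth).

    Duplicate pairs are appended copies of the first ``n_duplicate_pairs``
    samples, re-called with per-allele-copy error ``genotype_error_rate``
    (so their expected IBS distance is ~ the error rate).  The sparse panel
    is a random marker subset plus all trait-linked markers.  Missingness is
    applied uniformly at random, independently per panel.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_pops
    L = config.n_markers_dense
    sizes = config.samples_per_pop
    N = sum(sizes)
    if config.n_duplicate_pairs > N // 2:
        raise ValueError("n_duplicate_pairs exceeds half the sample count")

    ancestral = rng.uniform(0.05, 0.95, size=L)
    F = np.empty((K, L))
    for k, fst in enumerate(config.fst_per_pop):
        a = ancestral * (1.0 - fst) / fst
        b = (1.0 - ancestral) * (1.0 - fst) / fst
        F[k] = rng.beta(a, b)

    pop_labels = [f"pop{k + 1}" for k in range(K) for _ in range(sizes[k])]
    if config.admixture_alpha > 0:
        Q = rng.dirichlet(np.full(K, config.admixture_alpha), size=N)
    else:
        Q = np.zeros((N, K))
        for i, lab in enumerate(pop_labels):
            Q[i, int(lab[3:]) - 1] = 1.0

    P = Q @ F  # individual allele frequencies
    dosages = rng.binomial(2, P).astype(np.int16)

    # planted duplicates: copies of the first n_dup samples with call error
    dup_pairs: list[tuple[str, str]] = []
    n_dup = config.n_duplicate_pairs
    if n_dup:
        originals = dosages[:n_dup]
        e = config.genotype_error_rate
        flips_down = rng.binomial(originals, e)
        flips_up = rng.binomial(2 - originals, e)
        copies = (originals - flips_down + flips_up).astype(np.int16)
        dosages = np.vstack([dosages, copies])
        Q = np.vstack([Q, Q[:n_dup]])
        pop_labels = pop_labels + pop_labels[:n_dup]

    sample_ids = [f"S{i + 1:04d}" for i in range(N)]
    dup_ids = [f"{sample_ids[i]}_dup" for i in range(n_dup)]
    dup_pairs = [(sample_ids[i], dup_ids[i]) for i in range(n_dup)]
    all_ids = sample_ids + dup_ids
    n_total = len(all_ids)

    marker_meta = [
        MarkerMeta(id=f"M{j + 1:05d}", alleles=("A", "B"), counted_allele_index=1)
        for j in range(L)
    ]
    samples = [
        SampleMeta(id=sid, seed_source=lab) for sid, lab in zip(all_ids, pop_labels)
    ]

    # trait loci and binary/continuous phenotype views
    trait_defs: list[TraitMarkerDef] = []
    qtl_status: dict[str, pd.Series] = {}
    pheno = pd.DataFrame(index=pd.Index(all_ids, name="sample_id"))
    for arch in config.trait_arch:
        defn = TraitMarkerDef(
            marker_id=marker_meta[arch.marker_index].id,
            trait=arch.trait,
            favorable_allele="B",
            effect_model=arch.model,
        )
        trait_defs.append(defn)
        fav = dosages[:, arch.marker_index]
        need = 1 if arch.model == "dominant" else 2
        carrier = fav >= need
        u = rng.uniform(size=n_total)
        status = np.where(carrier, u < arch.penetrance, u < arch.phenocopy)
        threshold, (lo, hi), col, plus_is_low = _TRAIT_SCALES[arch.trait]
        sd = config.noise_sd.get(arch.trait, arch.effect_size / 6.0)
        gap = arch.effect_size / 2.0
        center_plus = threshold - gap if plus_is_low else threshold + gap
        center_minus = threshold + gap if plus_is_low else threshold - gap
        vals = np.where(status, center_plus, center_minus) + rng.normal(
            0.0, sd, size=n_total
        )
        # keep each draw on its class's side of the threshold and in range
        margin = 1e-3
        if plus_is_low:
            vals = np.where(status, np.minimum(vals, threshold), np.maximum(vals, threshold + margin))
        else:
            vals = np.where(status, np.maximum(vals, threshold), np.minimum(vals, threshold - margin))
        pheno[col] = np.clip(vals, lo, hi)
        qtl_status[arch.trait] = pd.Series(status, index=pheno.index)

    # sparse panel: random subset plus trait-linked markers
    trait_idx = sorted({a.marker_index for a in config.trait_arch})
    n_rand = max(config.n_markers_sparse - len(trait_idx), 0)
    pool = np.setdiff1d(np.arange(L), np.array(trait_idx, dtype=int))
    rand_idx = rng.choice(pool, size=min(n_rand, len(pool)), replace=False)
    sparse_idx = np.sort(np.concatenate([rand_idx, np.array(trait_idx, dtype=int)]))

    dense_d = dosages.copy()
    sparse_d = dosages[:, sparse_idx].copy()
    for panel in (dense_d, sparse_d):
        mask = rng.uniform(size=panel.shape) < config.missing_rate
        panel[mask] = MISSING

    dense = GenotypeMatrix(samples=samples, markers=marker_meta, dosages=dense_d)
    sparse = GenotypeMatrix(
        samples=[SampleMeta(id=s.id, seed_source=s.seed_source) for s in samples],
        markers=[marker_meta[j] for j in sparse_idx],
        dosages=sparse_d,
    )
    truth = SimTruth(
        Q=Q,
        pop_freqs=F,
        pop_labels=pop_labels,
        duplicate_pairs=dup_pairs,
        qtl_status=qtl_status,
        trait_defs=trait_defs,
    )
    return dense, sparse, pheno, truth


# ---------------------------------------------------------------------------
# Published worked-example fixtures
# ---------------------------------------------------------------------------


def worked_example_tables() -> dict:
    """In-memory fixtures for the published segregation and AMOVA tables.

    ``table3`` holds the genotype-class counts per trait-linked marker
    (hom-minor / het / hom-major) plus whether the favorable allele is the
    minor allele; ``table2_k2`` holds the two-cluster AMOVA mean squares,
    degrees of freedom, and cluster sizes.
    """
    table3 = {
        "S12-7926132": {"trait": "CMD", "favorable_allele": "T",
                        "counts": (40, 238, 53), "favorable_is_minor": False},
        "S12-7926163": {"trait": "CMD", "favorable_allele": "G",
                        "counts": (38, 241, 55), "favorable_is_minor": False},
        "S14-4626854": {"trait": "CMD", "favorable_allele": "A",
                        "counts": (46, 127, 160), "favorable_is_minor": True},
        "S1-24197219": {"trait": "DMC", "favorable_allele": "C",
                        "counts": (17, 160, 142), "favorable_is_minor": True},
        "S6-20589894": {"trait": "DMC", "favorable_allele": "G",
                        "counts": (67, 178, 72), "favorable_is_minor": True},
        "S12-5524524": {"trait": "DMC", "favorable_allele": "C",
                        "counts": (52, 177, 71), "favorable_is_minor": True},
        "S1-24155522": {"trait": "TCC", "favorable_allele": "A",
                        "counts": (14, 173, 117), "favorable_is_minor": False},
        "S1-30543962": {"trait": "TCC", "favorable_allele": "G",
                        "counts": (15, 129, 162), "favorable_is_minor": True},
        "S5-3387558": {"trait": "TCC", "favorable_allele": "T",
                       "counts": (2, 135, 165), "favorable_is_minor": True},
        "S8-25598183": {"trait": "TCC", "favorable_allele": "T",
                        "counts": (8, 65, 235), "favorable_is_minor": True},
    }
    table2_k2 = {
        "ms": (21438.064, 2832.135, 1839.685),
        "df": (1, 90, 92),
        "group_sizes": (58, 34),
    }
    return {"table3": table3, "table2_k2": table2_k2}
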