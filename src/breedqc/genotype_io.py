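"""Genotype, phenotype, and distance-matrix I/O.

The central container is :class:`GenotypeMatrix`: an ordered samples x markers
grid of allele dosages.  Each cell counts copies of the marker's *counted
allele* (0, 1, or 2) or holds the :data:`MISSING` sentinel.  For VCF input the
counted allele is ALT; for KASP-style call grids, which carry no REF/ALT, it
is the alphabetically first allele observed at the marker.

Supported formats: VCF (biallelic SNPs, GT field), call-grid CSV (first column
sample id, header row marker ids, cells like ``A:G`` or ``?`` for missing),
phenotype CSV, trait-marker definition CSV, square-CSV / PHYLIP square
distance matrices, and Newick export of merge trees.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from breedqc.relatedness import DistanceMatrix

#: Sentinel for a missing genotype call (distinct from dosage 0).
MISSING: int = -1

_VALID_BASES = frozenset("ACGT")


class GenotypeIOError(ValueError):
    """Raised for malformed genotype input files."""


@dataclass
class SampleMeta:
    """Per-sample metadata: id plus optional provenance labels."""

    id: str
    seed_source: str | None = None
    pedigree: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sample id must be non-empty")


@dataclass
class MarkerMeta:
    """Per-marker metadata.

    ``alleles`` is the ordered pair of single-base symbols; ``counted_allele_index``
    selects which of the two the dosage counts (0 or 1).  ``pos`` is 1-based.
    """

    id: str
    alleles: tuple[str, str] = ("A", "B")
    counted_allele_index: int = 1
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("marker id must be non-empty")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"marker {self.id}: alleles must be distinct")
        if self.counted_allele_index not in (0, 1):
            raise ValueError("counted_allele_index must be 0 or 1")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1")

    @property
    def counted_allele(self) -> str:
        return self.alleles[self.counted_allele_index]


@dataclass
class TraitMarkerDef:
    """A trait-linked marker: which allele is favorable and its effect model."""

    marker_id: str
    trait: str  # one of CMD, DMC, TCC
    favorable_allele: str
    effect_model: str = "dominant"  # or "additive"

    def __post_init__(self) -> None:
        if self.trait not in ("CMD", "DMC", "TCC"):
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.effect_model not in ("dominant", "additive"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage grid with metadata.

    ``dosages[i, j]`` counts copies of marker *j*'s counted allele carried by
    sample *i*; missing calls hold :data:`MISSING`.
    """

    samples: list[SampleMeta]
    markers: list[MarkerMeta]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError(
                f"dosage grid {self.dosages.shape} inconsistent with metadata "
                f"({len(self.samples)} samples, {len(self.markers)} markers)"
            )
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        mids = [m_.id for m_ in self.markers]
        if len(set(mids)) != len(mids):
            raise ValueError("marker ids must be unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values: {np.unique(self.dosages[bad])}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        marker_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index lists (order kept)."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            markers=[self.markers[j] for j in mi],
            dosages=self.dosages[np.ix_(si, mi)],
        )

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in matrix") from None


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, on_multiallelic: str = "skip") -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a dosage matrix.

    Dosage counts ALT-allele copies; any genotype with a missing allele maps
    to :data:`MISSING`.  ``on_multiallelic`` is ``"skip"`` (drop the record)
    or ``"error"``.
    """
    from cyvcf2 import VCF  # heavy import deferred

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad files
        raise GenotypeIOError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    markers: list[MarkerMeta] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if on_multiallelic == "error":
                raise GenotypeIOError(
                    f"non-biallelic-SNP record at line for {var.CHROM}:{var.POS}"
                )
            n_skipped += 1
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        row = np.empty(len(sample_ids), dtype=np.int16)
        for s, g in enumerate(gts):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                row[s] = MISSING
            else:
                row[s] = sum(1 for a in alleles if a > 0)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        markers.append(
            MarkerMeta(
                id=vid,
                alleles=(var.REF, var.ALT[0]),
                counted_allele_index=1,
                chrom=var.CHROM,
                pos=var.POS,
            )
        )
        rows.append(row)
    if not markers:
        raise GenotypeIOError(f"no biallelic SNP records in {path}")
    dosages = np.vstack(rows).T  # samples x markers
    return GenotypeMatrix(
        samples=[SampleMeta(id=s) for s in sample_ids],
        markers=markers,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# Call-grid CSV (KASP-style)
# ---------------------------------------------------------------------------


def _parse_call(cell: str) -> tuple[str, str] | None:
    cell = cell.strip().upper()
    if cell in ("", "?", "NA", "-", "./.", "N:N"):
        return None
    if ":" in cell:
        a, b = cell.split(":", 1)
    elif "/" in cell:
        a, b = cell.split("/", 1)
    elif len(cell) == 2:
        a, b = cell[0], cell[1]
    else:
        raise GenotypeIOError(f"cannot parse genotype call {cell!r}")
    a, b = a.strip(), b.strip()
    if a not in _VALID_BASES or b not in _VALID_BASES:
        raise GenotypeIOError(f"invalid base in genotype call {cell!r}")
    return a, b


def read_call_grid(path: str | Path) -> GenotypeMatrix:
    """Read a KASP-style call grid CSV.

    First column: sample id; header row: marker ids; cells ``X:Y`` with
    bases A/C/G/T (order-insensitive) or ``?`` / empty for missing.  The
    counted allele for each marker is the alphabetically first allele
    observed at that marker.
    """
    df = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
    marker_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index]
    n, m = len(sample_ids), len(marker_ids)
    calls: list[list[tuple[str, str] | None]] = []
    for i in range(n):
        row = []
        for j in range(m):
            cell = df.iat[i, j]
            try:
                row.append(_parse_call(cell))
            except GenotypeIOError as exc:
                raise GenotypeIOError(
                    f"{exc} (sample {sample_ids[i]!r}, marker {marker_ids[j]!r})"
                ) from None
        calls.append(row)

    markers: list[MarkerMeta] = []
    dosages = np.full((n, m), MISSING, dtype=np.int16)
    for j, mid in enumerate(marker_ids):
        observed = sorted({a for i in range(n) if calls[i][j] for a in calls[i][j]})
        if len(observed) > 2:
            raise GenotypeIOError(
                f"marker {mid!r} shows {len(observed)} alleles {observed}; "
                "only biallelic markers are supported"
            )
        if len(observed) == 0:
            observed = ["A", "N"]  # all-missing column; placeholder alleles
        elif len(observed) == 1:
            # monomorphic: pair with a placeholder so alleles stay distinct
            other = next(b for b in "ACGT" if b != observed[0])
            observed = [observed[0], other]
        counted = observed[0]
        markers.append(
            MarkerMeta(id=mid, alleles=(observed[0], observed[1]), counted_allele_index=0)
        )
        for i in range(n):
            call = calls[i][j]
            if call is not None:
                dosages[i, j] = (call[0] == counted) + (call[1] == counted)
    return GenotypeMatrix(
        samples=[SampleMeta(id=s) for s in sample_ids],
        markers=markers,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# Phenotypes & trait-marker definitions
# ---------------------------------------------------------------------------

_PHENO_RANGES = {
    "cmd_severity": (1.0, 5.0),
    "dmc": (0.0, 100.0),
    "tcc_chart": (1, 8),
    "tcc_icheck": (0.0, np.inf),
}


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table indexed by sample id.

    Recognized columns: ``cmd_severity`` (mean severity, 1-5), ``dmc``
    (dry matter %, open interval (0, 100)), ``tcc_chart`` (color chart 1-8),
    ``tcc_icheck`` (carotenoids ug/g, >= 0).  Any column may be absent;
    missing values are allowed.
    """
    for col, (lo, hi) in _PHENO_RANGES.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.dropna()
        if col == "dmc":
            bad = present[(present <= 0) | (present >= 100)]
        else:
            bad = present[(present < lo) | (present > hi)]
        if len(bad):
            raise ValueError(
                f"phenotype column {col!r} has out-of-range values, e.g. "
                f"{bad.iloc[0]} for sample {bad.index[0]!r}"
            )
        df[col] = vals
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read ``sample_id,cmd_severity,dmc,tcc_chart,tcc_icheck`` CSV."""
    df = pd.read_csv(path, index_col="sample_id")
    return validate_phenotypes(df)


def read_trait_markers(path: str | Path) -> list[TraitMarkerDef]:
    """Read a ``marker_id,trait,favorable_allele,effect_model`` CSV."""
    df = pd.read_csv(path, dtype=str)
    defs = []
    for _, row in df.iterrows():
        defs.append(
            TraitMarkerDef(
                marker_id=row["marker_id"],
                trait=row["trait"],
                favorable_allele=row["favorable_allele"],
                effect_model=row.get("effect_model", "dominant") or "dominant",
            )
        )
    return defs


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def write_distance_matrix(
    D: "DistanceMatrix", path: str | Path, dialect: str = "csv"
) -> None:
    """Write a distance matrix as square CSV (id header) or PHYLIP square."""
    path = Path(path)
    ids, V = D.ids, np.asarray(D.values, dtype=float)
    if dialect == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", *ids])
            for i, sid in enumerate(ids):
                w.writerow([sid, *(f"{v:.6f}" for v in V[i])])
    elif dialect == "phylip":
        with path.open("w") as fh:
            fh.write(f"{len(ids)}\n")
            for i, sid in enumerate(ids):
                fh.write(" ".join([sid, *(f"{v:.6f}" for v in V[i])]) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(path: str | Path) -> "DistanceMatrix":
    """Read a square CSV or PHYLIP square distance matrix (auto-detected)."""
    from breedqc.relatedness import DistanceMatrix

    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if first.split() and first.split()[0].isdigit() and "," not in first:
        # PHYLIP square: count line, then "id d d d ..." rows
        n = int(first.split()[0])
        ids, rows = [], []
        with path.open() as fh:
            fh.readline()
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(ids) != n:
            raise GenotypeIOError(f"PHYLIP header says {n} taxa, found {len(ids)}")
        V = np.asarray(rows, dtype=float)
    else:
        df = pd.read_csv(path, index_col=0)
        ids = [str(i) for i in df.index]
        V = df.to_numpy(dtype=float)
    _validate_square_distances(ids, V)
    return DistanceMatrix(ids=ids, values=V)


def _validate_square_distances(ids: list[str], V: np.ndarray) -> None:
    if V.shape != (len(ids), len(ids)):
        raise GenotypeIOError(f"distance matrix shape {V.shape} != ({len(ids)},)^2")
    if (V < 0).any():
        raise GenotypeIOError("distance matrix has negative entries")
    if not np.allclose(V, V.T, atol=1e-9):
        raise GenotypeIOError("distance matrix is not symmetric")
    if not np.allclose(np.diag(V), 0.0, atol=1e-9):
        raise GenotypeIOError("distance matrix diagonal is not zero")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string.

    Branch lengths encode merge heights: each child's branch length is its
    parent's merge height minus the child's own height (leaves have height 0).
    """
    names = list(leaf_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf names")
    Z = np.asarray(Z, dtype=float)
    n = len(names)

    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return names[node]
        row = Z[node - n]
        left, right, h = int(row[0]), int(row[1]), float(row[2])
        parts = []
        for child in (left, right):
            bl = h - heights[child]
            parts.append(f"{render(child)}:{bl:g}")
        return f"({parts[0]},{parts[1]})"

    for k in range(len(Z)):
        heights[n + k] = float(Z[k, 2])
    root = n + len(Z) - 1 if len(Z) else 0
    return render(root) + ";"


def write_newick(Z: np.ndarray, leaf_names: Sequence[str], path: str | Path) -> None:
    """Write a merge tree (SciPy linkage + leaf names) as a Newick file."""
    Path(path).write_text(linkage_to_newick(Z, leaf_names) + "\n")
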