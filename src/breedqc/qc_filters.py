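"""Marker and sample quality-control filters.

The filter protocol mirrors routine SNP-panel QC in breeding programs:
markers failing a call-rate or minor-allele-frequency threshold are removed
first, then samples whose call rate (over the retained markers) falls below
threshold are removed.  The order is fixed — markers, then samples — and both
stages are recorded in a :class:`QcReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from breedqc.genotype_io import MISSING, GenotypeMatrix


class EmptyPanelError(ValueError):
    """Raised when QC would remove every marker or every sample."""


@dataclass
class QcReport:
    """Counts and identities of removed markers/samples per QC stage."""

    n_markers_in: int
    n_markers_out: int
    n_samples_in: int
    n_samples_out: int
    removed_markers: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    removed_samples: list[tuple[str, float]] = field(default_factory=list)  # (id, call rate)

    def __post_init__(self) -> None:
        if self.n_markers_in - len(self.removed_markers) != self.n_markers_out:
            raise ValueError("marker counts inconsistent with removal list")
        if self.n_samples_in - len(self.removed_samples) != self.n_samples_out:
            raise ValueError("sample counts inconsistent with removal list")

    def to_dict(self) -> dict:
        return {
            "n_markers_in": self.n_markers_in,
            "n_markers_out": self.n_markers_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "removed_markers": [
                {"id": mid, "reason": reason} for mid, reason in self.removed_markers
            ],
            "removed_samples": [
                {"id": sid, "call_rate": cr} for sid, cr in self.removed_samples
            ],
        }


def marker_call_rate(G: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per marker column, in [0, 1]."""
    if G.n_samples == 0 or G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    return (G.dosages != MISSING).mean(axis=0)


def sample_call_rate(G: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per sample row, in [0, 1]."""
    if G.n_samples == 0 or G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    return (G.dosages != MISSING).mean(axis=1)


def minor_allele_freq(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency in [0, 0.5].

    p = sum(dosage) / (2 * n_nonmissing); MAF = min(p, 1-p).  A marker with
    no non-missing calls gets NaN (it always fails the MAF filter).
    """
    d = G.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    return np.minimum(p, 1.0 - p)


def apply_qc(
    G: GenotypeMatrix,
    marker_cr_min: float = 0.85,
    maf_min: float = 0.05,
    sample_cr_min: float = 0.85,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter markers (call rate, MAF), then samples (call rate).

    Within a sweep, marker call rate and MAF are evaluated on the same
    snapshot of the matrix; a marker failing either is removed with the first
    applicable reason (call rate checked first).  Sample call rates are then
    computed on the retained markers only.  Because removing samples can push
    a marker's call rate back under threshold, the marker->sample sweep
    repeats until nothing changes, making the filter idempotent.  Thresholds
    are inclusive: a value equal to the minimum passes.
    """
    for t in (marker_cr_min, maf_min, sample_cr_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    removed_markers: list[tuple[str, str]] = []
    removed_samples: list[tuple[str, float]] = []
    G2 = G
    while True:
        cr = marker_call_rate(G2)
        maf = minor_allele_freq(G2)
        keep_m = np.ones(G2.n_markers, dtype=bool)
        for j in range(G2.n_markers):
            if cr[j] < marker_cr_min:
                removed_markers.append((G2.markers[j].id, "call_rate"))
                keep_m[j] = False
            elif np.isnan(maf[j]) or maf[j] < maf_min:
                removed_markers.append((G2.markers[j].id, "maf"))
                keep_m[j] = False
        if not keep_m.any():
            raise EmptyPanelError("QC removed every marker")
        G1 = G2.subset(marker_idx=np.flatnonzero(keep_m))

        scr = sample_call_rate(G1)
        keep_s = scr >= sample_cr_min
        removed_samples.extend(
            (G1.samples[i].id, float(scr[i])) for i in np.flatnonzero(~keep_s)
        )
        if not keep_s.any():
            raise EmptyPanelError("QC removed every sample")
        stable = keep_m.all() and keep_s.all()
        G2 = G1.subset(sample_idx=np.flatnonzero(keep_s))
        if stable:
            break

    report = QcReport(
        n_markers_in=G.n_markers,
        n_markers_out=G2.n_markers,
        n_samples_in=G.n_samples,
        n_samples_out=G2.n_samples,
        removed_markers=removed_markers,
        removed_samples=removed_samples,
    )
    return G2, report
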