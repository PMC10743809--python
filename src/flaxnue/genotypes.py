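"""Shared genotype container: accessions x markers diploid dosages with a map.

Dosages count copies of the alternate allele (0, 1 or 2); missing calls are
stored as NaN.  Coordinates are 1-based base pairs, following VCF convention,
and marker identifiers default to ``{chrom}_{pos}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with chromosome/position map.

    Parameters
    ----------
    dosages : (n_accessions, n_markers) float array
        Alternate-allele dosages in {0, 1, 2}; NaN marks a missing call.
    accessions : accession identifiers (rows).
    chrom, pos : per-marker chromosome label and 1-based position.
    subpop : optional per-accession subpopulation label (simulator provenance).
    """

    dosages: np.ndarray
    accessions: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    subpop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (accessions x markers)")
        n_acc, n_mrk = self.dosages.shape
        if len(self.accessions) != n_acc:
            raise ValueError("accession labels do not match dosage rows")
        if len(self.chrom) != n_mrk or len(self.pos) != n_mrk:
            raise ValueError("chrom/pos map does not match dosage columns")
        if not self.marker_ids:
            self.marker_ids = [f"{c}_{p}" for c, p in zip(self.chrom, self.pos)]
        if len(self.marker_ids) != n_mrk:
            raise ValueError("marker_ids do not match dosage columns")
        with np.errstate(invalid="ignore"):
            bad = np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2
        if bad:
            raise ValueError("dosages must lie in [0, 2]")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------ basics
    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker (missing calls ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    # -------------------------------------------------------------- transforms
    def impute_mean(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-marker mean (single rule used
        everywhere downstream)."""
        if not np.isnan(self.dosages).any():
            return self
        filled = self.dosages.copy()
        col_mean = np.nanmean(filled, axis=0)
        idx = np.where(np.isnan(filled))
        filled[idx] = col_mean[idx[1]]
        return replace(self, dosages=filled, marker_ids=list(self.marker_ids))

    def select_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            accessions=list(self.accessions),
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            marker_ids=[self.marker_ids[i] for i in keep],
            subpop=self.subpop,
        )

    def select_accessions(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[keep, :],
            accessions=[self.accessions[i] for i in keep],
            chrom=self.chrom,
            pos=self.pos,
            marker_ids=list(self.marker_ids),
            subpop=None if self.subpop is None else self.subpop[keep],
        )

    def filter(self, call_rate: float = 0.95, maf_range: tuple[float, float] = (0.05, 0.5)) -> "GenotypeMatrix":
        """Apply call-rate then MAF filters, logging before/after counts."""
        n0 = self.n_markers
        keep_cr = self.call_rate() > call_rate if call_rate > 0 else np.ones(n0, bool)
        g = self.select_markers(keep_cr)
        maf = g.maf()
        lo, hi = maf_range
        g2 = g.select_markers((maf >= lo) & (maf <= hi))
        log.info(
            "marker filter: %d -> %d after call rate > %.2f -> %d after MAF in [%.3f, %.3f]",
            n0, g.n_markers, call_rate, g2.n_markers, lo, hi,
        )
        if g2.n_markers == 0:
            raise ValueError(
                f"no markers survive filtering (call rate > {call_rate}, MAF in {maf_range})"
            )
        return g2

    # ------------------------------------------------------------------- views
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.accessions, columns=self.marker_ids)

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chrom))

    def markers_on(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)
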