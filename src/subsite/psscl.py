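"""Reduction of positional-scanning synthetic combinatorial library plates.

A PSSCL screen uses four tetrapeptide sub-libraries (P1, P2, P3, P4), each
fixing one position to one of the 19 canonical amino acids (Cys replaced by
norleucine, written 'n') or Nle while the other three positions hold an
equimolar residue mixture — 8000 compounds in total, read out as initial
rates of fluorophore (ACC) release.  Reduction turns the per-well rates
into a P4..P1 specificity matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile import AA20, AA_PSSCL, BackgroundComposition, SpecificityMatrix, normalize_matrix

log = logging.getLogger(__name__)

SUBLIBRARIES: tuple[str, ...] = ("P4", "P3", "P2", "P1")

#: assay conditions of the reference screen, consumed by the simulator
DEFAULT_ASSAY = {
    "enzyme_nM": 60.0,
    "per_compound_nM": 31.25,
    "total_substrate_uM": 250.0,
    "temperature_C": 25.0,
}


class IncompletePlateError(ValueError):
    """A (sublibrary, fixed residue) combination is missing."""


@dataclass(frozen=True)
class PSSCLWell:
    """One well: a sub-library with one fixed residue, one replicate."""

    sublibrary: str  # P1..P4
    fixed_residue: str  # one of AA_PSSCL
    replicate: int
    rate: float  # fluorescence units / s
    blank: float = 0.0

    def __post_init__(self) -> None:
        if self.sublibrary not in SUBLIBRARIES:
            raise ValueError(f"unknown sub-library {self.sublibrary!r}")
        if self.fixed_residue not in AA_PSSCL:
            raise ValueError(f"unknown fixed residue {self.fixed_residue!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")


@dataclass
class PSSCLPlate:
    wells: list[PSSCLWell]
    assay: dict = field(default_factory=lambda: dict(DEFAULT_ASSAY))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (w.sublibrary, w.fixed_residue, w.replicate, w.rate, w.blank)
                for w in self.wells
            ],
            columns=["sublibrary", "fixed_residue", "replicate", "rate", "blank"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, assay: dict | None = None) -> "PSSCLPlate":
        wells = [
            PSSCLWell(
                str(r.sublibrary),
                str(r.fixed_residue),
                int(r.replicate),
                float(r.rate),
                float(getattr(r, "blank", 0.0) if not pd.isna(getattr(r, "blank", 0.0)) else 0.0),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(wells, assay=dict(assay) if assay else dict(DEFAULT_ASSAY))


def reduce_psscl(plate: PSSCLPlate, normalization: str = "rate") -> SpecificityMatrix:
    """Collapse plate wells to a P4..P1 specificity matrix.

    Each entry is the replicate mean of blank-subtracted rate, clipped at
    zero (fluorogenic rates are physically nonnegative); columns are then
    left as rates or rescaled per column (``pct_sum``, ``pct_max``).
    """
    if normalization not in ("rate", "pct_sum", "pct_max"):
        raise ValueError(f"unknown normalization {normalization!r}")
    df = plate.to_frame()
    if df.empty:
        raise IncompletePlateError("empty plate")
    df["net"] = df["rate"] - df["blank"].fillna(0.0)
    means = df.groupby(["sublibrary", "fixed_residue"], sort=False)["net"].mean()
    table = pd.DataFrame(np.nan, index=list(AA_PSSCL), columns=list(SUBLIBRARIES))
    for (sub, aa), val in means.items():
        table.at[aa, sub] = val
    if table.isna().any().any():
        missing = [
            (c, i) for c in table.columns for i in table.index if pd.isna(table.at[i, c])
        ]
        raise IncompletePlateError(f"missing sub-library/residue combinations: {missing[:5]}")
    n_neg = int((table.values < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} negative blank-subtracted mean rate(s) clipped to 0")
        log.warning("clipped %d negative blank-subtracted rates to 0", n_neg)
        table = table.clip(lower=0.0)
    m = SpecificityMatrix(table, mode="rate")
    if normalization == "rate":
        return m
    return normalize_matrix(m, normalization)


@dataclass
class QCReport:
    table: pd.DataFrame  # per (sublibrary, fixed_residue): n, mean, cv, flagged

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def qc_replicates(plate: PSSCLPlate, cv_threshold: float = 0.2) -> QCReport:
    """Flag well groups with high replicate scatter or a single replicate.

    The coefficient of variation uses the sample standard deviation
    (ddof=1); groups with CV above the threshold or fewer than 2
    replicates are flagged.
    """
    if cv_threshold <= 0:
        raise ValueError("cv_threshold must be positive")
    df = plate.to_frame()
    if df.empty:
        raise IncompletePlateError("empty plate")
    rows = []
    for (sub, aa), grp in df.groupby(["sublibrary", "fixed_residue"], sort=False):
        vals = grp["rate"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        cv = float(vals.std(ddof=1) / mean) if n >= 2 and mean != 0 else np.nan
        flagged = n < 2 or (np.isfinite(cv) and cv > cv_threshold)
        rows.append((sub, aa, n, mean, cv, flagged))
    table = pd.DataFrame(
        rows, columns=["sublibrary", "fixed_residue", "n", "mean", "cv", "flagged"]
    )
    n_flag = int(table["flagged"].sum())
    if n_flag:
        log.info("QC flagged %d of %d well groups", n_flag, len(table))
    return QCReport(table)


def psscl_to_canonical(
    m: SpecificityMatrix, background: BackgroundComposition
) -> SpecificityMatrix:
    """Map a PSSCL matrix (19 canonical + Nle) onto the 20-canonical alphabet.

    Norleucine carries no information about a natural residue, so its row
    is dropped; Cys, absent from the library, is imputed at its background
    frequency.  Columns are re-expressed as pct_sum so the imputation is a
    frequency statement, not a rate.
    """
    freqs = m.column_frequencies()
    freqs = freqs.drop(index="n", errors="ignore")
    # renormalize surviving residues, then give Cys its background share
    freqs = freqs / freqs.sum(axis=0)
    f_c = background["C"]
    freqs = freqs * (1.0 - f_c)
    freqs.loc["C"] = f_c
    freqs = freqs.reindex(list(AA20))
    return SpecificityMatrix(freqs * 100.0, mode="pct_sum")
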