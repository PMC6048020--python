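"""Subsite conventions, specificity matrices, and cleavage-site scoring.

Substrate residues flanking the scissile bond are named in the
Schechter-Berger convention: P6..P1 run N-terminal of the bond
(binding subsites S6..S1), P1'..P6' run C-terminal (S1'..S6').
Cleavage occurs between P1 and P1'.

A :class:`SpecificityMatrix` tabulates, for each subsite position, how
strongly each amino acid is preferred there — as raw event counts, as
cleavage rates (positional-scanning libraries), or normalized per column.
Entropy-based information content, background-corrected log-odds models
and sliding-window scanning of candidate substrates are built on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Canonical 20-letter alphabet, one-letter codes in alphabetical order.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

# Positional-scanning libraries replace oxidation-prone Cys by norleucine,
# written as lowercase 'n' to keep it distinct from Asn.
AA_PSSCL: tuple[str, ...] = tuple("n" if a == "C" else a for a in AA20)

GAP: str = "-"

NONPRIME_LABELS: tuple[str, ...] = ("P6", "P5", "P4", "P3", "P2", "P1")
PRIME_LABELS: tuple[str, ...] = ("P1'", "P2'", "P3'", "P4'", "P5'", "P6'")
POSITION_LABELS: tuple[str, ...] = NONPRIME_LABELS + PRIME_LABELS

#: signed offsets relative to the scissile bond: P1 = -1, P1' = +1
POSITION_INDEX: dict[str, int] = {
    **{lab: -(6 - i) for i, lab in enumerate(NONPRIME_LABELS)},
    **{lab: i + 1 for i, lab in enumerate(PRIME_LABELS)},
}

MATRIX_MODES = ("counts", "rate", "pct_sum", "pct_max", "enrichment")


class DegenerateColumnError(ValueError):
    """A subsite column is all zero and cannot be normalized."""


class AlphabetError(ValueError):
    """A symbol outside the expected amino-acid alphabet was encountered."""


@dataclass(frozen=True)
class SubsitePosition:
    """One subsite position, e.g. ``P2`` (index -2) or ``P1'`` (index +1)."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in POSITION_INDEX:
            raise ValueError(f"unknown subsite position {self.label!r}")

    @property
    def index(self) -> int:
        return POSITION_INDEX[self.label]

    @property
    def prime(self) -> bool:
        return self.index > 0


@dataclass(frozen=True)
class BackgroundComposition:
    """Background amino-acid frequencies, e.g. proteome-wide composition."""

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.freq.values()))
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("background frequencies must be nonnegative")

    @classmethod
    def uniform(cls, alphabet: Iterable[str] = AA20) -> "BackgroundComposition":
        letters = list(alphabet)
        return cls({a: 1.0 / len(letters) for a in letters})

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "BackgroundComposition":
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError("empty composition")
        return cls({a: c / total for a, c in counts.items()})

    def __getitem__(self, aa: str) -> float:
        try:
            return self.freq[aa]
        except KeyError:
            raise AlphabetError(f"amino acid {aa!r} missing from background") from None

    def as_series(self, alphabet: Iterable[str] | None = None) -> pd.Series:
        letters = list(alphabet) if alphabet is not None else list(self.freq)
        return pd.Series({a: self[a] for a in letters}, dtype=float)


@dataclass
class SpecificityMatrix:
    """Amino-acid x subsite-position weight table.

    ``values`` is indexed by amino-acid letter (rows) and position label
    (columns).  ``n_events`` records, per column, how many cleavage events
    had that position defined (edge windows leave outer positions
    undefined, so columns can differ).
    """

    values: pd.DataFrame
    mode: str = "counts"
    n_events: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in MATRIX_MODES:
            raise ValueError(f"unknown matrix mode {self.mode!r}")
        if (self.values.values < 0).any():
            raise ValueError("specificity matrix values must be nonnegative")
        if self.n_events is not None:
            self.n_events = self.n_events.reindex(self.values.columns)

    @property
    def alphabet(self) -> list[str]:
        return list(self.values.index)

    @property
    def positions(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "SpecificityMatrix":
        return SpecificityMatrix(
            self.values.copy(),
            self.mode,
            None if self.n_events is None else self.n_events.copy(),
        )

    def column_frequencies(self) -> pd.DataFrame:
        """Columns rescaled to probability distributions."""
        sums = self.values.sum(axis=0)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise DegenerateColumnError(f"all-zero column(s): {bad}")
        return self.values / sums

    @classmethod
    def zeros(
        cls,
        alphabet: Iterable[str] = AA20,
        positions: Iterable[str] = POSITION_LABELS,
        mode: str = "counts",
    ) -> "SpecificityMatrix":
        rows = list(alphabet)
        cols = list(positions)
        return cls(pd.DataFrame(0.0, index=rows, columns=cols), mode=mode)


def normalize_matrix(m: SpecificityMatrix, mode: str) -> SpecificityMatrix:
    """Rescale each column to percentages.

    ``pct_sum`` makes every column sum to 100; ``pct_max`` sets each
    column's maximum to 100.  Only count/rate matrices can be normalized.
    """
    if m.mode not in ("counts", "rate"):
        raise ValueError(f"cannot normalize a matrix in mode {m.mode!r}")
    if mode not in ("pct_sum", "pct_max"):
        raise ValueError(f"normalization target must be pct_sum or pct_max, got {mode!r}")
    if mode == "pct_sum":
        denom = m.values.sum(axis=0)
    else:
        denom = m.values.max(axis=0)
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])
        raise DegenerateColumnError(f"all-zero column(s): {bad}")
    out = m.values / denom * 100.0
    return SpecificityMatrix(out, mode=mode, n_events=None if m.n_events is None else m.n_events.copy())


def position_entropy(m: SpecificityMatrix, position: str) -> tuple[float, float]:
    """Shannon entropy H (bits) of one subsite column and its information
    content ``log2(20) - H``.

    A uniform column gives H = log2(20) ~ 4.32 bits (no specificity); a
    one-hot column gives H = 0 (absolute specificity).
    """
    if position not in m.values.columns:
        raise KeyError(f"position {position!r} not in matrix")
    col = m.values[position].to_numpy(dtype=float)
    total = col.sum()
    if total <= 0:
        raise DegenerateColumnError(f"all-zero column {position!r}")
    p = col / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h, math.log2(len(m.values.index)) - h


@dataclass
class LogOddsModel:
    """Per-position log2 odds of each residue against a background.

    ``weights[a, p] = log2( f_obs_pseudo(a, p) / f_bg(a) )`` where the
    pseudocounted observed frequency is
    ``(count(a,p) + pc * f_bg(a)) / (n_p + pc)``.  With observed
    frequencies equal to background all weights are zero.
    """

    weights: pd.DataFrame  # rows: amino acids, columns: position labels
    pseudocount: float
    background: BackgroundComposition
    positions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.positions:
            self.positions = list(self.weights.columns)

    def weight(self, aa: str, position: str) -> float:
        if aa not in self.weights.index:
            raise AlphabetError(f"residue {aa!r} not in model alphabet")
        return float(self.weights.at[aa, position])


def build_log_odds(
    m: SpecificityMatrix,
    bg: BackgroundComposition,
    pseudocount: float = 1.0,
) -> LogOddsModel:
    """Turn a count matrix into a log-odds scoring model.

    The pseudocount is Laplace-style but scaled by the background, so the
    prior pulls towards the background composition rather than uniform.
    """
    if m.mode != "counts":
        raise ValueError("log-odds models are built from count matrices")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    f_bg = bg.as_series(m.alphabet)  # raises AlphabetError on missing residues
    if m.n_events is not None:
        n_p = m.n_events.astype(float)
    else:
        n_p = m.values.sum(axis=0)
    counts = m.values
    freq = (counts.add(pseudocount * f_bg, axis=0)).div(n_p + pseudocount, axis=1)
    weights = np.log2(freq.div(f_bg, axis=0))
    return LogOddsModel(weights, pseudocount, bg, list(m.positions))


@dataclass(frozen=True)
class SubstrateWindow:
    """A P6..P6' cleavage context; ``-`` marks positions outside the protein.

    ``residues`` holds exactly 12 symbols; cleavage occurs between
    residues[5] (P1) and residues[6] (P1').
    """

    residues: str

    def __post_init__(self) -> None:
        r = self.residues
        if len(r) != 12:
            raise ValueError(f"window must have 12 symbols, got {len(r)}")
        if r[5] == GAP:
            raise ValueError("P1 must be a residue, not a gap")
        core = r.strip(GAP)
        if GAP in core:
            raise ValueError("gaps may only pad the window edges")
        for sym in core:
            if sym not in AA20:
                raise AlphabetError(f"invalid residue {sym!r} in window")

    @property
    def p1_residue(self) -> str:
        return self.residues[5]

    def residue_at(self, position: str) -> str:
        idx = POSITION_INDEX[position]
        # P6..P1 sit at string offsets 0..5, P1'..P6' at 6..11
        offset = idx + 6 if idx < 0 else idx + 5
        return self.residues[offset]

    def __str__(self) -> str:  # e.g. "--NRLR.ATGE--" with '.' at the bond
        return self.residues[:6] + "." + self.residues[6:]


def window_from_sequence(sequence: str, p1_index: int) -> SubstrateWindow:
    """Extract the P6..P6' window around the bond after 1-based ``p1_index``."""
    n = len(sequence)
    if not 1 <= p1_index <= n:
        raise IndexError(f"p1_index {p1_index} out of bounds for length {n}")
    # P6..P1 are 0-based residues p1_index-6 .. p1_index-1,
    # P1'..P6' are p1_index .. p1_index+5
    chars = [
        sequence[i] if 0 <= i < n else GAP
        for i in range(p1_index - 6, p1_index + 6)
    ]
    return SubstrateWindow("".join(chars))


@dataclass(frozen=True)
class SiteScore:
    """A scored candidate cleavage site inside one protein."""

    protein_id: str
    p1_index: int  # 1-based residue N-terminal to the scissile bond
    window: SubstrateWindow
    score: float  # bits
    rank: int = 0


def score_window(
    model: LogOddsModel,
    window: SubstrateWindow,
    positions: Sequence[str] | None = None,
) -> float:
    """Sum of per-position log-odds over the window's non-gap positions.

    Positions absent from the model (e.g. scoring a 12-position window with
    a P4..P1 positional-scanning model) and gap positions contribute 0, so
    the score is additive over any partition of the positions.
    """
    pos = list(positions) if positions is not None else model.positions
    total = 0.0
    for p in pos:
        if p not in model.positions:
            continue
        aa = window.residue_at(p)
        if aa == GAP:
            continue
        total += model.weight(aa, p)
    return total


def scan_sequence(
    model: LogOddsModel,
    sequence: str,
    p1_restrict: Iterable[str] | None = None,
    protein_id: str = "query",
) -> list[SiteScore]:
    """Score every candidate scissile bond in a protein.

    One :class:`SiteScore` is emitted per eligible P1 position (optionally
    restricted to a residue set, e.g. ``{"R", "K"}`` for a tryptic
    protease), ranked by descending score with ties broken by ascending
    position.  Edge windows are gap-padded.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    for sym in seq:
        if sym not in AA20:
            raise AlphabetError(f"invalid residue {sym!r} in sequence")
    restrict = {r.upper() for r in p1_restrict} if p1_restrict is not None else None
    hits = []
    for p1 in range(1, len(seq)):  # bond after the last residue does not exist
        if restrict is not None and seq[p1 - 1] not in restrict:
            continue
        w = window_from_sequence(seq, p1)
        hits.append((p1, w, score_window(model, w)))
    hits.sort(key=lambda t: (-t[2], t[0]))
    return [
        SiteScore(protein_id, p1, w, s, rank=i + 1)
        for i, (p1, w, s) in enumerate(hits)
    ]


# --- reliability of a specificity profile --------------------------------

#: below this many cleavage events an entropy-based profile is considered
#: unreliable at the 95% level
RELIABILITY_EVENT_LIMIT: int = 30


@dataclass
class ReliabilityReport:
    flag: str  # "reliable" | "low_confidence"
    n_events: int
    entropy_ci: pd.DataFrame  # per position: entropy, ci_low, ci_high


def reliability_assessment(
    n_events: int,
    matrix: SpecificityMatrix,
    n_boot: int = 1000,
    seed: int = 0,
) -> ReliabilityReport:
    """Flag small profiles and bootstrap per-position entropy intervals.

    Profiles built from fewer than 30 cleavage events are flagged
    ``low_confidence``; the bootstrap resamples ``n_events`` events per
    column from the observed column distribution and reports the 95%
    percentile interval of the column entropy.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    freqs = matrix.column_frequencies()
    rows = []
    for pos in freqs.columns:
        p = freqs[pos].to_numpy()
        h_obs, _ = position_entropy(matrix, pos)
        draws = rng.multinomial(n_events, p, size=n_boot).astype(float)
        q = draws / n_events
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(q > 0, q * np.log2(q), 0.0)
        h_boot = -terms.sum(axis=1)
        lo, hi = np.percentile(h_boot, [2.5, 97.5])
        rows.append((pos, h_obs, float(lo), float(hi)))
    ci = pd.DataFrame(rows, columns=["position", "entropy", "ci_low", "ci_high"]).set_index("position")
    flag = "low_confidence" if n_events < RELIABILITY_EVENT_LIMIT else "reliable"
    return ReliabilityReport(flag=flag, n_events=n_events, entropy_ci=ci)
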