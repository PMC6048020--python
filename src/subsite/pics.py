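"""Proteomic identification of cleavage sites (PICS).

A peptide library is produced by digesting a reference proteome with a
specific protease (GluC by default, cleaving after Glu), then exposed to
the test protease.  Peptides whose quantity rises more than 8-fold in the
treated sample and that match the proteome with exactly one terminus not
explained by the library digestion ("semi-specific") reveal a cleavage
site of the test protease; the flanking P6..P6' window is read from the
reference protein, and per-position residue counts form the specificity
heat maps — raw, and corrected for the proteome's natural amino-acid
abundance.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profile import (
    AA20,
    GAP,
    POSITION_LABELS,
    BackgroundComposition,
    SpecificityMatrix,
    SubstrateWindow,
    window_from_sequence,
)

log = logging.getLogger(__name__)


class NoEventsError(ValueError):
    """The pipeline produced no accepted cleavage events."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class DigestRule:
    """Cleavage specificity of the library-generating protease.

    Defaults describe GluC in ammonium-bicarbonate-type buffers: cleavage
    C-terminal of Glu, blocked by Pro in P1'.  Asp cleavage (phosphate
    buffers) is available via ``cleave_after={"E", "D"}``.
    """

    cleave_after: frozenset[str] = frozenset({"E"})
    exclude_p1prime: frozenset[str] = frozenset({"P"})
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def cuts_after(self, sequence: str, i: int) -> bool:
        """True if the rule cleaves between 0-based residues i and i+1."""
        if sequence[i] not in self.cleave_after:
            return False
        if i + 1 < len(sequence) and sequence[i + 1] in self.exclude_p1prime:
            return False
        return True


@dataclass(frozen=True)
class QuantifiedPeptide:
    """A library peptide with treated/control intensities.

    ``fold_change`` is treated/control with the control floored at a small
    epsilon so that never-detected controls give large finite (or infinite)
    ratios rather than NaN.
    """

    sequence: str
    intensity_treated: float
    intensity_control: float
    fold_change: float = field(init=False)
    control_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_treated < 0 or self.intensity_control < 0:
            raise ValueError("intensities must be nonnegative")
        denom = max(self.intensity_control, self.control_floor)
        fc = np.inf if denom == 0 else self.intensity_treated / denom
        object.__setattr__(self, "fold_change", float(fc))


@dataclass(frozen=True)
class Peptide:
    """A digestion fragment with provenance ([start, end) 0-based)."""

    sequence: str
    protein_id: str
    start: int
    end: int


@dataclass(frozen=True)
class CleavageEvent:
    """A reconstructed test-protease cleavage in a reference protein.

    ``p1_index`` is the 1-based index of the residue N-terminal to the
    scissile bond; the bond lies between p1_index and p1_index + 1.
    ``neo_terminus`` says which end of the source peptide was created by
    the test protease.
    """

    protein_id: str
    p1_index: int
    window: SubstrateWindow
    source_peptide: str
    neo_terminus: str  # "N" | "C"
    fold_change: float = np.inf


def digest_proteome(
    proteome: Sequence[ProteinRecord],
    rule: DigestRule = DigestRule(),
    length_range: tuple[int, int] | None = (6, 30),
) -> list[Peptide]:
    """In-silico digest; returns peptides with protein provenance.

    With the length filter disabled and no missed cleavages the fragments
    tile each protein exactly.
    """
    if not proteome:
        raise ValueError("empty proteome")
    peptides: list[Peptide] = []
    for rec in proteome:
        seq = rec.sequence
        bounds = [0]
        for i in range(len(seq) - 1):
            if rule.cuts_after(seq, i):
                bounds.append(i + 1)
        bounds.append(len(seq))
        frags = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        for k in range(rule.missed_cleavages + 1):
            for i in range(len(frags) - k):
                start, end = frags[i][0], frags[i + k][1]
                pep = seq[start:end]
                if length_range is not None and not (
                    length_range[0] <= len(pep) <= length_range[1]
                ):
                    continue
                peptides.append(Peptide(pep, rec.id, start, end))
    return peptides


def filter_fold_change(
    peptides: Iterable[QuantifiedPeptide], threshold: float = 8.0
) -> list[QuantifiedPeptide]:
    """Keep peptides enriched strictly more than ``threshold``-fold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [p for p in peptides if p.fold_change > threshold]


class ProteomeIndex:
    """Exact-substring index over a proteome (concatenation + linear scan).

    Adequate for desk-scale proteomes; locates every occurrence of a
    peptide and maps it back to (protein, start).
    """

    def __init__(self, proteome: Sequence[ProteinRecord]):
        if not proteome:
            raise ValueError("empty proteome")
        self.proteome = list(proteome)
        self._by_id = {rec.id: rec for rec in self.proteome}
        parts, offsets = [], []
        pos = 0
        for rec in self.proteome:
            offsets.append(pos)
            parts.append(rec.sequence)
            pos += len(rec.sequence) + 1
        self._blob = "|".join(parts)
        self._offsets = offsets

    def protein(self, protein_id: str) -> ProteinRecord:
        return self._by_id[protein_id]

    def find_all(self, peptide: str) -> list[tuple[str, int]]:
        """All (protein_id, 0-based start) occurrences of ``peptide``."""
        hits = []
        start = self._blob.find(peptide)
        while start != -1:
            k = int(np.searchsorted(self._offsets, start, side="right")) - 1
            rec = self.proteome[k]
            local = start - self._offsets[k]
            if local + len(peptide) <= len(rec.sequence):
                hits.append((rec.id, local))
            start = self._blob.find(peptide, start + 1)
        return hits


@dataclass
class LocateResult:
    event: CleavageEvent | None
    reason: str  # "ok" | "not_in_proteome" | "ambiguous_location" |
    #              "fully_specific" | "both_termini_neo"


def locate_semi_specific(
    peptide: QuantifiedPeptide | str,
    index: ProteomeIndex,
    rule: DigestRule = DigestRule(),
    allow_multi_location: bool = False,
) -> LocateResult:
    """Classify a peptide's termini and reconstruct the cleavage event.

    A terminus is *conforming* if it coincides with a protein terminus or
    with a library-protease cut site; exactly one non-conforming (neo)
    terminus identifies a test-protease cleavage there.  Fully specific
    peptides are ordinary digestion products; peptides with two neo
    termini are ambiguous (two unlinked cleavages) and rejected.
    """
    seq = peptide.sequence if isinstance(peptide, QuantifiedPeptide) else peptide
    fc = peptide.fold_change if isinstance(peptide, QuantifiedPeptide) else np.inf
    hits = index.find_all(seq)
    if not hits:
        return LocateResult(None, "not_in_proteome")
    if len(hits) > 1 and not allow_multi_location:
        return LocateResult(None, "ambiguous_location")
    protein_id, start = hits[0]
    prot = index.protein(protein_id).sequence
    end = start + len(seq)
    n_conforms = start == 0 or rule.cuts_after(prot, start - 1)
    c_conforms = end == len(prot) or rule.cuts_after(prot, end - 1)
    if n_conforms and c_conforms:
        return LocateResult(None, "fully_specific")
    if not n_conforms and not c_conforms:
        return LocateResult(None, "both_termini_neo")
    if not n_conforms:
        neo, p1_index = "N", start  # bond between start-1 and start (1-based: start)
    else:
        neo, p1_index = "C", end  # bond between end-1 and end
    window = window_from_sequence(prot, p1_index)
    return LocateResult(
        CleavageEvent(protein_id, p1_index, window, seq, neo, fc), "ok"
    )


def reconstruct_window(
    event: CleavageEvent, proteome: ProteomeIndex | Sequence[ProteinRecord]
) -> SubstrateWindow:
    """Re-read the P6..P6' window around an event from the proteome."""
    if not isinstance(proteome, ProteomeIndex):
        proteome = ProteomeIndex(proteome)
    prot = proteome.protein(event.protein_id).sequence
    return window_from_sequence(prot, event.p1_index)


def compute_background(proteome: Sequence[ProteinRecord]) -> BackgroundComposition:
    """Amino-acid frequencies over all residues of the proteome."""
    if not proteome:
        raise ValueError("empty proteome")
    counts: Counter[str] = Counter()
    for rec in proteome:
        counts.update(rec.sequence)
    counts = Counter({a: counts.get(a, 0) for a in AA20})
    return BackgroundComposition.from_counts(counts)


def count_matrix(events: Sequence[CleavageEvent]) -> SpecificityMatrix:
    """Per-position residue counts over events; gaps are not counted."""
    if not events:
        raise NoEventsError("no cleavage events")
    counts = pd.DataFrame(0.0, index=list(AA20), columns=list(POSITION_LABELS))
    for ev in events:
        for pos in POSITION_LABELS:
            aa = ev.window.residue_at(pos)
            if aa != GAP:
                counts.at[aa, pos] += 1.0
    n_events = counts.sum(axis=0).astype(int)
    return SpecificityMatrix(counts, mode="counts", n_events=n_events)


def build_heatmaps(
    events: Sequence[CleavageEvent],
    background: BackgroundComposition,
) -> tuple[SpecificityMatrix, SpecificityMatrix]:
    """Per-position residue counts as raw and abundance-corrected heat maps.

    The raw map is the column-normalized (pct_sum) count matrix.  The
    corrected map rescales each observed frequency by the residue's
    proteome abundance, ``f_obs(a, p) / f_bg(a)``, then renormalizes the
    column to pct_sum — so residues rare in the proteome but common at a
    subsite stand out.  Gap positions (windows at protein termini) are
    excluded from the per-column event counts.
    """
    cm = count_matrix(events)
    counts, n_events = cm.values, cm.n_events
    raw = SpecificityMatrix(
        counts / counts.sum(axis=0) * 100.0, mode="pct_sum", n_events=n_events
    )
    f_bg = background.as_series(list(AA20))
    f_obs = counts / counts.sum(axis=0)
    enrich = f_obs.div(f_bg, axis=0)
    corrected = SpecificityMatrix(
        enrich / enrich.sum(axis=0) * 100.0, mode="pct_sum", n_events=n_events
    )
    return raw, corrected


@dataclass
class PICSResult:
    events: list[CleavageEvent]
    raw_matrix: SpecificityMatrix
    corrected_matrix: SpecificityMatrix
    background: BackgroundComposition
    report: dict


def run_pics(
    proteome: Sequence[ProteinRecord],
    quant: Sequence[QuantifiedPeptide] | pd.DataFrame,
    rule: DigestRule = DigestRule(),
    threshold: float = 8.0,
    control_floor_scale: float = 1e-6,
) -> PICSResult:
    """Full PICS stage: filter, locate, reconstruct, tabulate.

    ``control_floor_scale`` sets the epsilon protecting against zero
    control intensities, as a fraction of the median control intensity.
    """
    if isinstance(quant, pd.DataFrame):
        controls = quant["intensity_control"].to_numpy(dtype=float)
        floor = control_floor_scale * float(np.median(controls[controls > 0])) if (controls > 0).any() else 0.0
        quant = [
            QuantifiedPeptide(
                str(r.peptide),
                float(r.intensity_treated),
                float(r.intensity_control),
                control_floor=floor,
            )
            for r in quant.itertuples(index=False)
        ]
    quant = list(quant)
    if not quant:
        raise NoEventsError("no events: empty quantification table")
    accepted = filter_fold_change(quant, threshold)
    index = ProteomeIndex(proteome)
    events: list[CleavageEvent] = []
    rejections: Counter[str] = Counter()
    for pep in accepted:
        res = locate_semi_specific(pep, index, rule)
        if res.event is not None:
            events.append(res.event)
        else:
            rejections[res.reason] += 1
    report = {
        "n_input": len(quant),
        "n_above_threshold": len(accepted),
        "n_below_threshold": len(quant) - len(accepted),
        "n_accepted_events": len(events),
        "rejections": dict(rejections),
        "threshold": threshold,
    }
    log.info(
        "PICS: %d peptides in, %d above %.3g-fold, %d cleavage events (%s)",
        len(quant), len(accepted), len(events), dict(rejections),
    )
    if not events:
        raise NoEventsError("no events passed semi-specific matching")
    background = compute_background(proteome)
    raw, corrected = build_heatmaps(events, background)
    return PICSResult(events, raw, corrected, background, report)
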