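"""Seedable generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and ships
a :class:`TruthRecord` holding the planted parameters, so downstream
stages can be tested for recovery without any external data:

* random proteomes at a stated amino-acid composition (an E. coli-like
  table is embedded, matching the composition of the proteome used to
  build PICS peptide libraries),
* PICS quantification tables with planted semi-specific cleavage
  peptides, drawn in proportion to a truth specificity profile, plus
  decoys,
* PSSCL plates with replicate noise around a truth rate matrix,
* kinetic rate tables and progress curves under Michaelis-Menten,
  inhibition, dose-response, burst and activation models.

The packaged "KLK8-like" truth profile is an emulation constructed from
the protease's published qualitative preferences (P1 Arg >> Lys, P2
aliphatic, P3 basic, P1' Ser/Met); it is not measured data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profile import (
    AA20,
    AA_PSSCL,
    POSITION_LABELS,
    BackgroundComposition,
    SpecificityMatrix,
)
from .pics import DigestRule, ProteinRecord, ProteomeIndex
from .psscl import DEFAULT_ASSAY, PSSCLPlate, PSSCLWell, SUBLIBRARIES
from .kinetics import (
    EPSILON_PNP_410,
    KineticSeries,
    ProgressCurve,
    _activation_rate,
    _mechanism_rate,
)

#: Average amino-acid composition of the E. coli K-12 proteome (fractions).
ECOLI_COMPOSITION: dict[str, float] = {
    "A": 0.095, "C": 0.012, "D": 0.054, "E": 0.057, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.044, "L": 0.107,
    "M": 0.028, "N": 0.039, "P": 0.044, "Q": 0.044, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.071, "W": 0.015, "Y": 0.028,
}

#: True Zn2+ inhibition constant (µM) used by the default inhibition
#: scenario — the wild-type KLK8 IC50.
DEFAULT_ZN_KI_UM: float = 3.6


@dataclass
class TruthRecord:
    """Planted parameters serialized alongside every generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, pd.DataFrame):
                return {c: o[c].to_dict() for c in o.columns}
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(
            {"generator": self.generator, "seed": self.seed, "params": self.params},
            default=default,
            indent=2,
            sort_keys=True,
        )


@dataclass
class CompositionSpec:
    """Shape of a random proteome: composition, count and length model."""

    frequencies: dict[str, float] = field(default_factory=lambda: dict(ECOLI_COMPOSITION))
    n_proteins: int = 500
    mean_length: int = 300
    length_sd: int = 80
    min_length: int = 30

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            self.frequencies = {a: f / total for a, f in self.frequencies.items()}


def generate_proteome(
    spec: CompositionSpec | None = None, seed: int = 0
) -> tuple[list[ProteinRecord], TruthRecord]:
    """Random proteome with i.i.d. residues at the stated composition."""
    spec = spec or CompositionSpec()
    if spec.n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)
    letters = np.array(list(spec.frequencies))
    probs = np.array([spec.frequencies[a] for a in letters])
    probs = probs / probs.sum()
    records = []
    width = len(str(spec.n_proteins))
    for i in range(spec.n_proteins):
        length = max(spec.min_length, int(round(rng.normal(spec.mean_length, spec.length_sd))))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(ProteinRecord(f"SYN{i + 1:0{width}d}", seq))
    truth = TruthRecord(
        "proteome",
        seed,
        {
            "n_proteins": spec.n_proteins,
            "mean_length": spec.mean_length,
            "frequencies": spec.frequencies,
        },
    )
    return records, truth


# ----------------------------------------------------------- truth profiles

def _preference_profile(prefs: dict[str, dict[str, float]]) -> SpecificityMatrix:
    """Columns = background composition, with stated residues overridden.

    For each position, preferred residues take their stated frequencies
    and the remaining probability mass is spread over the other residues
    in proportion to the background.
    """
    bg = pd.Series(ECOLI_COMPOSITION)
    cols = {}
    for pos in POSITION_LABELS:
        col = bg.copy()
        if pos in prefs:
            override = prefs[pos]
            mass = sum(override.values())
            rest = [a for a in AA20 if a not in override]
            rest_bg = col[rest] / col[rest].sum()
            col[rest] = (1.0 - mass) * rest_bg
            for a, f in override.items():
                col[a] = f
        cols[pos] = col
    values = pd.DataFrame(cols)[list(POSITION_LABELS)].reindex(list(AA20))
    return SpecificityMatrix(values, mode="enrichment")


def klk8_like_profile() -> SpecificityMatrix:
    """Tryptic-like truth profile emulating KLK8's subsite preferences.

    P1 strongly Arg with Lys a distant second; P2 aliphatic (Leu/Val/Ile);
    P3 basic (Arg/Lys) — unusual for a trypsin-like protease; P4 mildly
    Thr/Trp; P1' Ser/Met; P2' Ile/Trp/Ala/Val; P5' His; P6' Tyr.  Columns
    are probability distributions.
    """
    return _preference_profile(
        {
            "P4": {"T": 0.14, "W": 0.08},
            "P3": {"R": 0.22, "K": 0.15, "S": 0.07, "A": 0.08},
            "P2": {"L": 0.18, "V": 0.16, "I": 0.12, "N": 0.06, "S": 0.06, "T": 0.06},
            "P1": {"R": 0.70, "K": 0.14},
            "P1'": {"S": 0.26, "M": 0.13, "A": 0.10},
            "P2'": {"I": 0.13, "A": 0.11, "V": 0.10, "W": 0.06},
            "P5'": {"H": 0.10},
            "P6'": {"Y": 0.11},
        }
    )


def klk8_like_log_odds(pseudocount: float = 1.0):
    """Log-odds scoring model for the packaged KLK8-like profile.

    The profile's column distributions are treated as counts from a
    nominal 1000-event experiment against the embedded E. coli-like
    background; suitable for ranking candidate cleavage sites in protein
    substrates.
    """
    from .profile import build_log_odds

    freqs = klk8_like_profile().column_frequencies()
    counts = SpecificityMatrix(freqs * 1000.0, mode="counts")
    bg = BackgroundComposition(dict(ECOLI_COMPOSITION))
    return build_log_odds(counts, bg, pseudocount=pseudocount)


def klk8_like_psscl_truth(vmax_rate: float = 100.0) -> SpecificityMatrix:
    """P4..P1 truth rate matrix over the PSSCL alphabet (Nle for Cys)."""
    prof = klk8_like_profile().values[list(SUBLIBRARIES)]
    rates = prof / prof.max(axis=0) * vmax_rate
    rates.index = [("n" if a == "C" else a) for a in rates.index]
    rates = rates.reindex(list(AA_PSSCL))
    return SpecificityMatrix(rates, mode="rate")


# --------------------------------------------------------------- PICS tables

def _gluc_fragments(seq: str, rule: DigestRule) -> list[tuple[int, int]]:
    bounds = [0]
    for i in range(len(seq) - 1):
        if rule.cuts_after(seq, i):
            bounds.append(i + 1)
    bounds.append(len(seq))
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _draw_from(rng: np.random.Generator, letters: np.ndarray, probs: np.ndarray) -> str:
    return str(rng.choice(letters, p=probs))


def simulate_pics_experiment(
    proteome: Sequence[ProteinRecord],
    truth_model: SpecificityMatrix | None = None,
    n_true: int = 73,
    n_decoy: int = 200,
    fold_noise_sd: float = 0.3,
    seed: int = 0,
    threshold: float = 8.0,
    rule: DigestRule = DigestRule(),
    length_range: tuple[int, int] = (6, 30),
) -> tuple[list[ProteinRecord], pd.DataFrame, TruthRecord]:
    """Plant cleavage sites into a proteome and emit a quantification table.

    Returns ``(planted_proteome, quant_table, truth)``.  Each of the
    ``n_true`` sites is a cassette spliced into a copy of the proteome: a
    library-protease (GluC) cut site, a spacer, and a P6..P6' cleavage
    window whose residues are drawn per position from the
    composition-weighted truth profile ``q(a, p) ~ f_bg(a) * truth(a, p)``
    — the residue distribution that cleavage-site selection in proportion
    to the truth-model likelihood induces on a background proteome, so
    the abundance-corrected heat map converges to the truth profile.  The
    site's semi-specific peptide (neo C-terminus at the planted bond)
    gets a log-normal fold change guaranteed above the acceptance
    threshold.  Decoys are fully specific library fragments above
    threshold (rejected as digestion products) and semi-specific peptides
    at or below threshold (removed by the fold-change filter), so exactly
    ``n_true`` events survive the full pipeline.
    """
    truth_model = truth_model if truth_model is not None else klk8_like_profile()
    rng = np.random.default_rng(seed)
    freqs = truth_model.column_frequencies()
    bg = pd.Series(
        {a: f for a, f in ECOLI_COMPOSITION.items()}, dtype=float
    ).reindex(list(AA20))
    # per-position sampling law for planted windows
    q = freqs.mul(bg, axis=0)
    q = q / q.sum(axis=0)
    # nonprime-side residues may not recreate a library cut (no Glu)
    q_nonprime = q[list(NONPRIME := ("P6", "P5", "P4", "P3", "P2", "P1"))].copy()
    q_nonprime.loc["E"] = 0.0
    q_nonprime = q_nonprime / q_nonprime.sum(axis=0)
    letters = np.array(list(AA20))
    bg_no_e = bg.copy()
    bg_no_e["E"] = 0.0
    bg_no_e = (bg_no_e / bg_no_e.sum()).to_numpy()
    bg_no_ep = bg.copy()
    bg_no_ep[["E", "P"]] = 0.0
    bg_no_ep = (bg_no_ep / bg_no_ep.sum()).to_numpy()

    lo, hi = length_range
    min_left, max_left = max(lo, 8), min(hi, 20)
    sequences = {rec.id: list(rec.sequence) for rec in proteome}
    ids = [rec.id for rec in proteome]
    used_regions: dict[str, list[tuple[int, int]]] = {rid: [] for rid in ids}

    planted: list[dict] = []
    attempts = 0
    while len(planted) < n_true:
        attempts += 1
        if attempts > 50 * n_true:
            raise ValueError(f"proteome too small to host {n_true} planted sites")
        rid = ids[int(rng.integers(len(ids)))]
        seq = sequences[rid]
        left_len = int(rng.integers(min_left, max_left + 1))
        span = 1 + left_len + 6  # E + peptide + prime-side window
        if len(seq) < span + 2:
            continue
        o = int(rng.integers(1, len(seq) - span))
        if any(o < e + 1 and o + span + 1 > s for s, e in used_regions[rid]):
            continue
        cassette = ["E"]
        cassette.append(_draw_from(rng, letters, bg_no_ep))  # P1' of the library cut
        for _ in range(left_len - 7):
            cassette.append(_draw_from(rng, letters, bg_no_e))
        for pos in ("P6", "P5", "P4", "P3", "P2", "P1"):
            cassette.append(_draw_from(rng, letters, q_nonprime[pos].to_numpy()))
        for pos in ("P1'", "P2'", "P3'", "P4'", "P5'", "P6'"):
            cassette.append(_draw_from(rng, letters, q[pos].to_numpy()))
        seq[o : o + span] = cassette
        peptide = "".join(seq[o + 1 : o + 1 + left_len])
        p1_index = o + 1 + left_len  # 1-based residue N-terminal to the bond
        used_regions[rid].append((o, o + span))
        planted.append(
            {"protein_id": rid, "p1_index": p1_index, "peptide": peptide, "neo_terminus": "C"}
        )

    planted_proteome = [
        ProteinRecord(rid, "".join(sequences[rid])) for rid in ids
    ]
    index = ProteomeIndex(planted_proteome)
    bad = [ev for ev in planted if len(index.find_all(ev["peptide"])) != 1]
    if bad:
        # coincidental duplicates elsewhere in the random background;
        # extremely rare for peptides of >= 8 residues
        raise ValueError(
            f"{len(bad)} planted peptide(s) occur more than once; re-run with another seed"
        )

    def lognormal_fc(log2_mean: float) -> float:
        return float(2.0 ** rng.normal(log2_mean, fold_noise_sd))

    used_peptides = {ev["peptide"] for ev in planted}
    rows = []
    for ev in planted:
        fc = lognormal_fc(5.0)
        while fc <= threshold:  # guarantee acceptance of planted truths
            fc = lognormal_fc(5.0)
        base = float(rng.lognormal(np.log(1e6), 0.5))
        rows.append((ev["peptide"], base * fc, base))

    # decoy class 1: fully specific library fragments, enriched > threshold
    frag_pool = []
    for rec in planted_proteome:
        for a, b in _gluc_fragments(rec.sequence, rule):
            pep = rec.sequence[a:b]
            if lo <= len(pep) <= hi and pep not in used_peptides:
                frag_pool.append(pep)
    frag_pool = sorted(set(frag_pool))
    rng.shuffle(frag_pool)
    n_specific = n_decoy // 2
    if len(frag_pool) < n_specific:
        raise ValueError("proteome too small to supply fully-specific decoys")
    for pep in frag_pool[:n_specific]:
        fc = lognormal_fc(5.0)
        while fc <= threshold:
            fc = lognormal_fc(5.0)
        base = float(rng.lognormal(np.log(1e6), 0.5))
        rows.append((pep, base * fc, base))
        used_peptides.add(pep)

    # decoy class 2: semi-specific peptides at or below the threshold
    # (prefixes of library fragments: N-terminus conforms, C-terminus neo)
    n_low = n_decoy - n_specific
    added = 0
    for pep in frag_pool[n_specific:]:
        if added == n_low:
            break
        cut = len(pep) - 1 if len(pep) - 1 >= lo else len(pep)
        sub = pep[:cut]
        if sub in used_peptides:
            continue
        fc = threshold if added == 0 else min(lognormal_fc(1.0), threshold)
        base = float(rng.lognormal(np.log(1e6), 0.5))
        rows.append((sub, base * fc, base))
        used_peptides.add(sub)
        added += 1

    quant = pd.DataFrame(rows, columns=["peptide", "intensity_treated", "intensity_control"])
    quant = quant.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
    truth = TruthRecord(
        "pics",
        seed,
        {
            "n_true": n_true,
            "n_decoy": len(rows) - n_true,
            "threshold": threshold,
            "expected_accepted": n_true,
            "events": planted,
            "truth_matrix": freqs,
        },
    )
    return planted_proteome, quant, truth


# --------------------------------------------------------------- PSSCL plates

def simulate_psscl(
    truth: SpecificityMatrix | None = None,
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[PSSCLPlate, TruthRecord]:
    """PSSCL plate readout around a P4..P1 truth rate matrix."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    truth = truth if truth is not None else klk8_like_psscl_truth()
    rng = np.random.default_rng(seed)
    wells = []
    for sub in SUBLIBRARIES:
        for aa in truth.alphabet:
            mu = float(truth.values.at[aa, sub])
            for rep in range(1, replicates + 1):
                rate = mu * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else mu
                wells.append(PSSCLWell(sub, aa, rep, max(rate, 0.0)))
    plate = PSSCLPlate(wells, assay=dict(DEFAULT_ASSAY))
    record = TruthRecord(
        "psscl",
        seed,
        {"replicates": replicates, "noise_cv": noise_cv, "truth_matrix": truth.values},
    )
    return plate, record


# ------------------------------------------------------------------- kinetics

def simulate_mm_rates(
    kcat: float,
    km_uM: float,
    substrate_uM: Sequence[float],
    enzyme_total_nM: float = 60.0,
    active_fraction: float = 1.0,
    noise_cv: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[KineticSeries, TruthRecord]:
    """Initial rates from the Michaelis-Menten law + multiplicative noise."""
    rng = np.random.default_rng(seed)
    s = np.repeat(np.asarray(substrate_uM, dtype=float), replicates)
    e_uM = enzyme_total_nM * active_fraction / 1000.0
    v = kcat * e_uM * s / (km_uM + s)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=v.shape))
    series = KineticSeries(
        substrate_uM=s,
        rates=np.clip(v, 0.0, None),
        enzyme_total_nM=enzyme_total_nM,
        active_fraction=active_fraction,
    )
    truth = TruthRecord(
        "mm", seed, {"kcat": kcat, "km_uM": km_uM, "noise_cv": noise_cv}
    )
    return series, truth


def simulate_progress_curve(
    kcat: float,
    km_uM: float,
    enzyme_uM: float,
    s0_uM: float,
    t_end: float = 300.0,
    dt_sample: float = 20.0,
    calibration: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ProgressCurve, TruthRecord]:
    """Progress curve by RK4 integration of substrate depletion (1 s steps).

    dP/dt = kcat * E * (S0 - P) / (KM + S0 - P); the signal is
    baseline + calibration * P plus additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)

    def rate(p):
        s = max(s0_uM - p, 0.0)
        return kcat * enzyme_uM * s / (km_uM + s)

    h = 1.0
    n_steps = int(round(t_end / h))
    p = 0.0
    ts, ps = [0.0], [0.0]
    for i in range(n_steps):
        k1 = rate(p)
        k2 = rate(p + 0.5 * h * k1)
        k3 = rate(p + 0.5 * h * k2)
        k4 = rate(p + h * k3)
        p += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append((i + 1) * h)
        ps.append(p)
    ts, ps = np.array(ts), np.array(ps)
    keep = np.isclose(ts % dt_sample, 0.0) | np.isclose(ts % dt_sample, dt_sample)
    t_samp, p_samp = ts[keep], ps[keep]
    signal = baseline + calibration * p_samp
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    curve = ProgressCurve(
        times=t_samp, signal=signal, calibration=calibration, substrate_uM=s0_uM
    )
    truth = TruthRecord(
        "progress_curve",
        seed,
        {"kcat": kcat, "km_uM": km_uM, "enzyme_uM": enzyme_uM, "s0_uM": s0_uM,
         "v0_uM_s": rate(0.0)},
    )
    return curve, truth


def simulate_inhibition_panel(
    mechanism: str,
    vmax: float = 1.0,
    km_uM: float = 15.0,
    ki_uM: float = DEFAULT_ZN_KI_UM,
    alpha: float = 1.0,
    substrate_uM: Sequence[float] = (5.0, 10.0, 20.0, 50.0, 100.0),
    inhibitor_uM: Sequence[float] = (0.0, 2.0, 10.0),
    noise_cv: float = 0.02,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[list[KineticSeries], TruthRecord]:
    """Rate panel at several inhibitor levels from a chosen mechanism."""
    rng = np.random.default_rng(seed)
    s = np.repeat(np.asarray(substrate_uM, dtype=float), replicates)
    panel = []
    for i_level in inhibitor_uM:
        v = _mechanism_rate(mechanism, s, float(i_level), vmax, km_uM, ki_uM, alpha)
        if noise_cv > 0:
            v = v * (1.0 + rng.normal(0.0, noise_cv, size=v.shape))
        panel.append(
            KineticSeries(
                substrate_uM=s,
                rates=np.clip(v, 0.0, None),
                modifier="inhibitor",
                modifier_uM=float(i_level),
            )
        )
    truth = TruthRecord(
        "inhibition",
        seed,
        {"mechanism": mechanism, "vmax": vmax, "km_uM": km_uM, "ki_uM": ki_uM,
         "alpha": alpha, "noise_cv": noise_cv},
    )
    return panel, truth


def simulate_dose_response(
    ic50_uM: float,
    conc_uM: Sequence[float],
    hill: float = 1.0,
    top: float = 1.0,
    bottom: float = 0.0,
    noise_cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Rates from a log-logistic inhibition curve + multiplicative noise."""
    rng = np.random.default_rng(seed)
    c = np.repeat(np.asarray(conc_uM, dtype=float), replicates)
    ratio = np.zeros_like(c)
    nz = c > 0
    ratio[nz] = (c[nz] / ic50_uM) ** hill
    v = bottom + (top - bottom) / (1.0 + ratio)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=v.shape))
    truth = TruthRecord(
        "dose_response",
        seed,
        {"ic50_uM": ic50_uM, "hill": hill, "top": top, "bottom": bottom,
         "noise_cv": noise_cv},
    )
    return c, np.clip(v, 0.0, None), truth


def simulate_burst_curve(
    active_fraction: float = 0.62,
    enzyme_total_nM: float = 120.0,
    epsilon: float = EPSILON_PNP_410,
    path_length: float = 1.0,
    k_burst: float = 0.05,
    steady_slope: float = 2e-6,
    baseline: float = 0.01,
    times: Sequence[float] | None = None,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> tuple[ProgressCurve, TruthRecord]:
    """Burst-titration progress curve at a stated active fraction.

    The burst amplitude is pi = epsilon * l * [E_active]; noise is
    Gaussian with SD equal to ``noise_frac`` of the amplitude.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times if times is not None else np.arange(0.0, 601.0, 10.0), dtype=float)
    active_M = enzyme_total_nM * active_fraction * 1e-9
    pi = epsilon * path_length * active_M
    signal = pi * (1.0 - np.exp(-k_burst * t)) + steady_slope * t + baseline
    if noise_frac > 0:
        signal = signal + rng.normal(0.0, noise_frac * pi, size=signal.shape)
    curve = ProgressCurve(times=t, signal=signal, calibration=1.0, path_length=path_length)
    truth = TruthRecord(
        "burst",
        seed,
        {"active_fraction": active_fraction, "enzyme_total_nM": enzyme_total_nM,
         "epsilon": epsilon, "path_length": path_length, "burst_amplitude": pi,
         "k_burst": k_burst, "steady_slope": steady_slope},
    )
    return curve, truth


def simulate_activation(
    fold_max: float = 2.0,
    k_act_uM: float = 60.0,
    v0: float = 1.0,
    k_att_uM: float | None = None,
    conc_uM: Sequence[float] = (0.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
    noise_cv: float = 0.03,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Rates from the hyperbolic activation model + multiplicative noise."""
    rng = np.random.default_rng(seed)
    a = np.repeat(np.asarray(conc_uM, dtype=float), replicates)
    v = _activation_rate(a, v0, fold_max, k_act_uM, k_att_uM)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=v.shape))
    truth = TruthRecord(
        "activation",
        seed,
        {"fold_max": fold_max, "k_act_uM": k_act_uM, "v0": v0,
         "k_att_uM": k_att_uM, "noise_cv": noise_cv},
    )
    return a, np.clip(v, 0.0, None), truth
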