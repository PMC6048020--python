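"""Published reference values for KLK8 used as worked-example inputs.

These are literature-reported kinetic and regulatory parameters of human
kallikrein-related peptidase 8 (KLK8/neuropsin) with synthetic
tetrapeptide substrates.  They serve as inputs for worked examples and
for generating synthetic datasets at realistic parameter values; none of
them is produced by this package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SubstrateKinetics:
    """Published kcat (s^-1), KM (µM) and catalytic efficiency (M^-1 s^-1)."""

    name: str
    kcat: float
    kcat_se: float
    km_uM: float
    km_se: float
    efficiency_printed: float  # published kcat/KM, at its printed rounding
    efficiency_precision: float  # rounding step of the printed efficiency


#: KLK8 kinetic parameters with synthetic substrates (25 C for AMC/ACC).
KLK8_SUBSTRATES: tuple[SubstrateKinetics, ...] = (
    SubstrateKinetics("Ac-Thr-Lys-Leu-Arg-ACC", 48.0, 2.1, 15.3, 1.5, 3_137_300.0, 100.0),
    SubstrateKinetics("Ac-Thr-Lys-Leu-Arg-AMC", 43.9, 6.2, 14.4, 0.2, 3_049_000.0, 1000.0),
    SubstrateKinetics("Z-Val-Val-Arg-AMC", 6.5, 0.9, 57.5, 10.7, 113_000.0, 1000.0),
    SubstrateKinetics("Boc-Val-Pro-Arg-AMC", 8.8, 0.4, 434.0, 100.2, 20_300.0, 100.0),
    SubstrateKinetics("Bz-Pro-Phe-Arg-pNA", 2.0, 0.5, 430.0, 68.0, 4_650.0, 10.0),
)

#: Zn2+ IC50 values (µM) for wild-type KLK8 and 99-loop variants.
ZN_IC50_UM: dict[str, float] = {
    "wild_type": 3.6,
    "H99A": 46.7,
    "Y94F": 6.9,
}

#: Active fraction of the recombinant KLK8 preparation by NPGB burst
#: titration (percent).
ACTIVE_FRACTION_PCT: float = 62.0

#: Maximal Ca2+ fold-stimulation with the optimized ACC/AMC substrates.
CA_FOLD_STIMULATION: float = 2.0

#: Number of cleavage events in the KLK8 PICS profiling experiment.
PICS_EVENT_COUNT: int = 73
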