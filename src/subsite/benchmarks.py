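"""End-to-end recovery benchmarks run on synthetic data.

Each function generates data at a published KLK8 parameter value with the
:mod:`subsite.simulate` generators, runs the corresponding fitting or
pipeline stage, and reports the recovered quantity.  They are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import reference, simulate
from .kinetics import (
    fit_activation,
    fit_burst_titration,
    fit_dose_response,
)
from .pics import run_pics

#: Zn2+ titration designs per variant (µM); the H99A variant needs a
#: higher range because its IC50 is an order of magnitude larger.
ZN_DOSE_LEVELS: dict[str, tuple[float, ...]] = {
    "wild_type": (0.5, 1.0, 2.0, 5.0, 10.0, 50.0, 100.0, 500.0),
    "Y94F": (0.5, 1.0, 2.0, 5.0, 10.0, 50.0, 100.0, 500.0),
    "H99A": tuple(np.round(np.logspace(np.log10(2.0), np.log10(2000.0), 8), 3)),
}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def efficiency_values() -> dict[str, float]:
    """kcat/KM (M^-1 s^-1) computed from the published kcat and KM values."""
    return {
        sub.name: sub.kcat / (sub.km_uM * 1e-6) for sub in reference.KLK8_SUBSTRATES
    }


def zn_ic50_recovery(
    variant: str = "wild_type",
    seed: int = 0,
    n_rep: int = 20,
    noise_cv: float = 0.05,
    replicates: int = 3,
) -> dict:
    """Mean IC50 recovered from synthetic Zn2+ inhibition titrations.

    Rates are generated from a log-logistic inhibition curve (hill 1,
    bottom 0) at the published IC50 of the chosen variant, with
    multiplicative noise, and refit with the four-parameter model
    (bottom pinned at 0).
    """
    true_ic50 = reference.ZN_IC50_UM[variant]
    levels = ZN_DOSE_LEVELS[variant]
    fits, ses = [], []
    for rep_seed in _spawn_seeds(seed, n_rep):
        c, v, _ = simulate.simulate_dose_response(
            true_ic50, levels, hill=1.0, top=1.0, bottom=0.0,
            noise_cv=noise_cv, replicates=replicates, seed=rep_seed,
        )
        fit = fit_dose_response(c, v, fix_bottom=0.0)
        fits.append(fit.ic50)
        ses.append(fit.ic50_se)
    return {
        "variant": variant,
        "true_ic50_uM": true_ic50,
        "mean_ic50_uM": float(np.mean(fits)),
        "sd_ic50_uM": float(np.std(fits, ddof=1)),
        "mean_ci_halfwidth_uM": float(1.96 * np.nanmean(ses)),
        "n_rep": n_rep,
    }


def burst_recovery(seed: int = 0, n_rep: int = 10, noise_frac: float = 0.02) -> dict:
    """Mean active-enzyme percentage recovered from synthetic NPGB bursts."""
    fracs = []
    for rep_seed in _spawn_seeds(seed, n_rep):
        curve, truth = simulate.simulate_burst_curve(
            active_fraction=reference.ACTIVE_FRACTION_PCT / 100.0,
            enzyme_total_nM=120.0,
            noise_frac=noise_frac,
            seed=rep_seed,
        )
        fit = fit_burst_titration(
            curve, epsilon=truth.params["epsilon"], enzyme_total_nM=120.0
        )
        fracs.append(fit.active_fraction_pct)
    return {
        "true_pct": reference.ACTIVE_FRACTION_PCT,
        "mean_pct": float(np.mean(fracs)),
        "sd_pct": float(np.std(fracs, ddof=1)),
        "n_rep": n_rep,
    }


def pics_event_count(seed: int = 7, n_proteins: int = 500, n_decoy: int = 200) -> dict:
    """Accepted-event count of the full PICS pipeline on the planted fixture."""
    proteome, _ = simulate.generate_proteome(
        simulate.CompositionSpec(n_proteins=n_proteins), seed=seed
    )
    planted, quant, truth = simulate.simulate_pics_experiment(
        proteome, n_true=reference.PICS_EVENT_COUNT, n_decoy=n_decoy, seed=seed
    )
    result = run_pics(planted, quant)
    return {
        "expected": truth.params["expected_accepted"],
        "accepted": len(result.events),
        "n_peptides": len(quant),
        "report": result.report,
    }


def activation_recovery(seed: int = 0, n_rep: int = 20, noise_cv: float = 0.03) -> dict:
    """Mean maximal fold-stimulation recovered from synthetic Ca2+ curves."""
    folds = []
    for rep_seed in _spawn_seeds(seed, n_rep):
        a, v, _ = simulate.simulate_activation(
            fold_max=reference.CA_FOLD_STIMULATION,
            k_act_uM=60.0,
            noise_cv=noise_cv,
            seed=rep_seed,
        )
        folds.append(fit_activation(a, v).fold_max)
    return {
        "true_fold": reference.CA_FOLD_STIMULATION,
        "mean_fold": float(np.mean(folds)),
        "sd_fold": float(np.std(folds, ddof=1)),
        "n_rep": n_rep,
    }
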