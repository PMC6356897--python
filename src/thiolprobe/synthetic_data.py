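"""In-silico differential-alkylation experiments with known ground truth.

Emulates the two-stage labelling protocol on a two-cysteine protein of base
mass 11,712.6 Da: stage 1 probes the attacking cysteine (IAM/protein = 2,
105 s incubation), stage 2 probes the resolving cysteine after complete
pre-monoalkylation at pH 7.1 (IAM/protein = 10, 2 min). Two generators are
deliberately kept separate:

* the *phenomenological* generator draws fractions straight from the
  Henderson-Hasselbalch sigmoid the fitting model assumes (model-matched,
  unbiased) — the basis for pKa-recovery checks;
* the *kinetic* generator integrates the reagent-depletion reaction scheme
  at each pH, which carries the endpoint-saturation bias any fixed-time
  alkylation protocol has (the apparent pKa is pulled below the true one
  once conversion saturates).

All randomness flows from a single master seed through ``SeedSequence``
spawning, so every output (manifests included) is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alkylation_kinetics import (
    AlkylationScheme,
    CysSite,
    ReactionConditions,
    SpeciesFractions,
    simulate_with_depletion,
)
from .spectra import SpeciesLayout, render_spectrum, write_spectrum
from .titration import TitrationSeries, hh_model
from .inactivation import ActivityTimecourse

__all__ = [
    "ExperimentConfig",
    "generate_titration_phenomenological",
    "generate_titration_kinetic",
    "generate_spectra",
    "generate_inactivation",
]

#: parental (non-alkylated, average) mass of the model protein, Da
BASE_MASS = 11712.6


@dataclass
class ExperimentConfig:
    """Ground truth and protocol parameters for one in-silico experiment.

    Concentrations follow the wet protocol's dilution arithmetic: stage 1
    mixes 2.1 uL of 230 uM protein with 1 uL of 1 mM IAM in 10 uL (48.3 uM
    protein, 100 uM IAM, ratio ~2); stage 2 mixes 2.4 uL of 200 uM
    pre-monoalkylated protein with 385 uM IAM at the stated IAM/TRX
    ratio of 10 (the printed dilution volumes imply ~48 uM protein and a
    ratio of 8; the stated ratio wins, via P0 = 38.5 uM). The intrinsic thiolate rate constants
    are free simulation parameters (not reported quantities), set so stage-1
    monoalkylation is partial on the 105 s timescale.
    """

    pKa_N: float = 6.63
    pKa_C: float = 9.53
    k_int_N: float = 100.0  # M^-1 s^-1
    k_int_C: float = 100.0
    base_mass: float = BASE_MASS

    stage1_P0: float = 48.3e-6  # M
    stage1_IAM0: float = 100.0e-6
    stage1_t: float = 105.0  # s
    stage2_P0: float = 38.5e-6
    stage2_IAM0: float = 385.0e-6
    stage2_t: float = 120.0
    prealkylation_pH: float = 7.1

    pH_grid: tuple[float, ...] = tuple(np.round(np.arange(4.5, 10.01, 0.5), 1))
    n_replicates_step1: int = 3
    n_replicates_step2: int = 2
    fraction_noise_sd: float = 0.03

    sigma: float = 6.0
    adduct_delta: float = 206.2
    adduct_intensity: float = 0.15
    spectrum_noise_rel: float = 0.01  # noise sd as a fraction of max peak height

    inact_IAM_doses: tuple[float, ...] = (0.05e-3, 0.1e-3)  # M
    inact_pH_values: tuple[float, ...] = (5.0, 6.0, 6.5, 7.0, 8.0)
    inact_times_min: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0)
    inact_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.pH_grid) < 3.5 or max(self.pH_grid) > 10.5:
            raise ValueError("pH grid must stay within [3.5, 10.5]")
        if self.stage1_IAM0 <= 0 or self.stage2_IAM0 <= 0:
            raise ValueError("IAM concentrations must be > 0")

    @property
    def scheme(self) -> AlkylationScheme:
        return AlkylationScheme(
            CysSite("CysN", self.pKa_N, self.k_int_N),
            CysSite("CysC", self.pKa_C, self.k_int_C),
        )

    def true_pKa(self, stage: str) -> float:
        return self.pKa_N if stage == "step1" else self.pKa_C

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_titration_phenomenological(
    config: ExperimentConfig, seed: int, stage: str = "step1"
) -> tuple[TitrationSeries, dict]:
    """Model-matched titration series: sigmoid plus clipped Gaussian noise.

    Stage 1 reports the fraction of non-alkylated protein (midpoint at the
    CysN pKa); stage 2 the fraction of monoalkylated protein (midpoint at
    the CysC pKa). Both run from top plateau 1 to bottom plateau 0.
    """
    if stage not in ("step1", "step2"):
        raise ValueError(f"unknown stage {stage!r}")
    true_pka = config.true_pKa(stage)
    n_rep = (config.n_replicates_step1 if stage == "step1"
             else config.n_replicates_step2)
    pH = np.array(config.pH_grid, dtype=float)
    truth = hh_model(pH, true_pka, 1.0, 0.0)
    (rng,) = _rngs(seed, 1)
    rows_pH, rows_frac, rows_rep = [], [], []
    for rep in range(1, n_rep + 1):
        noisy = np.clip(truth + rng.normal(0.0, config.fraction_noise_sd, pH.size),
                        0.0, 1.0)
        rows_pH.append(pH)
        rows_frac.append(noisy)
        rows_rep.append(np.full(pH.size, rep))
    series = TitrationSeries(
        np.concatenate(rows_pH), np.concatenate(rows_frac),
        np.concatenate(rows_rep), stage,
    )
    manifest = {
        "generator": "phenomenological",
        "stage": stage,
        "true_pKa": true_pka,
        "noise_sd": config.fraction_noise_sd,
        "n_replicates": n_rep,
        "seed": seed,
        "true_fractions": {f"{p:.1f}": float(f) for p, f in zip(pH, truth)},
    }
    return series, manifest


def _kinetic_fractions(config: ExperimentConfig, stage: str) -> list[tuple[float, SpeciesFractions]]:
    scheme = config.scheme
    out = []
    if stage == "step1":
        for pH in config.pH_grid:
            cond = ReactionConditions(pH, config.stage1_IAM0, config.stage1_P0,
                                      config.stage1_t)
            out.append((pH, simulate_with_depletion(scheme, cond)))
    else:
        # stage-2 initial condition: pre-monoalkylation at pH 7.1 idealized
        # as complete (the attacking Cys is fully labelled before step 2)
        initial = SpeciesFractions(0.0, 1.0, 0.0)
        for pH in config.pH_grid:
            cond = ReactionConditions(pH, config.stage2_IAM0, config.stage2_P0,
                                      config.stage2_t)
            out.append((pH, simulate_with_depletion(scheme, cond, initial=initial)))
    return out


def generate_titration_kinetic(
    config: ExperimentConfig, seed: int, stage: str = "step1"
) -> tuple[TitrationSeries, dict]:
    """Titration series from the reagent-depletion kinetic forward model."""
    if stage not in ("step1", "step2"):
        raise ValueError(f"unknown stage {stage!r}")
    endpoints = _kinetic_fractions(config, stage)
    pH = np.array([p for p, _ in endpoints])
    truth = np.array([f.fR if stage == "step1" else f.fM for _, f in endpoints])
    n_rep = (config.n_replicates_step1 if stage == "step1"
             else config.n_replicates_step2)
    (rng,) = _rngs(seed, 1)
    rows_pH, rows_frac, rows_rep = [], [], []
    for rep in range(1, n_rep + 1):
        noisy = np.clip(truth + rng.normal(0.0, config.fraction_noise_sd, pH.size),
                        0.0, 1.0)
        rows_pH.append(pH)
        rows_frac.append(noisy)
        rows_rep.append(np.full(pH.size, rep))
    series = TitrationSeries(
        np.concatenate(rows_pH), np.concatenate(rows_frac),
        np.concatenate(rows_rep), stage,
    )
    manifest = {
        "generator": "kinetic",
        "stage": stage,
        "true_pKa": config.true_pKa(stage),
        "noise_sd": config.fraction_noise_sd,
        "n_replicates": n_rep,
        "seed": seed,
        "true_fractions": {
            f"{p:.1f}": {"fR": f.fR, "fM": f.fM, "fD": f.fD}
            for p, f in endpoints
        },
    }
    return series, manifest


def generate_spectra(
    config: ExperimentConfig,
    seed: int,
    out_dir,
    stage: str = "step1",
    kinetic: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Write one spectrum text file per (pH, replicate) plus manifest files.

    Stage-1 spectra contain the reduced/mono/di ladder starting at the base
    mass; stage-2 spectra start at the monoalkylated mass (no reduced
    species survives pre-alkylation). Returns the manifest table; also
    writes ``manifest.csv`` and ``truth.json`` into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kinetic:
        endpoints = _kinetic_fractions(config, stage)
        frac_maps = []
        for pH, f in endpoints:
            if stage == "step1":
                frac_maps.append((pH, {"reduced": f.fR, "mono": f.fM, "di": f.fD}))
            else:
                frac_maps.append((pH, {"mono": f.fM, "di": f.fD}))
    else:
        pHs = np.array(config.pH_grid)
        tr = hh_model(pHs, config.true_pKa(stage), 1.0, 0.0)
        if stage == "step1":
            frac_maps = [(p, {"reduced": t, "mono": 1 - t, "di": 0.0})
                         for p, t in zip(pHs, tr)]
        else:
            frac_maps = [(p, {"mono": t, "di": 1 - t}) for p, t in zip(pHs, tr)]

    layout = SpeciesLayout.for_alkylation(
        config.base_mass,
        n_species=3 if stage == "step1" else 2,
        first_n_cam=0 if stage == "step1" else 1,
        sigma=config.sigma,
        adduct_delta=config.adduct_delta,
        adduct_intensity=config.adduct_intensity,
    )
    n_rep = (config.n_replicates_step1 if stage == "step1"
             else config.n_replicates_step2)
    peak_height = 1.0 / (config.sigma * np.sqrt(2 * np.pi))
    noise_sd = config.spectrum_noise_rel * peak_height
    rngs = _rngs(seed, len(frac_maps) * n_rep)
    rows = []
    truth: dict = {"seed": seed, "stage": stage, "config": config.to_dict(),
                   "files": {}}
    i = 0
    for pH, fmap in frac_maps:
        for rep in range(1, n_rep + 1):
            spec = render_spectrum(fmap, layout, noise_sd=noise_sd, seed=rngs[i],
                                   pH=pH, replicate=rep, stage=stage)
            fname = f"spectrum_{stage}_pH{pH:.1f}_rep{rep}.txt"
            write_spectrum(spec, out_dir / fname)
            rows.append({"file": fname, "pH": pH, "replicate": rep, "stage": stage})
            truth["files"][fname] = {k: float(v) for k, v in fmap.items()}
            i += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest, truth


def generate_inactivation(
    config: ExperimentConfig, seed: int
) -> list[ActivityTimecourse]:
    """Activity time courses at two IAM doses across the assayed pH values.

    Residual activity follows single-site Poisson survival in the attacking
    cysteine's thiolate, exp(-k_int * alpha(pH) * [IAM] * t), plus clipped
    Gaussian noise. At pH 5 the thiolate fraction is negligible and the
    course is flat.
    """
    t_s = np.array(config.inact_times_min) * 60.0
    combos = [(d, p) for d in config.inact_IAM_doses for p in config.inact_pH_values]
    rngs = _rngs(seed, len(combos))
    alpha = lambda pH: 1.0 / (1.0 + 10.0 ** (config.pKa_N - pH))
    out = []
    for rng, (dose, pH) in zip(rngs, combos):
        clean = np.exp(-config.k_int_N * alpha(pH) * dose * t_s)
        noisy = clean
        if config.inact_noise_sd > 0:
            noisy = np.clip(clean + rng.normal(0, config.inact_noise_sd, t_s.size),
                            1e-6, None)
        out.append(ActivityTimecourse(np.array(config.inact_times_min), noisy,
                                      pH=pH, IAM_M=dose))
    return out
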