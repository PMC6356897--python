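"""Synthetic intact-protein MALDI-TOF spectra and peak-area quantification.

Rendering: each protein species (reduced, mono-, dialkylated) contributes a
Gaussian centred at its mass, with area proportional to its fraction, plus
an optional matrix-adduct satellite at ``mass + adduct_delta``. Quantification
inverts that: trapezoidal peak areas over windows around each expected mass,
after subtracting a linear baseline anchored at the window edges, and
fractions as area ratios under an equal-response assumption — the same
digital-integration readout the wet protocol uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alkylation_kinetics import SpeciesFractions

__all__ = [
    "Spectrum",
    "SpeciesLayout",
    "AreaReport",
    "render_spectrum",
    "integrate_species",
    "fractions_from_areas",
    "read_spectrum",
    "write_spectrum",
]

#: default linear-mode peak sigma at ~11.7 kDa, in Da
DEFAULT_SIGMA = 6.0
#: default sinapinic-acid matrix adduct offset, Da (a convention; the adduct
#: identity is instrument/matrix dependent)
DEFAULT_ADDUCT_DELTA = 206.2
DEFAULT_ADDUCT_INTENSITY = 0.15


class SpectrumRangeError(ValueError):
    """The m/z range does not cover the declared species peaks."""


class EmptySpectrumError(ValueError):
    """All integration windows are empty; fractions are undefined."""


@dataclass
class Spectrum:
    """An intact-protein mass spectrum on a uniform m/z grid."""

    mz: np.ndarray
    intensity: np.ndarray
    pH: float | None = None
    replicate: int | None = None
    stage: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size < 2 or np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz grid must be strictly increasing")


@dataclass
class SpeciesLayout:
    """Expected species masses, peak width and adduct model for one spectrum."""

    species: list[tuple[str, float]]
    sigma: float = DEFAULT_SIGMA
    adduct_delta: float = DEFAULT_ADDUCT_DELTA
    adduct_intensity: float = DEFAULT_ADDUCT_INTENSITY

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        masses = [m for _, m in self.species]
        if len(set(masses)) != len(masses):
            raise ValueError("species masses must be distinct")
        gaps = np.diff(np.sort(masses))
        if gaps.size and gaps.min() < 2 * self.sigma:
            warnings.warn(
                f"species separated by {gaps.min():.1f} Da < 2 sigma "
                f"({2 * self.sigma:.1f} Da); quantification may be biased",
                stacklevel=2,
            )

    @classmethod
    def for_alkylation(
        cls,
        base_mass: float,
        n_species: int = 3,
        cam_delta: float = 57.0513,
        first_n_cam: int = 0,
        **kwargs,
    ) -> "SpeciesLayout":
        """Layout for a CAM-alkylation ladder starting at ``first_n_cam`` groups."""
        names = {0: "reduced", 1: "mono", 2: "di", 3: "tri"}
        species = [
            (names.get(first_n_cam + i, f"cam{first_n_cam + i}"),
             base_mass + (first_n_cam + i) * cam_delta)
            for i in range(n_species)
        ]
        return cls(species, **kwargs)


@dataclass
class AreaReport:
    """Integrated peak areas and the species fractions derived from them."""

    areas: dict[str, float]
    windows: dict[str, tuple[float, float]]
    adduct_areas: dict[str, float] = field(default_factory=dict)

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.areas.values())
        if total <= 0:
            raise EmptySpectrumError("total integrated area is zero")
        return {name: a / total for name, a in self.areas.items()}


def render_spectrum(
    fractions: SpeciesFractions | dict[str, float],
    layout: SpeciesLayout,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    mz_range: tuple[float, float] | None = None,
    step: float = 0.5,
    **metadata,
) -> Spectrum:
    """Render a noisy Gaussian-peak spectrum from species fractions.

    Peak *areas* (not heights) are proportional to fractions; the adduct
    satellite of each species carries ``adduct_intensity`` times its parent's
    area. ``noise_sd`` is additive zero-mean Gaussian noise in intensity
    units; intensities are clipped at zero as a detector would.
    """
    if isinstance(fractions, SpeciesFractions):
        keys = [name for name, _ in layout.species]
        vals = [fractions.fR, fractions.fM, fractions.fD]
        if len(keys) != 3:
            raise ValueError("SpeciesFractions input needs a 3-species layout")
        frac_map = dict(zip(keys, vals))
    else:
        frac_map = dict(fractions)

    masses = dict(layout.species)
    lo_need = min(masses.values()) - 4 * layout.sigma
    hi_need = max(masses.values()) + layout.adduct_delta + 4 * layout.sigma
    if mz_range is None:
        mz_range = (lo_need - 50.0, hi_need + 50.0)
    if mz_range[0] > lo_need or mz_range[1] < hi_need:
        raise SpectrumRangeError(
            f"mz_range {mz_range} does not cover species peaks "
            f"[{lo_need:.1f}, {hi_need:.1f}]"
        )
    mz = np.arange(mz_range[0], mz_range[1] + step / 2, step)
    intensity = np.zeros_like(mz)
    norm = 1.0 / (layout.sigma * np.sqrt(2.0 * np.pi))
    for name, mass in layout.species:
        area = frac_map.get(name, 0.0)
        if area <= 0:
            continue
        intensity += area * norm * np.exp(-0.5 * ((mz - mass) / layout.sigma) ** 2)
        if layout.adduct_intensity > 0:
            adduct_area = area * layout.adduct_intensity
            centre = mass + layout.adduct_delta
            intensity += adduct_area * norm * np.exp(
                -0.5 * ((mz - centre) / layout.sigma) ** 2
            )
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=mz.size)
    intensity = np.clip(intensity, 0.0, None)
    return Spectrum(mz, intensity, **metadata)


def _anchor_level(spec: Spectrum, pos: float, half_band: float) -> float:
    """Median intensity in a band of +/- half_band around ``pos`` (0 if empty)."""
    mask = (spec.mz >= pos - half_band) & (spec.mz <= pos + half_band)
    if not mask.any():
        return 0.0
    return float(np.median(spec.intensity[mask]))


def _window_area(spec: Spectrum, lo: float, hi: float, sigma: float) -> float:
    """Baseline-corrected trapezoidal area over [lo, hi].

    The linear baseline is anchored one sigma outside each window edge
    (median over a +/- sigma/2 band) so the Gaussian tail inside the window
    is not clipped away for an isolated peak.
    """
    mask = (spec.mz >= lo) & (spec.mz <= hi)
    if mask.sum() < 3:
        return 0.0
    x = spec.mz[mask]
    y = spec.intensity[mask]
    a_pos, b_pos = lo - sigma, hi + sigma
    a = _anchor_level(spec, a_pos, sigma / 2)
    b = _anchor_level(spec, b_pos, sigma / 2)
    baseline = a + (b - a) * (x - a_pos) / (b_pos - a_pos)
    return float(np.trapezoid(np.clip(y - baseline, 0.0, None), x))


def integrate_species(spec: Spectrum, layout: SpeciesLayout) -> AreaReport:
    """Per-species peak areas by windowed trapezoidal integration.

    Each window is +/- min(3 sigma, half the gap to the nearest declared
    neighbour peak, adducts included) around the expected mass, so adduct
    satellites are never counted into a species area.
    """
    centres: list[tuple[str, float]] = list(layout.species)
    adducts = [
        (f"{name}+adduct", mass + layout.adduct_delta)
        for name, mass in layout.species
        if layout.adduct_intensity > 0
    ]
    all_centres = sorted(centres + adducts, key=lambda p: p[1])
    positions = np.array([m for _, m in all_centres])
    if positions.min() < spec.mz[0] or positions.max() > spec.mz[-1]:
        raise SpectrumRangeError("layout masses fall outside the spectrum range")

    half_widths: dict[str, float] = {}
    for i, (name, mass) in enumerate(all_centres):
        gaps = [abs(mass - positions[j]) for j in range(len(positions)) if j != i]
        half_gap = min(gaps) / 2.0 if gaps else np.inf
        hw = min(3.0 * layout.sigma, half_gap)
        if hw < 3.0 * layout.sigma:
            warnings.warn(
                f"window for {name!r} shrunk to +/-{hw:.1f} Da to avoid overlap",
                stacklevel=2,
            )
        half_widths[name] = hw

    areas, windows, adduct_areas = {}, {}, {}
    for name, mass in centres:
        hw = half_widths[name]
        windows[name] = (mass - hw, mass + hw)
        areas[name] = _window_area(spec, mass - hw, mass + hw, layout.sigma)
    for name, mass in adducts:
        hw = half_widths[name]
        adduct_areas[name] = _window_area(spec, mass - hw, mass + hw, layout.sigma)
    if sum(areas.values()) <= 0:
        raise EmptySpectrumError("no signal in any species window")
    return AreaReport(areas, windows, adduct_areas)


def fractions_from_areas(report: AreaReport) -> dict[str, float]:
    """Species fractions as area ratios (equal ionization/response assumed)."""
    return report.fractions


def write_spectrum(spec: Spectrum, path) -> None:
    """Two-column text spectrum with '#' metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        if spec.pH is not None:
            fh.write(f"# pH: {spec.pH}\n")
        if spec.replicate is not None:
            fh.write(f"# replicate: {spec.replicate}\n")
        if spec.stage is not None:
            fh.write(f"# stage: {spec.stage}\n")
        if spec.label:
            fh.write(f"# label: {spec.label}\n")
        for m, i in zip(spec.mz, spec.intensity):
            fh.write(f"{m:.4f}\t{i:.6g}\n")


def read_spectrum(path) -> Spectrum:
    """Read a two-column (m/z, intensity) text spectrum; '#' lines are metadata."""
    meta: dict[str, str] = {}
    mz, inten = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, val = line[1:].split(":", 1)
                    meta[key.strip().lower()] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            mz.append(float(parts[0]))
            inten.append(float(parts[1]))
    return Spectrum(
        np.array(mz),
        np.array(inten),
        pH=float(meta["ph"]) if "ph" in meta else None,
        replicate=int(meta["replicate"]) if "replicate" in meta else None,
        stage=meta.get("stage"),
        label=meta.get("label", ""),
    )
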