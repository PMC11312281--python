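"""Synthetic SORS spectra with the statistical structure of a spiking study.

The generator is deliberately not a physical Raman simulator.  It reproduces
the features the downstream analysis relies on:

* each sugar (fructose, glucose, sucrose, maltose) contributes a fixed set of
  Gaussian bands at literature positions — maltose around 865/935 cm^-1,
  sucrose around 711-839 cm^-1, glucose around 1047-1126 cm^-1 — so that
  syrup spiking moves spectral mass into interpretable band regions;
* a honey or syrup spectrum is the mass-fraction-weighted sum of its sugar
  component spectra, and spiking at level a % w/w is the exact convex
  combination (1 - a/100)*honey + (a/100)*syrup of the sugar profiles;
* every measurement carries a multiplicative detector gain, a broad smooth
  fluorescence background (very wide Gaussian) and additive white noise;
* honey-type individuality enters as one per-type multiplicative jitter of
  the base sugar profile, drawn once per type.

Two factory designs mirror the study layouts: ``year2_design`` (14 honey
types, rice r01 and sugar-beet b05 syrups at 10/20/30/50 % w/w, 3 technical
replicates, 1024-point axis over 112-1934 cm^-1) and ``year1_design``
(heather honeys spiked with sugar-cane syrup at 20/40/60 % w/w).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra_io import SpectraSet

SUGARS = ("fructose", "glucose", "sucrose", "maltose")


class DesignError(ValueError):
    """Invalid study-design or peak configuration."""


@dataclass(frozen=True)
class SugarProfile:
    """Mass fractions of the four dominant sugars, g per 100 g."""

    fructose_g_per_100g: float = 0.0
    glucose_g_per_100g: float = 0.0
    sucrose_g_per_100g: float = 0.0
    maltose_g_per_100g: float = 0.0

    def __post_init__(self) -> None:
        for sugar, value in self.as_dict().items():
            if not np.isfinite(value) or value < 0:
                raise DesignError(f"{sugar} mass fraction must be finite and >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "fructose": self.fructose_g_per_100g,
            "glucose": self.glucose_g_per_100g,
            "sucrose": self.sucrose_g_per_100g,
            "maltose": self.maltose_g_per_100g,
        }

    def scaled(self, factors: Mapping[str, float]) -> "SugarProfile":
        d = {s: v * factors.get(s, 1.0) for s, v in self.as_dict().items()}
        return SugarProfile(d["fructose"], d["glucose"], d["sucrose"], d["maltose"])


# Band positions (centre cm^-1, width cm^-1, relative amplitude) for each
# sugar.  Centres sit at the regions reported as discriminative for syrup
# adulteration; widths/amplitudes are free parameters of the generator.
DEFAULT_PEAKS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "maltose": ((865.0, 12.0, 0.85), (935.0, 10.0, 1.0)),
    "sucrose": ((711.0, 9.0, 0.7), (718.0, 9.0, 0.6), (808.0, 12.0, 1.0), (839.0, 10.0, 0.8)),
    "glucose": ((706.0, 10.0, 0.5), (1047.0, 12.0, 0.9), (1060.0, 12.0, 0.7), (1126.0, 12.0, 1.0)),
    "fructose": ((823.0, 12.0, 0.8), (872.0, 12.0, 0.6), (1060.0, 14.0, 1.0)),
}

# Average UK multifloral honey, g/100 g (fructose/glucose dominant).
DEFAULT_HONEY_BASE = SugarProfile(38.0, 31.0, 1.0, 2.0)

# Syrup compositions measured by HPLC-ELSD for the spiking syrups.
RICE_R01 = SugarProfile(glucose_g_per_100g=22.49, maltose_g_per_100g=31.90)
BEET_B05 = SugarProfile(fructose_g_per_100g=24.74, glucose_g_per_100g=24.37, sucrose_g_per_100g=31.52)
# Partially inverted sugar-cane (golden) syrup.
CANE_SYRUP = SugarProfile(fructose_g_per_100g=21.83, glucose_g_per_100g=22.95, sucrose_g_per_100g=12.74)


@dataclass
class StudyDesign:
    """Full specification of a synthetic spiking study."""

    honey_types: Sequence[str]
    adulterants: Sequence[tuple[str, SugarProfile]]
    levels_pct: Sequence[float]
    replicates: int = 3
    axis: tuple[float, float, int] = (112.0, 1934.0, 1024)
    fluorescence: tuple[float, float, float] = (0.5, 3.0, 600.0)  # amp lo/hi (x signal max), sigma
    noise: tuple[float, float] = (0.005, 0.1)  # additive sd (intensity units), lognormal gain sd
    honey_base: SugarProfile = DEFAULT_HONEY_BASE
    honey_jitter: float = 0.10  # +/- multiplicative jitter per type and sugar
    peaks: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_PEAKS))
    spatial_offset_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, n_points = self.axis
        if n_points < 64:
            raise DesignError(f"axis needs >= 64 points, got {n_points}")
        if not start < stop:
            raise DesignError("axis start must be < stop")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        levels = np.asarray(self.levels_pct, dtype=float)
        if levels.size and (np.any(levels <= 0) or np.any(levels > 100)):
            raise DesignError("adulteration levels must lie in (0, 100]")
        if len(set(self.honey_types)) != len(self.honey_types):
            raise DesignError("duplicate honey type names")

    def axis_values(self) -> np.ndarray:
        start, stop, n_points = self.axis
        return np.linspace(start, stop, n_points)


def year2_design(n_types: int = 14, seed: int = 0, **overrides) -> StudyDesign:
    """Rice + sugar-beet spiking at 10/20/30/50 % w/w, 3 replicates."""
    design = StudyDesign(
        honey_types=[f"H{i + 1:02d}" for i in range(n_types)],
        adulterants=[("rice", RICE_R01), ("sugar_beet", BEET_B05)],
        levels_pct=[10.0, 20.0, 30.0, 50.0],
        seed=seed,
    )
    return replace(design, **overrides) if overrides else design


def year1_design(n_types: int = 27, seed: int = 0, **overrides) -> StudyDesign:
    """Heather honeys spiked with sugar-cane syrup at 20/40/60 % w/w."""
    design = StudyDesign(
        honey_types=[f"S{i + 1:02d}" for i in range(n_types)],
        adulterants=[("sugar_cane", CANE_SYRUP)],
        levels_pct=[20.0, 40.0, 60.0],
        spatial_offset_mm=2.5,
        seed=seed,
    )
    return replace(design, **overrides) if overrides else design


def component_spectrum(sugar: str, axis: np.ndarray, peaks: Mapping[str, tuple] | None = None) -> np.ndarray:
    """Unit-normalised sum-of-Gaussians band spectrum for one sugar.

    Normalisation is to the global maximum of the band model (evaluated on a
    dense grid spanning the peaks plus the exact centres), not the on-axis
    maximum, so an axis that misses every band correctly yields near-zero
    intensity rather than a rescaled artefact.
    """
    table = DEFAULT_PEAKS if peaks is None else peaks
    if sugar not in table or not len(table[sugar]):
        raise DesignError(f"no peak model defined for sugar {sugar!r}")
    comps = np.asarray(table[sugar], dtype=float)
    if np.any(comps[:, 1] <= 0) or np.any(comps[:, 2] <= 0):
        raise DesignError(f"peak widths and amplitudes must be > 0 for {sugar!r}")
    axis = np.asarray(axis, dtype=float)

    def evaluate(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        for centre, width, amp in comps:
            out += amp * np.exp(-0.5 * ((x - centre) / width) ** 2)
        return out

    lo = comps[:, 0].min() - 5 * comps[:, 1].max()
    hi = comps[:, 0].max() + 5 * comps[:, 1].max()
    ref = np.concatenate([np.linspace(lo, hi, 4096), comps[:, 0]])
    peak_max = evaluate(ref).max()
    return evaluate(axis) / peak_max


def clean_signal(profile: SugarProfile, axis: np.ndarray, peaks: Mapping[str, tuple] | None = None) -> np.ndarray:
    """Noise-free spectrum: mass-fraction-weighted sum of sugar components."""
    out = np.zeros_like(np.asarray(axis, dtype=float))
    for sugar, grams in profile.as_dict().items():
        if grams > 0:
            out += (grams / 100.0) * component_spectrum(sugar, axis, peaks)
    return out


def mixture_profile(base: SugarProfile, adulterant: SugarProfile, level_pct: float) -> SugarProfile:
    """Sugar profile of honey spiked with syrup at ``level_pct`` % w/w."""
    if not 0 <= level_pct <= 100:
        raise DesignError(f"level_pct must be in [0, 100], got {level_pct}")
    f = level_pct / 100.0
    b, a = base.as_dict(), adulterant.as_dict()
    mixed = {s: (1 - f) * b[s] + f * a[s] for s in SUGARS}
    return SugarProfile(mixed["fructose"], mixed["glucose"], mixed["sucrose"], mixed["maltose"])


def render_measurement(profile: SugarProfile, design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """One noisy measurement: clean signal x gain + fluorescence + noise.

    Draw order (gain, background amplitude, background centre, additive
    noise) is fixed so a given generator state always yields the same vector.
    """
    axis = design.axis_values()
    signal = clean_signal(profile, axis, design.peaks)
    additive_sd, gain_sd = design.noise
    amp_lo, amp_hi, sigma = design.fluorescence

    gain = rng.lognormal(mean=0.0, sigma=gain_sd) if gain_sd > 0 else 1.0
    scale = signal.max() if signal.max() > 0 else 1.0
    amplitude = rng.uniform(amp_lo, amp_hi) * scale if amp_hi > 0 else 0.0
    centre = rng.uniform(axis[0], axis[-1])
    background = amplitude * np.exp(-0.5 * ((axis - centre) / sigma) ** 2)
    noise = rng.normal(0.0, additive_sd, size=axis.size) if additive_sd > 0 else 0.0
    return signal * gain + background + noise


def honey_base_profiles(design: StudyDesign) -> dict[str, SugarProfile]:
    """Per-type base sugar profiles: shared default with seeded jitter."""
    ss = np.random.SeedSequence(design.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    profiles: dict[str, SugarProfile] = {}
    for honey_type in design.honey_types:
        factors = {s: rng.uniform(1 - design.honey_jitter, 1 + design.honey_jitter) for s in SUGARS}
        profiles[honey_type] = design.honey_base.scaled(factors)
    return profiles


def generate_study(design: StudyDesign) -> SpectraSet:
    """Simulate the full study: every honey type, pure and spiked, replicated.

    One sample per honey_type x ({pure} | adulterant x level), each measured
    ``design.replicates`` times.  Bit-reproducible for a fixed seed.
    """
    axis = design.axis_values()
    profiles = honey_base_profiles(design)
    ss = np.random.SeedSequence(design.seed)
    measure_rng = np.random.default_rng(ss.spawn(2)[1])

    rows, meta_rows = [], []
    for honey_type in design.honey_types:
        base = profiles[honey_type]
        conditions: list[tuple[str, float, SugarProfile]] = [("none", 0.0, base)]
        for kind, syrup in design.adulterants:
            for level in design.levels_pct:
                conditions.append((kind, float(level), mixture_profile(base, syrup, level)))
        for kind, level, profile in conditions:
            suffix = "pure" if kind == "none" else f"{kind}-{level:g}"
            sample_id = f"{honey_type}-{suffix}"
            for rep in range(1, design.replicates + 1):
                rows.append(render_measurement(profile, design, measure_rng))
                meta_rows.append(
                    {
                        "measurement_id": f"{sample_id}-r{rep}",
                        "sample_id": sample_id,
                        "honey_type": honey_type,
                        "role": "honey",
                        "adulterant": kind,
                        "level_pct": level,
                        "replicate": rep,
                        "spatial_offset_mm": design.spatial_offset_mm,
                    }
                )
    return SpectraSet(axis, np.array(rows), pd.DataFrame(meta_rows))
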