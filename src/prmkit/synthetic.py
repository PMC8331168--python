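"""Synthetic targeted-MS experiment generator.

Emulates a genotype x condition x replicate design with injected protein
abundance fold-changes and phosphosite occupancies, scheduled-acquisition
extracted-ion chromatograms with exponentially-modified-Gaussian peaks, a
constant-plus-drift baseline, and per-point multiplicative log-normal noise.
Every stream of randomness derives from a single root seed by stable named
sub-seeding, so identical (config, seed) pairs give byte-identical output.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .errors import ConfigurationError
from .peaks import Chromatogram
from .rng import named_rng
from .targets import PeptideTarget, SpectralLibrary, TransitionTarget

Sample = namedtuple("Sample", "sample_id genotype condition replicate")

#: Fraction of a peptide's signal carried by each precursor charge state.
DEFAULT_CHARGE_FRACTIONS = {2: 0.65, 3: 0.35}


@dataclass(frozen=True)
class StudyDesign:
    genotypes: tuple[str, ...]
    conditions: tuple[str, ...]
    replicates: int
    seed: int

    def __post_init__(self):
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ConfigurationError("genotype labels must be unique")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        if not self.genotypes or not self.conditions:
            raise ConfigurationError("need at least one genotype and one condition")

    def cells(self) -> list[tuple[str, str]]:
        return [(g, c) for g in self.genotypes for c in self.conditions]

    def samples(self) -> list[Sample]:
        return [
            Sample(f"{g}.{c}.r{r}", g, c, r)
            for g, c in self.cells()
            for r in range(1, self.replicates + 1)
        ]


@dataclass(frozen=True)
class PeakShape:
    """Retention-time center (min), Gaussian sigma (min), exponential tail tau (min)."""

    rt: float
    sigma: float
    tau: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("peak sigma must be > 0")
        if self.tau < 0:
            raise ConfigurationError("peak tau must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative CV (fraction), additive baseline (a.u.), drift (a.u./min)."""

    cv: float = 0.0
    baseline: float = 0.0
    drift: float = 0.0

    def __post_init__(self):
        if self.cv < 0 or self.baseline < 0:
            raise ConfigurationError("noise cv and baseline must be >= 0")


@dataclass(frozen=True)
class GradientGrid:
    """Fixed-step acquisition time grid over the LC gradient (minutes)."""

    start: float = 0.0
    end: float = 60.0
    step: float = 0.01

    def slice(self, lo: float, hi: float) -> np.ndarray:
        lo = max(lo, self.start)
        hi = min(hi, self.end)
        if lo >= hi:
            raise ConfigurationError("RT schedule window outside the gradient")
        i0 = int(np.ceil(round((lo - self.start) / self.step, 9)))
        i1 = int(np.floor(round((hi - self.start) / self.step, 9)))
        return self.start + self.step * np.arange(i0, i1 + 1)


@dataclass
class GroundTruth:
    """Injected truth: abundances, occupancies, peak shapes, noise parameters."""

    abundance: dict[tuple[str, str, str], float]
    occupancy: dict[tuple[str, str, str], float]
    sites: dict[str, tuple[str, int]]
    noise: NoiseModel
    peak_sigma: float = 0.05
    peak_tau: float = 0.02
    seed: int = 0
    peak_shapes: dict[str, PeakShape] = field(default_factory=dict)

    def __post_init__(self):
        for key, a in self.abundance.items():
            if a <= 0:
                raise ConfigurationError(f"abundance must be > 0 ({key})")
        for key, p in self.occupancy.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"occupancy must be in [0, 1] ({key}: {p})")

    def peak_shape_for(self, peptide_key: str, rt_center: float) -> PeakShape:
        """Deterministic per-peptide shape: +-10% sigma jitter around the default."""
        if peptide_key not in self.peak_shapes:
            rng = named_rng(self.seed, "peak_shape", peptide_key)
            sigma = self.peak_sigma * rng.uniform(0.9, 1.1)
            self.peak_shapes[peptide_key] = PeakShape(rt=rt_center, sigma=sigma, tau=self.peak_tau)
        return self.peak_shapes[peptide_key]


def _cell_value(table: dict, label: str, genotype: str, condition: str, kind: str) -> float:
    key = f"{genotype}:{condition}"
    try:
        return float(table[key])
    except KeyError:
        raise ConfigurationError(f"missing {kind} for {label} in cell {key}") from None


def make_design(config: dict, seed: int) -> tuple[StudyDesign, GroundTruth]:
    """Build the study design and ground truth from a flat configuration dict.

    The configuration declares genotypes, conditions, replicates, per-protein
    baseline abundances with per-cell fold-changes (cells keyed "genotype:
    condition"), phosphosites with per-cell occupancies, and noise/peak/gradient
    parameters.  A declared cell with no fold-change or occupancy is a
    configuration error.
    """
    design = StudyDesign(
        genotypes=tuple(config["genotypes"]),
        conditions=tuple(config["conditions"]),
        replicates=int(config.get("replicates", 3)),
        seed=int(seed),
    )
    if not config.get("baseline_abundance"):
        raise ConfigurationError("config must declare at least one protein")

    abundance = {}
    for protein, base in config["baseline_abundance"].items():
        folds = config.get("fold_change", {}).get(protein, {})
        for g, c in design.cells():
            abundance[(protein, g, c)] = float(base) * _cell_value(
                folds, protein, g, c, "fold-change"
            )

    occupancy = {}
    sites = {}
    for site, info in (config.get("phosphosites") or {}).items():
        sites[site] = (info["protein"], int(info["position"]))
        occ = config.get("occupancy", {}).get(site, {})
        for g, c in design.cells():
            occupancy[(site, g, c)] = _cell_value(occ, site, g, c, "occupancy")

    noise_cfg = config.get("noise", {})
    peak_cfg = config.get("peak", {})
    truth = GroundTruth(
        abundance=abundance,
        occupancy=occupancy,
        sites=sites,
        noise=NoiseModel(
            cv=float(noise_cfg.get("cv", 0.0)),
            baseline=float(noise_cfg.get("baseline", 0.0)),
            drift=float(noise_cfg.get("drift", 0.0)),
        ),
        peak_sigma=float(peak_cfg.get("sigma", 0.05)),
        peak_tau=float(peak_cfg.get("tau", 0.02)),
        seed=int(seed),
    )
    return design, truth


def emg_profile(times: np.ndarray, area: float, rt: float, sigma: float, tau: float) -> np.ndarray:
    """Exponentially-modified Gaussian with the given integrated area.

    tau = 0 reduces exactly to a Gaussian of area ``area``; a Gaussian of
    amplitude A and width sigma corresponds to area = A * sigma * sqrt(2*pi).
    """
    if tau < 1e-9:
        return area * _st.norm.pdf(times, loc=rt, scale=sigma)
    return area * _st.exponnorm.pdf(times, tau / sigma, loc=rt, scale=sigma)


def gaussian_area(amplitude: float, sigma: float) -> float:
    """Closed-form area of a Gaussian peak: amplitude * sigma * sqrt(2*pi)."""
    return amplitude * sigma * np.sqrt(2.0 * np.pi)


def simulate_library(
    peptides: list[PeptideTarget],
    seed: int,
    n_fragments: int = 6,
    concentration: float = 2.0,
    irt_range: tuple[float, float] = (5.0, 95.0),
) -> SpectralLibrary:
    """Draw a frozen spectral library for the given peptides.

    Fragment response patterns (y3 upward) are drawn once per stripped peptide
    sequence from a Dirichlet with the given concentration, scaled by a
    log-normal per-peptide response factor; phospho and nonphospho forms of a
    peptide therefore share one pattern and the stoichiometry calculation's
    equal-response assumption holds by construction.  Phosphopeptides elute
    2 iRT units earlier than their nonphosphorylated counterparts.
    """
    lib = SpectralLibrary()
    for pep in peptides:
        seq = pep.sequence
        if seq not in lib.patterns:
            rng = named_rng(seed, "library", seq)
            n = min(n_fragments, len(seq) - 3)
            rel = rng.dirichlet(np.full(n, concentration))
            response = rng.lognormal(mean=0.0, sigma=0.3)
            lib.patterns[seq] = {
                ("y", 3 + i): float(rel[i] * response) for i in range(n)
            }
            lib.irt[seq] = float(named_rng(seed, "irt", seq).uniform(*irt_range))
        base_irt = lib.irt[seq]
        key = pep.modified_sequence
        lib.irt[key] = base_irt - 2.0 if pep.is_phospho else base_irt
    return lib


def simulate_xics(
    design: StudyDesign,
    truth: GroundTruth,
    transitions: list[TransitionTarget],
    seed: int,
    grid: GradientGrid = GradientGrid(),
    charge_fractions: dict[int, float] | None = None,
) -> list[Chromatogram]:
    """Simulate one chromatogram per (sample, transition).

    Fragment peak areas are proportional to (true protein abundance) x
    (library fragment intensity) x (charge-state fraction) x (occupancy or
    1 - occupancy for the phospho/nonphospho forms of a phosphopeptide).
    """
    fractions = dict(DEFAULT_CHARGE_FRACTIONS if charge_fractions is None else charge_fractions)
    chromatograms = []
    noise = truth.noise
    ln_sigma = float(np.sqrt(np.log1p(noise.cv**2))) if noise.cv > 0 else 0.0
    for tr in transitions:
        times = grid.slice(tr.rt_start, tr.rt_end)
        shape = truth.peak_shape_for(
            tr.peptide.modified_sequence, 0.5 * (tr.rt_start + tr.rt_end)
        )
        frac = fractions.get(tr.precursor_charge)
        if frac is None:
            raise ConfigurationError(
                f"no charge fraction configured for {tr.precursor_charge}+"
            )
        for sample in design.samples():
            key = (tr.peptide.protein, sample.genotype, sample.condition)
            if key not in truth.abundance:
                raise ConfigurationError(
                    f"transition {tr.transition_id} references unknown peptide/protein "
                    f"{tr.peptide.protein}"
                )
            amount = truth.abundance[key]
            if tr.peptide.site is not None:
                occ_key = (tr.peptide.site, sample.genotype, sample.condition)
                if occ_key not in truth.occupancy:
                    raise ConfigurationError(f"no occupancy for {occ_key}")
                p = truth.occupancy[occ_key]
                amount *= p if tr.peptide.is_phospho else (1.0 - p)
            area = amount * tr.library_intensity * frac
            signal = emg_profile(times, area, shape.rt, shape.sigma, shape.tau)
            trace = signal + noise.baseline + noise.drift * times
            if ln_sigma > 0:
                rng = named_rng(seed, "xic", sample.sample_id, tr.transition_id)
                factors = np.exp(
                    rng.normal(-0.5 * ln_sigma**2, ln_sigma, size=times.size)
                )
                trace = trace * factors
            chromatograms.append(
                Chromatogram(
                    sample_id=sample.sample_id,
                    transition_id=tr.transition_id,
                    times=times,
                    intensities=np.clip(trace, 0.0, None),
                )
            )
    return chromatograms
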