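"""Targeting layer for scheduled PRM acquisition.

Builds everything upstream of the mass spectrometer: tryptic digestion with
coordinates, proteotypic peptide selection against a background proteome,
monoisotopic fragment m/z computation, and transition lists with retention-time
schedule windows derived from a linear iRT calibration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from pyteomics import mass as _ptmass

from .errors import ConfigurationError, InsufficientPeptidesError, LibraryError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue masses (Da), from the pyteomics reference table.
RESIDUE_MASS: dict[str, float] = {aa: _ptmass.std_aa_mass[aa] for aa in AMINO_ACIDS}

PROTON = 1.00727646688
WATER = 18.0105646863
#: Mass shift of a phosphate group (HPO3), Da.
PHOSPHO_DELTA = 79.96633

_TRYPSIN_SITE = re.compile(r"[KR](?!P)")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with annotated modification sites (1-based)."""

    accession: str
    sequence: str
    mod_sites: frozenset[tuple[int, str]] = frozenset()

    def __post_init__(self):
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"{self.accession}: non-standard residues {sorted(bad)}")
        for pos, label in self.mod_sites:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"{self.accession}: site {label}@{pos} outside sequence")


@dataclass(frozen=True)
class PeptideTarget:
    """A targeted peptide: a slice of its parent with optional modifications.

    ``modifications`` holds (1-based position within the peptide, mass delta in
    Da).  ``site`` names the phosphosite a phospho/nonphospho pair monitors; it
    is set on both members of the pair.
    """

    protein: str
    sequence: str
    start: int
    end: int
    modifications: tuple[tuple[int, float], ...] = ()
    precursor_charge: int | None = None
    irt: float | None = None
    site: str | None = None

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide span does not match sequence length")
        for pos, _ in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError("modification position outside peptide")

    @property
    def is_phospho(self) -> bool:
        return any(abs(delta - PHOSPHO_DELTA) < 1e-3 for _, delta in self.modifications)

    @property
    def modified_sequence(self) -> str:
        """Sequence in the ``S[+80.0]`` dialect (deltas to one decimal)."""
        mods = dict(self.modifications)
        out = []
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if i in mods:
                out.append(f"[{mods[i]:+.1f}]")
        return "".join(out)

    def neutral_mass(self) -> float:
        m = sum(RESIDUE_MASS[aa] for aa in self.sequence) + WATER
        return m + sum(delta for _, delta in self.modifications)


@dataclass(frozen=True)
class TransitionTarget:
    """One monitored (peptide, precursor charge, fragment, product charge)."""

    peptide: PeptideTarget
    series: str
    ordinal: int
    product_charge: int
    precursor_charge: int
    precursor_mz: float
    product_mz: float
    rt_start: float
    rt_end: float
    library_intensity: float = 1.0

    @property
    def fragment(self) -> str:
        label = f"{self.series}{self.ordinal}"
        return label if self.product_charge == 1 else f"{label}^{self.product_charge}"

    @property
    def transition_id(self) -> str:
        return (
            f"{self.peptide.protein}|{self.peptide.modified_sequence}"
            f"|z{self.precursor_charge}|{self.fragment}"
        )


def digest_trypsin(sequence: str, max_missed: int = 0) -> list[tuple[str, int, int]]:
    """Tryptic peptides as (sequence, start, end) with 1-based inclusive spans.

    Cleaves after K or R except when the next residue is P; returns every
    peptide with at most ``max_missed`` internal cleavage sites, ordered by
    start position then length.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    cuts = [0] + [m.end() for m in _TRYPSIN_SITE.finditer(sequence)]
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            s, e = cuts[i], cuts[j]
            peptides.append((sequence[s:e], s + 1, e))
    return peptides


def _occurrences(needle: str, haystack: str) -> int:
    return sum(
        1 for i in range(len(haystack) - len(needle) + 1) if haystack.startswith(needle, i)
    )


def select_proteotypic(
    protein: ProteinRecord,
    background: list[ProteinRecord],
    library: "SpectralLibrary | None" = None,
    n_min: int = 3,
    n_max: int = 4,
    min_length: int = 7,
    max_length: int = 25,
) -> list[PeptideTarget]:
    """Choose 3-4 proteotypic peptides for a protein.

    Eligible peptides are fully tryptic (no missed cleavage), 7-25 residues,
    occur exactly once in the whole background proteome, contain no methionine
    (oxidation is a variable modification) and overlap no annotated
    modification site.  Ranking is by descending summed library fragment
    intensity, ties broken alphabetically.
    """
    if not any(p.accession == protein.accession for p in background):
        raise ConfigurationError(f"background does not include {protein.accession}")
    site_positions = {pos for pos, _ in protein.mod_sites}
    eligible = []
    for seq, start, end in digest_trypsin(protein.sequence, max_missed=0):
        if not min_length <= len(seq) <= max_length:
            continue
        if "M" in seq:
            continue
        if any(start <= pos <= end for pos in site_positions):
            continue
        hits = sum(_occurrences(seq, rec.sequence) for rec in background)
        if hits != 1:
            continue
        eligible.append(PeptideTarget(protein.accession, seq, start, end))
    if len(eligible) < n_min:
        raise InsufficientPeptidesError(
            f"{protein.accession}: {len(eligible)} eligible proteotypic peptides "
            f"(need >= {n_min})"
        )

    def rank_key(p: PeptideTarget):
        score = 0.0
        if library is not None and p.sequence in library.patterns:
            score = sum(library.patterns[p.sequence].values())
        return (-score, p.sequence)

    return sorted(eligible, key=rank_key)[:n_max]


def fragment_mz(peptide: PeptideTarget, series: str, ordinal: int, charge: int) -> float:
    """Monoisotopic m/z of a b- or y-series fragment.

    y fragments carry the C-terminal water; b fragments have no offset.
    Modifications located on residues within the fragment shift its mass.
    """
    if series not in ("b", "y"):
        raise ValueError(f"unknown ion series {series!r}")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    n = len(peptide.sequence)
    if not 1 <= ordinal <= n - 1:
        raise ValueError(f"ordinal {ordinal} out of range for length-{n} peptide")
    if series == "b":
        residues = range(1, ordinal + 1)
        offset = 0.0
    else:
        residues = range(n - ordinal + 1, n + 1)
        offset = WATER
    m = sum(RESIDUE_MASS[peptide.sequence[i - 1]] for i in residues) + offset
    m += sum(delta for pos, delta in peptide.modifications if pos in residues)
    return (m + charge * PROTON) / charge


def precursor_mz(peptide: PeptideTarget, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide.neutral_mass() + charge * PROTON) / charge


@dataclass
class SpectralLibrary:
    """Frozen fragment response patterns and iRT values.

    ``patterns`` maps a *stripped* peptide sequence to fragment intensities
    keyed by (series, ordinal); phospho and nonphospho forms of one peptide
    share a pattern.  ``irt`` is keyed by modified sequence.
    """

    patterns: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)
    irt: dict[str, float] = field(default_factory=dict)

    def fragments_for(self, peptide: PeptideTarget) -> dict[tuple[str, int], float]:
        try:
            return self.patterns[peptide.sequence]
        except KeyError:
            raise LibraryError(f"peptide {peptide.sequence} absent from library") from None

    def irt_for(self, peptide: PeptideTarget) -> float:
        try:
            return self.irt[peptide.modified_sequence]
        except KeyError:
            raise LibraryError(
                f"no iRT for {peptide.modified_sequence} in library"
            ) from None


@dataclass(frozen=True)
class IrtCalibration:
    """Linear iRT -> retention time mapping (minutes)."""

    slope: float = 0.5
    intercept: float = 5.0

    def rt(self, irt: float) -> float:
        return self.slope * irt + self.intercept


def build_transition_list(
    library: SpectralLibrary,
    peptides: list[PeptideTarget],
    charges: tuple[int, ...] = (2, 3),
    k_fragments: int = 3,
    calibration: IrtCalibration = IrtCalibration(),
    window_min: float = 3.0,
) -> list[TransitionTarget]:
    """Expand peptides into transitions for the k most intense library fragments.

    Both the doubly and triply charged precursors are targeted by default for
    every peptide form.  RT schedule windows come from the linear iRT mapping.
    """
    transitions: list[TransitionTarget] = []
    for pep in peptides:
        pattern = library.fragments_for(pep)
        n = len(pep.sequence)
        usable = {k: v for k, v in pattern.items() if 1 <= k[1] <= n - 1}
        top = sorted(usable.items(), key=lambda kv: (-kv[1], kv[0]))[:k_fragments]
        center = calibration.rt(library.irt_for(pep))
        rt_start, rt_end = center - window_min / 2, center + window_min / 2
        for z in charges:
            pep_z = replace(pep, precursor_charge=z)
            pre = precursor_mz(pep_z, z)
            for (series, ordinal), intensity in top:
                transitions.append(
                    TransitionTarget(
                        peptide=pep_z,
                        series=series,
                        ordinal=ordinal,
                        product_charge=1,
                        precursor_charge=z,
                        precursor_mz=pre,
                        product_mz=fragment_mz(pep_z, series, ordinal, 1),
                        rt_start=rt_start,
                        rt_end=rt_end,
                        library_intensity=intensity,
                    )
                )
    return transitions
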