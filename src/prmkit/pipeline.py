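"""End-to-end workflow glue: simulate -> integrate -> quantify.

Also ships a small self-contained demo study: two synthetic proteins (one
carrying a regulatory phosphosite preceded by an R-x-x-S motif, one serving as
a loading control) measured across a genotype x condition x replicate design
with a stress-induced occupancy shift and a genotype abundance fold-change,
mirroring the structure of a phosphomimetic-mutant PRM experiment.
"""

from __future__ import annotations

import pandas as pd

from . import peaks, quant
from .synthetic import (
    GradientGrid, GroundTruth, StudyDesign, make_design, simulate_library,
    simulate_xics,
)
from .targets import (
    IrtCalibration, PeptideTarget, ProteinRecord, SpectralLibrary,
    TransitionTarget, PHOSPHO_DELTA, build_transition_list, digest_trypsin,
    select_proteotypic,
)

# Synthetic demonstration proteins (not biological sequences).  PROT1 carries
# an annotated phosphoserine at position 31, three residues after an arginine
# (an R-x-x-S basophilic kinase motif spanning the preceding tryptic boundary).
DEMO_SEQUENCES = {
    "PROT1": "MTTADLGVKLSEGVDAAYKVTDLNPAVRAGSFDELNKYVEDLTPGAKGH",
    "PROT2": "MAVGDELSTKLNDPFAVGYRTSGELVADKFVQGDLAPKGW",
}
DEMO_SITE = "PROT1_S31"
DEMO_SITE_POSITION = 31


def demo_proteins() -> list[ProteinRecord]:
    return [
        ProteinRecord(
            "PROT1", DEMO_SEQUENCES["PROT1"],
            mod_sites=frozenset({(DEMO_SITE_POSITION, "Phospho")}),
        ),
        ProteinRecord("PROT2", DEMO_SEQUENCES["PROT2"]),
    ]


def demo_config(
    fold: float = 2.5,
    occ_reference: float = 0.12,
    occ_shifted: float = 0.40,
    cv: float = 0.0,
    replicates: int = 3,
    genotypes: tuple[str, str] = ("WT", "S91D"),
    conditions: tuple[str, ...] = ("control", "UVB"),
) -> dict:
    """Study configuration: mutant carries ``fold``-times the WT abundance of
    PROT1; site occupancy shifts from ``occ_reference`` (control) to
    ``occ_shifted`` (stress).  With a single condition the occupancy shift is
    keyed by genotype instead so both values are still exercised."""
    cells = [f"{g}:{c}" for g in genotypes for c in conditions]
    fold_by_cell = {cell: (fold if cell.split(":")[0] == genotypes[1] else 1.0)
                    for cell in cells}
    if len(conditions) > 1:
        occ_by_cell = {cell: (occ_shifted if cell.endswith(":" + conditions[1])
                              else occ_reference) for cell in cells}
    else:
        occ_by_cell = {cell: (occ_shifted if cell.startswith(genotypes[1] + ":")
                              else occ_reference) for cell in cells}
    return {
        "genotypes": list(genotypes),
        "conditions": list(conditions),
        "replicates": replicates,
        "baseline_abundance": {"PROT1": 800.0, "PROT2": 1000.0},
        "fold_change": {
            "PROT1": fold_by_cell,
            "PROT2": {cell: 1.0 for cell in cells},
        },
        "phosphosites": {DEMO_SITE: {"protein": "PROT1", "position": DEMO_SITE_POSITION}},
        "occupancy": {DEMO_SITE: occ_by_cell},
        "noise": {"cv": cv, "baseline": 2.0, "drift": 0.02},
        "peak": {"sigma": 0.05, "tau": 0.02},
    }


def phosphopeptide_pair(
    protein: ProteinRecord, position: int, site: str
) -> tuple[PeptideTarget, PeptideTarget]:
    """The tryptic peptide covering ``position`` in phospho and nonphospho form."""
    for seq, start, end in digest_trypsin(protein.sequence, max_missed=0):
        if start <= position <= end:
            pos_in_pep = position - start + 1
            nonphospho = PeptideTarget(protein.accession, seq, start, end, site=site)
            phospho = PeptideTarget(
                protein.accession, seq, start, end,
                modifications=((pos_in_pep, PHOSPHO_DELTA),), site=site,
            )
            return phospho, nonphospho
    raise ValueError(f"no tryptic peptide covers position {position}")


def build_demo_assets(
    config: dict | None = None, seed: int = 0
) -> tuple[StudyDesign, GroundTruth, SpectralLibrary, list[TransitionTarget]]:
    """Design + truth + library + transition list for the demo study."""
    if config is None:
        config = demo_config()
    design, truth = make_design(config, seed)
    proteins = demo_proteins()
    peptides: list[PeptideTarget] = []
    for prot in proteins:
        library_probe = None  # selection before the library exists: alphabetical ties
        peptides.extend(
            select_proteotypic(prot, proteins, library=library_probe)
        )
    for site, (acc, pos) in truth.sites.items():
        prot = next(p for p in proteins if p.accession == acc)
        peptides.extend(phosphopeptide_pair(prot, pos, site))
    library = simulate_library(peptides, seed=seed)
    transitions = build_transition_list(library, peptides, calibration=IrtCalibration())
    return design, truth, library, transitions


def integrate_experiment(
    chromatograms, transitions, k_fragments: int = 3
) -> pd.DataFrame:
    """Detect/integrate every chromatogram into a fragment-area table.

    Keeps the ``k_fragments`` largest areas per (sample, peptide, charge); a
    "no peak" call contributes area 0 with its flag propagated.
    """
    meta = {tr.transition_id: tr for tr in transitions}
    rows = []
    for xic in chromatograms:
        tr = meta[xic.transition_id]
        expected_rt = 0.5 * (tr.rt_start + tr.rt_end)
        window = tr.rt_end - tr.rt_start
        result = peaks.detect_peak(xic, expected_rt=expected_rt, window=window)
        rows.append(
            {
                "sample_id": xic.sample_id,
                "protein": tr.peptide.protein,
                "peptide": tr.peptide.modified_sequence,
                "site": tr.peptide.site,
                "is_phospho": tr.peptide.is_phospho,
                "charge": tr.precursor_charge,
                "fragment": tr.fragment,
                "area": result.area,
                "flag": result.flag,
            }
        )
    table = pd.DataFrame(rows, columns=quant.AREA_COLUMNS)
    kept = []
    for _, sub in table.groupby(["sample_id", "peptide", "charge"], sort=False):
        areas = dict(zip(sub["fragment"], sub["area"]))
        top = set(peaks.top_k_fragments(areas, k=min(k_fragments, len(areas))))
        kept.append(sub[sub["fragment"].isin(top)])
    return pd.concat(kept, ignore_index=True)


def quantify_experiment(
    design: StudyDesign,
    area_table: pd.DataFrame,
    reference: tuple[str, str | None] = ("WT", "control"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein and phospho quantification tables relative to a reference cell.

    ``reference`` is (genotype, condition); a None condition references every
    sample of the genotype.
    """
    ref_g, ref_c = reference
    ref_samples = [
        s.sample_id
        for s in design.samples()
        if s.genotype == ref_g and (ref_c is None or s.condition == ref_c)
    ]
    protein_table = quant.protein_quant_table(area_table, ref_samples)
    phospho_table = quant.phospho_quant_table(area_table, ref_samples)
    return protein_table, phospho_table


def run_demo_pipeline(
    config: dict | None = None,
    seed: int = 0,
    grid: GradientGrid = GradientGrid(),
    reference: tuple[str, str | None] = ("WT", "control"),
):
    """Simulate the demo study and quantify it; returns all intermediate tables."""
    design, truth, library, transitions = build_demo_assets(config, seed=seed)
    chromatograms = simulate_xics(design, truth, transitions, seed=seed, grid=grid)
    area_table = integrate_experiment(chromatograms, transitions)
    protein_table, phospho_table = quantify_experiment(design, area_table, reference)
    return {
        "design": design,
        "truth": truth,
        "library": library,
        "transitions": transitions,
        "chromatograms": chromatograms,
        "areas": area_table,
        "proteins": protein_table,
        "phospho": phospho_table,
    }
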