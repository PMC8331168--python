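"""Relative protein abundance and phosphosite stoichiometry.

Relative protein abundance is the sum, over a protein's targeted proteotypic
peptides, of the integrated areas of their most intense fragment ions::

    A = f11 + f12 + f13 + f21 + f22 + f23 + (f31 + f32 + f33) [+ peptide 4]

and is expressed relative to the mean of the reference (WT) replicates.  The
phosphorylation level of a site is the percentage of the phosphopeptide signal
over the total (phospho + nonphospho) signal, summed over fragments and both
targeted precursor charge states::

    P = 100 * sum(pt) / (sum(t) + sum(pt))

The fragment-area table is a pandas DataFrame with columns
``sample_id, protein, peptide, site, is_phospho, charge, fragment, area, flag``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

AREA_COLUMNS = [
    "sample_id", "protein", "peptide", "site", "is_phospho",
    "charge", "fragment", "area", "flag",
]


def protein_abundance(table: pd.DataFrame, protein: str, sample_id: str) -> float:
    """A: double sum of retained fragment areas over the protein's targeted peptides.

    Phosphopeptide pairs (rows with a ``site``) are stoichiometry probes and do
    not contribute; peptides flagged "no peak" contribute their area of 0.
    """
    rows = table[(table["protein"] == protein) & (table["sample_id"] == sample_id)]
    if rows.empty:
        raise KeyError(f"protein {protein!r} absent from table for sample {sample_id!r}")
    rows = rows[rows["site"].isna()] if "site" in rows else rows
    return float(rows["area"].sum())


def normalize_to_reference(
    a_by_sample: Mapping[str, float], reference_samples: Iterable[str]
) -> dict[str, float]:
    """Express each sample's value relative to the mean over reference samples."""
    refs = [a_by_sample[s] for s in reference_samples]
    if not refs:
        raise ValueError("no reference samples given")
    ref_mean = float(np.mean(refs))
    if ref_mean <= 0:
        raise ValueError("reference mean must be > 0")
    return {s: v / ref_mean for s, v in a_by_sample.items()}


def phospho_stoichiometry(
    phospho_areas: Iterable[float], nonphospho_areas: Iterable[float]
) -> float | None:
    """P in percent, or None when both totals are zero (undefined stoichiometry)."""
    spt = float(np.sum(np.fromiter(phospho_areas, dtype=float)))
    st = float(np.sum(np.fromiter(nonphospho_areas, dtype=float)))
    if spt < 0 or st < 0:
        raise ValueError("areas must be non-negative")
    total = spt + st
    if total == 0:
        return None
    return 100.0 * spt / total


def relative_phosphorylation(p_sample: float, p_reference_mean: float) -> float:
    """Phosphorylation level relative to the WT control mean."""
    if p_reference_mean <= 0:
        raise ValueError("reference mean phosphorylation must be > 0")
    return p_sample / p_reference_mean


def protein_quant_table(
    table: pd.DataFrame, reference_samples: Iterable[str]
) -> pd.DataFrame:
    """Per (sample, protein) abundance A and its WT-relative ratio.

    Emits columns ``sample_id, protein, A, relative_abundance, flags``.
    """
    reference_samples = list(reference_samples)
    out = []
    for protein, prot_rows in table[table["site"].isna()].groupby("protein"):
        a_by_sample = {
            s: float(rows["area"].sum()) for s, rows in prot_rows.groupby("sample_id")
        }
        rel = normalize_to_reference(a_by_sample, reference_samples)
        for s in sorted(a_by_sample):
            flags = sorted(set(prot_rows.loc[prot_rows["sample_id"] == s, "flag"]) - {"ok"})
            out.append(
                {
                    "sample_id": s,
                    "protein": protein,
                    "A": a_by_sample[s],
                    "relative_abundance": rel[s],
                    "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(out)


def phospho_quant_table(
    table: pd.DataFrame, reference_samples: Iterable[str]
) -> pd.DataFrame:
    """Per (sample, site) stoichiometry P and its WT-control-relative ratio.

    Emits ``sample_id, site, P_percent, relative_phosphorylation, flags``; an
    undefined stoichiometry (no signal in either form) yields NaN with an
    ``undefined`` flag rather than a number.
    """
    reference_samples = list(reference_samples)
    out = []
    for site, site_rows in table[table["site"].notna()].groupby("site"):
        p_by_sample: dict[str, float | None] = {}
        flag_by_sample: dict[str, list[str]] = {}
        for s, rows in site_rows.groupby("sample_id"):
            p = phospho_stoichiometry(
                rows.loc[rows["is_phospho"], "area"],
                rows.loc[~rows["is_phospho"], "area"],
            )
            p_by_sample[s] = p
            flag_by_sample[s] = sorted(set(rows["flag"]) - {"ok"})
            if p is None:
                flag_by_sample[s].append("undefined")
        refs = [p_by_sample[s] for s in reference_samples if p_by_sample.get(s) is not None]
        ref_mean = float(np.mean(refs)) if refs else np.nan
        for s in sorted(p_by_sample):
            p = p_by_sample[s]
            out.append(
                {
                    "sample_id": s,
                    "site": site,
                    "P_percent": np.nan if p is None else p,
                    "relative_phosphorylation": (
                        np.nan if (p is None or not ref_mean > 0) else p / ref_mean
                    ),
                    "flags": ";".join(flag_by_sample[s]),
                }
            )
    return pd.DataFrame(out)
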