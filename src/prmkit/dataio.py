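"""On-disk formats for the synthetic experiment and analysis tables.

All files are plain text: the design and transition list as CSV, ground truth
as JSON, chromatograms as a four-column TSV
(``sample_id<TAB>transition_id<TAB>time_min<TAB>intensity``, UTF-8, '.'
decimal, LF line endings).  Floats are written at full repr precision so a
write/read round trip reproduces every numeric value.
"""

from __future__ import annotations

import json
from collections import namedtuple
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .peaks import Chromatogram
from .synthetic import GroundTruth, NoiseModel, PeakShape, StudyDesign

Dataset = namedtuple("Dataset", "design truth chromatograms transitions")

CHROM_HEADER = ["sample_id", "transition_id", "time_min", "intensity"]

TRANSITION_COLUMNS = [
    "protein", "peptide_modified_sequence", "precursor_charge", "fragment_ion",
    "product_charge", "precursor_mz", "product_mz", "rt_start_min", "rt_end_min",
]


def _truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "seed": truth.seed,
        "abundance": {"|".join(k): v for k, v in truth.abundance.items()},
        "occupancy": {"|".join(k): v for k, v in truth.occupancy.items()},
        "sites": {s: list(v) for s, v in truth.sites.items()},
        "noise": {"cv": truth.noise.cv, "baseline": truth.noise.baseline,
                  "drift": truth.noise.drift},
        "peak": {"sigma": truth.peak_sigma, "tau": truth.peak_tau},
        "peak_shapes": {
            k: [s.rt, s.sigma, s.tau] for k, s in truth.peak_shapes.items()
        },
    }


def _truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        abundance={tuple(k.split("|")): v for k, v in d["abundance"].items()},
        occupancy={tuple(k.split("|")): v for k, v in d["occupancy"].items()},
        sites={s: (v[0], int(v[1])) for s, v in d["sites"].items()},
        noise=NoiseModel(**d["noise"]),
        peak_sigma=d["peak"]["sigma"],
        peak_tau=d["peak"]["tau"],
        seed=d["seed"],
        peak_shapes={
            k: PeakShape(rt=v[0], sigma=v[1], tau=v[2])
            for k, v in d.get("peak_shapes", {}).items()
        },
    )


def transitions_to_frame(transitions) -> pd.DataFrame:
    rows = []
    for tr in transitions:
        rows.append(
            {
                "protein": tr.peptide.protein,
                "peptide_modified_sequence": tr.peptide.modified_sequence,
                "precursor_charge": tr.precursor_charge,
                "fragment_ion": tr.fragment,
                "product_charge": tr.product_charge,
                "precursor_mz": tr.precursor_mz,
                "product_mz": tr.product_mz,
                "rt_start_min": tr.rt_start,
                "rt_end_min": tr.rt_end,
                "library_intensity": tr.library_intensity,
                "site": tr.peptide.site or "",
                "is_phospho": tr.peptide.is_phospho,
                "transition_id": tr.transition_id,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(design: StudyDesign, truth: GroundTruth, chromatograms, out_dir,
                  transitions=None) -> Path:
    """Write design.csv, ground_truth.json, chromatograms.tsv (and transitions.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(design.samples()).to_csv(out / "design.csv", index=False)
    meta = {
        "genotypes": list(design.genotypes),
        "conditions": list(design.conditions),
        "replicates": design.replicates,
        "seed": design.seed,
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump({"design": meta, "truth": _truth_to_dict(truth)}, fh, indent=1)
    if transitions is not None:
        transitions_to_frame(transitions).to_csv(out / "transitions.csv", index=False)
    with open(out / "chromatograms.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CHROM_HEADER) + "\n")
        for xic in chromatograms:
            for t, y in zip(xic.times, xic.intensities):
                fh.write(
                    f"{xic.sample_id}\t{xic.transition_id}\t{float(t)!r}\t{float(y)!r}\n"
                )
    return out


def read_chromatograms(path) -> list[Chromatogram]:
    path = Path(path)
    groups: dict[tuple[str, str], tuple[list, list]] = {}
    order: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CHROM_HEADER:
            raise ParseError("bad chromatogram header", path=str(path), line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"expected 4 fields, got {len(parts)}", path=str(path), line=lineno
                )
            sample_id, transition_id, t_str, y_str = parts
            try:
                t, y = float(t_str), float(y_str)
            except ValueError:
                raise ParseError("non-numeric value", path=str(path), line=lineno) from None
            key = (sample_id, transition_id)
            if key not in groups:
                groups[key] = ([], [])
                order.append(key)
            groups[key][0].append(t)
            groups[key][1].append(y)
    return [
        Chromatogram(sample_id=s, transition_id=tr,
                     times=np.array(groups[(s, tr)][0]),
                     intensities=np.array(groups[(s, tr)][1]))
        for s, tr in order
    ]


def read_dataset(out_dir) -> Dataset:
    """Read a dataset written by :func:`write_dataset`.

    Transitions come back as a DataFrame (or None when the file is absent);
    design, truth and chromatograms come back as the original object types.
    """
    out = Path(out_dir)
    with open(out / "ground_truth.json", encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(
                exc.msg, path=str(out / "ground_truth.json"), line=exc.lineno
            ) from None
    meta = payload["design"]
    design = StudyDesign(
        genotypes=tuple(meta["genotypes"]),
        conditions=tuple(meta["conditions"]),
        replicates=meta["replicates"],
        seed=meta["seed"],
    )
    truth = _truth_from_dict(payload["truth"])
    chrom_path = out / "chromatograms.tsv"
    chromatograms = read_chromatograms(chrom_path) if chrom_path.exists() else []
    tr_path = out / "transitions.csv"
    transitions = pd.read_csv(tr_path) if tr_path.exists() else None
    return Dataset(design=design, truth=truth, chromatograms=chromatograms,
                   transitions=transitions)
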