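"""Accurate-mass annotation of picked peaks.

Peaks are matched against metabolite records under the five negative-mode
adducts (M-H, M-H2O, M+K-2H, M+Na-2H, M+Cl) within a ppm tolerance
(default 4 ppm), and against enumerated glycan-fragment compositions as
[M-H]- ions.  A peak may carry several candidate annotations; candidates
are ranked by absolute ppm error.  Exogenous records (drugs, pesticides,
matrix compounds) can be filtered out downstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (
    ADDUCT_RULES,
    GLYCAN_MODIFICATIONS,
    GLYCAN_RESIDUES,
    GlycanComposition,
    adduct_mz,
    glycan_fragment_mass,
)
from .db import MetaboliteDB
from .preprocess import PeakList

__all__ = [
    "AnnotationRecord",
    "ppm_error",
    "annotate_peaks",
    "filter_exogenous",
    "annotate_glycans",
    "annotations_to_frame",
    "write_annotations",
]


@dataclass(frozen=True)
class AnnotationRecord:
    peak_mz: float
    record_id: str
    name: str
    adduct: str
    theoretical_mz: float
    ppm: float
    pathways: frozenset[str]
    chem_class: str
    source: str            # "metabolite" | "glycan"
    endogenous: bool = True


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def _sort_key(a: AnnotationRecord):
    return (a.peak_mz, abs(a.ppm), a.record_id, a.adduct)


def annotate_peaks(
    peaks: PeakList,
    db: MetaboliteDB,
    tol_ppm: float = 4.0,
    adducts: list[str] | None = None,
) -> list[AnnotationRecord]:
    """Match peak centers to metabolite records via adduct-aware exact mass.

    Every (peak, record, adduct) pair within ``tol_ppm`` is emitted; the
    result is sorted by (peak m/z, |ppm|, record id) and therefore
    independent of database row order.
    """
    if len(db) == 0:
        return []
    rules = [ADDUCT_RULES[a] for a in (adducts or list(ADDUCT_RULES))]
    theo, meta = [], []
    for rec in db:
        for rule in rules:
            try:
                mz = adduct_mz(rec.monoisotopic_mass, rule)
            except ValueError:
                continue  # degenerate adduct for this record (e.g. water - H2O)
            theo.append(mz)
            meta.append((rec, rule.label))
    theo = np.asarray(theo)
    order = np.argsort(theo)
    theo_sorted = theo[order]

    out: list[AnnotationRecord] = []
    tol = tol_ppm * 1e-6
    for center in peaks.centers:
        lo = np.searchsorted(theo_sorted, center / (1 + tol), side="left")
        hi = np.searchsorted(theo_sorted, center / (1 - tol), side="right")
        for idx in order[lo:hi]:
            err = ppm_error(center, theo[idx])
            if abs(err) <= tol_ppm:
                rec, adduct = meta[idx]
                out.append(
                    AnnotationRecord(
                        peak_mz=float(center),
                        record_id=rec.id,
                        name=rec.name,
                        adduct=adduct,
                        theoretical_mz=float(theo[idx]),
                        ppm=err,
                        pathways=rec.pathways,
                        chem_class=rec.chem_class,
                        source="metabolite",
                        endogenous=rec.endogenous,
                    )
                )
    return sorted(out, key=_sort_key)


def filter_exogenous(annotations: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Drop annotations whose record is flagged exogenous (drugs, pesticides,
    matrix compounds); glycan annotations are always retained."""
    return [a for a in annotations if a.endogenous]


def _enumerate_compositions(
    max_residues: dict[str, int],
    max_modifications: dict[str, int],
    max_total_residues: int,
    reducing_end_water: bool,
    max_compositions: int,
) -> list[GlycanComposition]:
    res_names = [r for r in GLYCAN_RESIDUES if max_residues.get(r, 0) > 0]
    mod_names = [m for m in GLYCAN_MODIFICATIONS if max_modifications.get(m, 0) > 0]
    res_ranges = [range(max_residues[r] + 1) for r in res_names]
    mod_ranges = [range(max_modifications[m] + 1) for m in mod_names]
    comps: list[GlycanComposition] = []
    for res_counts in itertools.product(*res_ranges) if res_names else [()]:
        total = sum(res_counts)
        if total == 0 or total > max_total_residues:
            continue
        residues = {r: c for r, c in zip(res_names, res_counts) if c}
        for mod_counts in itertools.product(*mod_ranges) if mod_names else [()]:
            mods = {m: c for m, c in zip(mod_names, mod_counts) if c}
            comps.append(
                GlycanComposition.from_counts(residues, mods, reducing_end_water)
            )
            if len(comps) > max_compositions:
                warnings.warn(
                    f"glycan enumeration capped at {max_compositions} compositions"
                )
                return comps
    return comps


def annotate_glycans(
    peaks: PeakList,
    max_residues: dict[str, int] | int = 2,
    max_modifications: dict[str, int] | int = 2,
    tol_ppm: float = 4.0,
    max_total_residues: int = 4,
    reducing_end_water: bool = True,
    max_compositions: int = 1_000_000,
) -> list[AnnotationRecord]:
    """Annotate peaks as glycan-fragment compositions via [M-H]- exact mass.

    Compositions over the residues Hex, HexNAc, HexA, HexN, dHex, NeuAc,
    NeuGc, Pen with sulfate/phosphate/acetyl modifications are enumerated
    within the given per-residue bounds; labels use residue-count
    nomenclature (e.g. ``HexNAc1S1``).  Glycans ionize as [M-H]- only
    (negative mode, 9-AA matrix).
    """
    if isinstance(max_residues, int):
        max_residues = {r: max_residues for r in GLYCAN_RESIDUES}
    if isinstance(max_modifications, int):
        max_modifications = {m: max_modifications for m in GLYCAN_MODIFICATIONS}
    comps = _enumerate_compositions(
        max_residues, max_modifications, max_total_residues,
        reducing_end_water, max_compositions,
    )
    if not comps:
        return []
    theo = np.array([adduct_mz(glycan_fragment_mass(c), "M-H") for c in comps])
    order = np.argsort(theo)
    theo_sorted = theo[order]
    out: list[AnnotationRecord] = []
    tol = tol_ppm * 1e-6
    for center in peaks.centers:
        lo = np.searchsorted(theo_sorted, center / (1 + tol), side="left")
        hi = np.searchsorted(theo_sorted, center / (1 - tol), side="right")
        for idx in order[lo:hi]:
            err = ppm_error(center, theo[idx])
            if abs(err) <= tol_ppm:
                comp = comps[idx]
                out.append(
                    AnnotationRecord(
                        peak_mz=float(center),
                        record_id=comp.label,
                        name=comp.label,
                        adduct="M-H",
                        theoretical_mz=float(theo[idx]),
                        ppm=err,
                        pathways=frozenset({"glycan_fragments"}),
                        chem_class="Glycan fragment",
                        source="glycan",
                    )
                )
    return sorted(out, key=_sort_key)


def annotations_to_frame(annotations: list[AnnotationRecord]) -> pd.DataFrame:
    rows = [
        {
            "peak_mz": a.peak_mz,
            "id": a.record_id,
            "name": a.name,
            "adduct": a.adduct,
            "theo_mz": a.theoretical_mz,
            "ppm": a.ppm,
            "pathways": ";".join(sorted(a.pathways)),
            "class": a.chem_class,
            "source": a.source,
            "endogenous": int(a.endogenous),
        }
        for a in annotations
    ]
    columns = ["peak_mz", "id", "name", "adduct", "theo_mz", "ppm",
               "pathways", "class", "source", "endogenous"]
    return pd.DataFrame(rows, columns=columns)


def write_annotations(
    annotations: list[AnnotationRecord],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    df = annotations_to_frame(annotations)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
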