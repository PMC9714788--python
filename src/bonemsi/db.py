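"""Bundled metabolite and glycan reference tables.

The metabolite table is a desk-scale stand-in for KEGG/HMDB records: each row
carries an identifier, a name, an elemental formula, the monoisotopic mass,
pathway memberships, a chemical-class label, and an endogenous flag
(exogenous records — drugs, pesticides, the MALDI matrix — are retained so
that the exogenous filter has something to remove).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chem import neutral_mass

__all__ = ["MetaboliteRecord", "MetaboliteDB", "load_default_db", "load_glycan_residues"]

MASS_RECOMPUTE_TOL = 1e-6  # Da


@dataclass(frozen=True)
class MetaboliteRecord:
    id: str
    name: str
    formula: str
    monoisotopic_mass: float
    pathways: frozenset[str]
    chem_class: str
    endogenous: bool

    def __post_init__(self) -> None:
        recomputed = neutral_mass(self.formula)
        if abs(recomputed - self.monoisotopic_mass) > MASS_RECOMPUTE_TOL:
            raise ValueError(
                f"{self.id}: stored mass {self.monoisotopic_mass} differs from "
                f"formula mass {recomputed:.6f} by more than {MASS_RECOMPUTE_TOL} Da"
            )


class MetaboliteDB:
    """An ordered collection of :class:`MetaboliteRecord` with unique ids."""

    def __init__(self, records: list[MetaboliteRecord]):
        ids = [r.id for r in records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        self.records = list(records)
        self._by_id = {r.id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> MetaboliteRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    @property
    def endogenous(self) -> list[MetaboliteRecord]:
        return [r for r in self.records if r.endogenous]

    def pathway_sets(self) -> dict[str, set[str]]:
        """pathway id -> set of endogenous metabolite ids."""
        out: dict[str, set[str]] = {}
        for rec in self.records:
            if not rec.endogenous:
                continue
            for pw in rec.pathways:
                out.setdefault(pw, set()).add(rec.id)
        return out

    @staticmethod
    def from_tsv(path: str | Path) -> "MetaboliteDB":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"id", "name", "formula", "mass", "pathways", "class", "endogenous"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metabolite table missing columns: {sorted(missing)}")
        records = []
        for row in df.to_dict("records"):
            pathways = frozenset(
                p for p in str(row["pathways"] or "").split(";") if p and p != "nan"
            )
            records.append(
                MetaboliteRecord(
                    id=row["id"],
                    name=row["name"],
                    formula=row["formula"],
                    monoisotopic_mass=float(row["mass"]),
                    pathways=pathways,
                    chem_class=row["class"],
                    endogenous=bool(int(row["endogenous"])),
                )
            )
        return MetaboliteDB(records)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "id": r.id,
                "name": r.name,
                "formula": r.formula,
                "mass": f"{r.monoisotopic_mass:.6f}",
                "pathways": ";".join(sorted(r.pathways)),
                "class": r.chem_class,
                "endogenous": int(r.endogenous),
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("bonemsi") / "data" / name)


def load_default_db() -> MetaboliteDB:
    """Load the bundled metabolite reference table."""
    return MetaboliteDB.from_tsv(_data_path("metabolites.tsv"))


def load_glycan_residues() -> pd.DataFrame:
    """Bundled glycan building-block table (residue label, residue formula)."""
    return pd.read_csv(_data_path("glycan_residues.tsv"), sep="\t")
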