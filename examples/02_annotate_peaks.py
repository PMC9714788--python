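"""Adduct-aware accurate-mass annotation, including glycan fragments.

Matches a handful of peak centers against the bundled metabolite table under
the five negative-mode adducts at 4 ppm, filters exogenous hits (the 9-AA
matrix ion among them), and annotates a sulfated glycan fragment by
enumerating compositions.
"""

import numpy as np

from bonemsi import (
    GlycanComposition,
    adduct_mz,
    annotate_glycans,
    annotate_peaks,
    filter_exogenous,
    glycan_fragment_mass,
    load_default_db,
    neutral_mass,
)
from bonemsi.preprocess import PeakList

db = load_default_db()

# peaks: the 9-AA matrix lock mass, pyrophosphate, ATP, and HexNAc-sulfate
centers = sorted(
    [
        adduct_mz(neutral_mass("C13H10N2"), "M-H"),          # 9-AA matrix
        adduct_mz(db["ppi"].monoisotopic_mass, "M-H"),       # PPi
        adduct_mz(db["atp"].monoisotopic_mass, "M-H"),       # ATP
        adduct_mz(
            glycan_fragment_mass(
                GlycanComposition.from_counts({"HexNAc": 1}, {"S": 1})
            ),
            "M-H",
        ),
    ]
)
peaks = PeakList(np.array(centers), np.full(4, 10.0), np.ones(4))

annotations = annotate_peaks(peaks, db, tol_ppm=4)
print(f"{len(annotations)} metabolite annotations before the exogenous filter:")
for a in annotations:
    tag = "endogenous" if a.endogenous else "EXOGENOUS"
    print(f"  m/z {a.peak_mz:9.4f} -> {a.name:18s} [{a.adduct:7s}] "
          f"{a.ppm:+.2f} ppm ({tag})")

kept = filter_exogenous(annotations)
print(f"after filtering drugs/pesticides/matrix: {len(kept)} annotations")

glycans = annotate_glycans(peaks, tol_ppm=4)
print("glycan-composition matches ([M-H]-):")
for g in glycans:
    print(f"  m/z {g.peak_mz:9.4f} -> {g.record_id} ({g.ppm:+.2f} ppm)")
# The ppm error is the signed relative deviation of the observed m/z from the
# theoretical adduct mass; 4 ppm is the annotation acceptance window.
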