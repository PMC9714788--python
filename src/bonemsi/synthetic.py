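"""Ground-truthed bone-phantom MSI generator.

Each phantom section is a 2-D pixel grid (50 um notional spacing) holding a
cross-section through a long bone: a mineralized cortical ring, an inner
osteoid seam, a marrow core, and off-tissue background.  Spectra span m/z
75-1100 and are synthesized as Gaussian peaks at the exact negative-adduct
m/z of bundled metabolite records, with

* compartment-specific base intensities (each peak has a "home" compartment
  where it is most abundant),
* two groups of sections (default WT-like and Hyp-like, n=5 each) with
  planted multiplicative group effects on selected peaks,
* per-pixel multiplicative log-normal noise of a given CV,
* optional per-section calibration jitter (<= 1 ppm) and additive baseline
  noise.

The generator returns the ground truth (masks, peak identities, planted
effect sets) alongside the datasets, so every pipeline stage can be scored
against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import adduct_mz
from .db import MetaboliteDB
from .io import DEFAULT_VOCABULARY, MSIDataset, ROIMask, write_imzml, write_roi_mask

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom_masks",
    "generate_dataset",
    "write_phantom",
    "COMPARTMENTS",
]

COMPARTMENTS = ("mineralized_bone", "osteoid", "bone_marrow")


@dataclass
class PhantomSpec:
    """Geometry, signal and noise parameters of the synthetic bone phantom."""

    n_rows: int = 64
    n_cols: int = 64
    outer_radius: float = 28.0       # cortical ring outer radius, pixels
    ring_width: float = 8.0          # mineralized shell thickness, pixels
    seam_width: float = 3.0          # osteoid seam thickness, pixels (>= 1)
    mask_perturb: float = 1.0        # per-section radius jitter, pixels
    groups: tuple[str, str] = ("WT", "Hyp")
    n_sections_per_group: int = 5
    n_peaks: int = 300               # target peak count from the database
    min_separation_ppm: float = 500.0
    n_up: int = 20                   # planted upregulated peaks (group B)
    n_down: int = 15                 # planted downregulated peaks
    effect_log2: float = 3.0         # |log2 fold change| of planted effects
    effect_table: dict[str, float] | None = None  # metabolite id -> log2 effect
    noise_cv: float = 0.2            # per-pixel log-normal multiplicative CV
    peak_sigma_ppm: float = 10.0     # Gaussian peak width (sigma) in ppm
    baseline_sigma: float = 0.1      # additive baseline noise, a.u.
    jitter_ppm: float = 0.3          # per-section calibration shift (<= 1 ppm)
    base_high: float = 100.0         # home-compartment base intensity, a.u.
    base_low_range: tuple[float, float] = (2.0, 10.0)
    # Group effects are planted in trace-abundance peaks so that the total
    # ion current stays nearly constant (the assumption under which RMS
    # normalization leaves fold changes interpretable).
    planted_home_range: tuple[float, float] = (8.0, 12.0)
    planted_low_range: tuple[float, float] = (1.5, 4.0)
    # 9-AA matrix ion: dominates off-tissue pixels, suppressed on tissue.
    include_matrix_peak: bool = True
    matrix_base_background: float = 500.0
    matrix_base_tissue: float = 50.0
    mz_range: tuple[float, float] = (75.0, 1100.0)
    adducts: tuple[str, ...] = ("M-H", "M+Cl")
    seed: int = 0

    def validate(self) -> None:
        if self.seam_width < 1:
            raise ValueError("osteoid seam width must be >= 1 pixel")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        half = min(self.n_rows, self.n_cols) / 2.0
        if self.outer_radius + self.mask_perturb >= half:
            raise ValueError("cortical ring does not fit the grid")
        if self.ring_width + self.seam_width >= self.outer_radius:
            raise ValueError("ring plus seam exceed the outer radius")
        if self.effect_table is not None and not all(
            np.isfinite(v) for v in self.effect_table.values()
        ):
            raise ValueError("effect table entries must be finite")


@dataclass
class GroundTruth:
    """What was planted: masks, peak identities, bases, and effect sets."""

    masks: list[ROIMask]
    peak_table: pd.DataFrame          # mz, id, name, adduct, home_compartment
    base: np.ndarray                  # (3 compartments, n_peaks) base intensity
    effect_log2: np.ndarray           # per-peak log2 effect (group B vs A)
    up_indices: np.ndarray
    down_indices: np.ndarray
    spec: PhantomSpec

    @property
    def mz(self) -> np.ndarray:
        return self.peak_table["mz"].values

    def home_compartments(self) -> np.ndarray:
        """Per-peak index into COMPARTMENTS (-1 for off-tissue, e.g. matrix)."""
        lookup = {c: i for i, c in enumerate(COMPARTMENTS)}
        return np.array(
            [lookup.get(c, -1) for c in self.peak_table["home_compartment"]]
        )


# ---------------------------------------------------------------------------

def _section_ids(spec: PhantomSpec) -> list[tuple[str, str]]:
    out = []
    for group in spec.groups:
        for i in range(spec.n_sections_per_group):
            out.append((f"{group}_{i + 1}", group))
    return out


def generate_phantom_masks(spec: PhantomSpec) -> list[ROIMask]:
    """Concentric compartment masks, one per section.

    Outside the outer radius is background; then the mineralized ring, the
    osteoid seam, and the marrow core.  A small seeded jitter of the radii
    and center distinguishes sections.  Deterministic given the spec seed.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    vocab = DEFAULT_VOCABULARY
    index = {name: i for i, name in enumerate(vocab)}
    masks = []
    yy, xx = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
    for section_id, group in _section_ids(spec):
        dc = rng.uniform(-spec.mask_perturb, spec.mask_perturb, size=4)
        cy = spec.n_rows / 2.0 + dc[0]
        cx = spec.n_cols / 2.0 + dc[1]
        r_out = spec.outer_radius + dc[2]
        r_ring = r_out - spec.ring_width + dc[3] * 0.5
        r_seam = r_ring - spec.seam_width
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        labels = np.full((spec.n_rows, spec.n_cols), index["background"], dtype=int)
        labels[r <= r_out] = index["mineralized_bone"]
        labels[r <= r_ring] = index["osteoid"]
        labels[r <= r_seam] = index["bone_marrow"]
        masks.append(ROIMask(labels, vocab, group=group, section_id=section_id))
    return masks


#: [M-H]- of the 9-aminoacridine matrix (lock-mass region kept effect-free).
MATRIX_MZ = 193.077122


def _build_peak_table(spec: PhantomSpec, db: MetaboliteDB) -> pd.DataFrame:
    """Deterministic peak list: adduct m/z of endogenous records, deduplicated
    to a minimum ppm separation, truncated to ``n_peaks``; the 9-AA matrix
    ion is inserted when enabled."""
    rows = []
    for rec in db.endogenous:
        for adduct in spec.adducts:
            try:
                mz = adduct_mz(rec.monoisotopic_mass, adduct)
            except ValueError:
                continue
            if spec.mz_range[0] <= mz <= spec.mz_range[1]:
                rows.append(
                    {"mz": mz, "id": rec.id, "name": rec.name, "adduct": adduct}
                )
    if spec.include_matrix_peak:
        rows = [
            r for r in rows
            if abs(r["mz"] - MATRIX_MZ) / MATRIX_MZ * 1e6 >= spec.min_separation_ppm
        ]
        rows.append(
            {"mz": MATRIX_MZ, "id": "x9aa", "name": "9-aminoacridine",
             "adduct": "M-H"}
        )
    rows.sort(key=lambda r: (r["mz"], r["id"], r["adduct"]))
    kept: list[dict] = []
    for row in rows:
        if (
            kept
            and row["id"] != "x9aa"
            and (row["mz"] - kept[-1]["mz"]) / kept[-1]["mz"] * 1e6
            < spec.min_separation_ppm
        ):
            continue
        kept.append(row)
    # the matrix ion and the pyrophosphate showcase peak survive truncation
    keep_always = {"x9aa", "ppi"}
    special = [r for r in kept if r["id"] in keep_always]
    others = [r for r in kept if r["id"] not in keep_always]
    kept = sorted(
        others[: spec.n_peaks - len(special)] + special, key=lambda r: r["mz"]
    )
    return pd.DataFrame(kept).reset_index(drop=True)


def _plant_effects(
    spec: PhantomSpec, table: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(table)
    effects = np.zeros(n)
    if spec.effect_table is not None:
        ids = list(table["id"])
        for mid, log2fc in spec.effect_table.items():
            if mid not in ids:
                raise ValueError(f"effect on unknown peak id {mid!r}")
            effects[ids.index(mid)] = log2fc
        up = np.flatnonzero(effects > 0)
        down = np.flatnonzero(effects < 0)
        return effects, up, down
    n_eff = spec.n_up + spec.n_down
    # eligible: not the matrix ion (lock mass), not within 2 Da of it, and
    # not pyrophosphate (kept as the compartment-specific showcase peak)
    mz = table["mz"].values
    eligible = np.flatnonzero(
        (np.abs(mz - MATRIX_MZ) > 2.0) & (table["id"] != "ppi").values
    )
    if n_eff > len(eligible):
        raise ValueError("more planted effects than eligible peaks")
    chosen = rng.choice(eligible, size=n_eff, replace=False)
    up = np.sort(chosen[: spec.n_up])
    down = np.sort(chosen[spec.n_up:])
    effects[up] = spec.effect_log2
    effects[down] = -spec.effect_log2
    return effects, up, down


def generate_dataset(
    spec: PhantomSpec, db: MetaboliteDB
) -> tuple[list[MSIDataset], GroundTruth]:
    """Generate one continuous-mode dataset per section plus ground truth.

    Pixel intensity of peak k = base(compartment, k) x 2^(log2 effect, group
    B only) x LogNormal(mean 1, CV); spectra are Gaussian peaks sampled on a
    sparse local grid (center and +/-3 sigma) at the adduct m/z shifted by
    the per-section calibration jitter, plus additive baseline noise clipped
    at zero.  Deterministic given the spec (seeded substreams per section).
    """
    spec.validate()
    masks = generate_phantom_masks(spec)
    table = _build_peak_table(spec, db)
    if len(table) == 0:
        raise ValueError("no peaks in range; check database and spec")
    n_peaks = len(table)
    root = np.random.SeedSequence([spec.seed, 202])
    rng = np.random.default_rng(root)

    # home compartments and base intensity profiles
    home = rng.integers(0, len(COMPARTMENTS), size=n_peaks)
    ids = list(table["id"])
    if "ppi" in ids:  # pyrophosphate lives in the unmineralized osteoid seam
        home[[i for i, x in enumerate(ids) if x == "ppi"]] = COMPARTMENTS.index(
            "osteoid"
        )
    base = rng.uniform(*spec.base_low_range, size=(len(COMPARTMENTS), n_peaks))
    base[home, np.arange(n_peaks)] = spec.base_high
    effects, up, down = _plant_effects(spec, table, rng)
    # planted-effect peaks are trace-abundance (home preference kept) so the
    # group effects barely move the per-pixel RMS
    planted = np.concatenate([up, down]).astype(int)
    if len(planted):
        base[:, planted] = rng.uniform(
            *spec.planted_low_range, size=(len(COMPARTMENTS), len(planted))
        )
        base[home[planted], planted] = rng.uniform(
            *spec.planted_home_range, size=len(planted)
        )
    # matrix ion: uniform over tissue, strongest off tissue
    bg_amp = np.zeros(n_peaks)
    home_labels = [COMPARTMENTS[h] for h in home]
    if spec.include_matrix_peak and "x9aa" in ids:
        k = ids.index("x9aa")
        base[:, k] = spec.matrix_base_tissue
        bg_amp[k] = spec.matrix_base_background
        home_labels[k] = "background"
    table = table.assign(home_compartment=home_labels, effect_log2=effects)

    mz0 = table["mz"].values
    sigma = spec.peak_sigma_ppm * 1e-6
    offsets = np.array([-3.5, 0.0, 3.5])  # in units of sigma
    shape = np.exp(-0.5 * offsets.astype(float) ** 2)

    # log-normal multiplicative noise with mean 1 and the requested CV
    s2 = np.log1p(spec.noise_cv**2)
    s = np.sqrt(s2)

    vocab_index = {name: i for i, name in enumerate(DEFAULT_VOCABULARY)}
    comp_of_label = np.full(len(DEFAULT_VOCABULARY), -1, dtype=int)
    for ci, cname in enumerate(COMPARTMENTS):
        comp_of_label[vocab_index[cname]] = ci

    datasets = []
    section_seeds = root.spawn(len(masks))
    group_b = spec.groups[1]
    for mask, sseed in zip(masks, section_seeds):
        srng = np.random.default_rng(sseed)
        jitter = (
            srng.uniform(-spec.jitter_ppm, spec.jitter_ppm) * 1e-6
            if spec.jitter_ppm > 0
            else 0.0
        )
        centers = mz0 * (1.0 + jitter)
        # shared axis: per peak, points at center * (1 + k * sigma)
        axis = (centers[:, None] * (1.0 + offsets[None, :] * sigma)).ravel()
        order = np.argsort(axis)
        axis = axis[order]
        # Gaussian profile matrix (n_peaks, n_axis_points)
        profile = np.zeros((n_peaks, axis.size))
        flat_cols = np.argsort(order)  # position of each original point
        for k in range(n_peaks):
            cols = flat_cols[k * len(offsets): (k + 1) * len(offsets)]
            profile[k, cols] = shape

        yy, xx = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        labels = mask.labels[coords[:, 1], coords[:, 0]]
        comp = comp_of_label[labels]
        amp = np.zeros((len(coords), n_peaks))
        tissue = comp >= 0
        amp[tissue] = base[comp[tissue]]
        amp[~tissue] = bg_amp
        if mask.group == group_b:
            amp *= np.power(2.0, effects)[None, :]
        if spec.noise_cv > 0:
            amp *= srng.lognormal(mean=-s2 / 2.0, sigma=s, size=amp.shape)
        intensities = amp @ profile
        if spec.baseline_sigma > 0:
            intensities += srng.normal(0.0, spec.baseline_sigma, intensities.shape)
            np.clip(intensities, 0.0, None, out=intensities)
        datasets.append(
            MSIDataset.continuous(
                coords, axis, intensities,
                section_id=mask.section_id, group=mask.group,
            ).sorted_canonical()
        )

    truth = GroundTruth(
        masks=masks,
        peak_table=table,
        base=base,
        effect_log2=effects,
        up_indices=up,
        down_indices=down,
        spec=spec,
    )
    return datasets, truth


def write_phantom(
    spec: PhantomSpec, db: MetaboliteDB, outdir: str | Path
) -> dict[str, list[Path]]:
    """Write the phantom to disk: imzML/ibd per section, mask TSVs, and
    ground-truth tables.  Returns the paths by kind."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, truth = generate_dataset(spec, db)
    paths: dict[str, list[Path]] = {"imzml": [], "masks": [], "truth": []}
    for ds, mask in zip(datasets, truth.masks):
        imz = outdir / f"{ds.section_id}.imzML"
        write_imzml(ds, imz)
        paths["imzml"].append(imz)
        mpath = outdir / f"{ds.section_id}_mask.tsv"
        write_roi_mask(mask, mpath)
        paths["masks"].append(mpath)
    tpath = outdir / "ground_truth_peaks.tsv"
    truth.peak_table.to_csv(tpath, sep="\t", index=False, float_format="%.6f")
    paths["truth"].append(tpath)
    sections = pd.DataFrame(
        [
            {"section_id": m.section_id, "group": m.group, "mask": f"{m.section_id}_mask.tsv"}
            for m in truth.masks
        ]
    )
    spath = outdir / "sections.tsv"
    sections.to_csv(spath, sep="\t", index=False)
    paths["truth"].append(spath)
    return paths
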