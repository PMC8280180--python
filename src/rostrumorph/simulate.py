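"""Synthetic belemnite rostrum assemblages with known ground truth.

The original CT-derived landmark coordinates are not publicly deposited, so
every pipeline stage is exercised on procedurally generated assemblages that
emulate their structure: 22-point landmark configurations with
species-specific robustness (width/length proportion), stage-dependent size
and temperature-regime-dependent allometry, Gaussian landmark noise,
per-subzone species composition vectors, and a bed-level isotope series with
a step change at the stage boundary.

The rostrum profile is a piecewise sagittal outline (conical apex blending
into a parallel-sided shaft) rather than a mesh: the pipeline consumes
landmarks only.  The rostrum cavum spans 1/6 of the rostrum solidum length,
matching the truncation rule applied to the CT models.  Two fixed landmarks
sit laterally on the reference transversal section, so configurations are
genuinely three-dimensional and the thin-plate-spline system is
well-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    LandmarkConfiguration,
    Lithology,
    OccurrenceTable,
    ProxyTable,
    SpecimenRecord,
    Stage,
    SUBZONE_ORDER,
)

#: fraction of solidum length over which the apex tapers to full diameter
TAPER_FRACTION = 0.35
#: cavum length as a fraction of solidum length (the truncation rule)
CAVUM_FRACTION = 1.0 / 6.0


def generate_rostrum_landmarks(
    length: float,
    max_diameter: float,
    wall_thickness: float,
    protoconch_offset: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    specimen_id: str = "synthetic",
) -> LandmarkConfiguration:
    """Procedural 22-landmark configuration of one rostrum.

    ``length`` is the rostrum solidum length (mm); the cavum adds length/6.
    Ten fixed landmarks: apex, ventral/dorsal/lateral outer walls and
    ventral/dorsal inner (alveolar) walls at the reference transversal
    section, protoconch, and the ventral/dorsal cavum rim.  Twelve sliding
    semilandmarks sit equidistantly (in arc length) along the ventral and
    dorsal sagittal outlines.  Isotropic Gaussian noise of ``noise_sd`` mm
    is added to every coordinate; deterministic given ``seed``.
    """
    ls, d, w = float(length), float(max_diameter), float(wall_thickness)
    if min(ls, d, w) <= 0:
        raise ValueError("length, max_diameter and wall_thickness must be positive")
    if d >= ls:
        raise ValueError("max_diameter must be smaller than length")
    if w >= d / 2:
        raise ValueError("wall_thickness must be smaller than the rostrum radius")
    if abs(protoconch_offset) >= d / 2 - w:
        raise ValueError("protoconch_offset places the protoconch outside the alveolus")
    lc = ls * CAVUM_FRACTION
    zt = TAPER_FRACTION * ls
    r = d / 2.0
    fixed = np.array(
        [
            [0.0, 0.0, 0.0],          # 1 apex
            [-r, 0.0, ls],            # 2 ventral outer wall, reference section
            [r, 0.0, ls],             # 3 dorsal outer wall, reference section
            [0.0, -r, ls],            # 4 lateral outer wall (left)
            [0.0, r, ls],             # 5 lateral outer wall (right)
            [-r + w, 0.0, ls],        # 6 ventral inner (alveolar) wall
            [r - w, 0.0, ls],         # 7 dorsal inner (alveolar) wall
            [protoconch_offset, 0.0, ls],  # 8 protoconch
            [-r, 0.0, ls + lc],       # 9 ventral cavum rim
            [r, 0.0, ls + lc],        # 10 dorsal cavum rim
        ]
    )

    def outline_sliders(sign: float) -> np.ndarray:
        # polyline: apex -> taper end -> rim, sliders at equal arc spacing
        verts = np.array(
            [[0.0, 0.0, 0.0], [sign * r, 0.0, zt], [sign * r, 0.0, ls + lc]]
        )
        seg = np.diff(verts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        total = seg_len.sum()
        cuts = np.concatenate([[0.0], np.cumsum(seg_len)])
        targets = total * np.arange(1, 7) / 7.0
        pts = np.empty((6, 3))
        for i, s in enumerate(targets):
            j = int(np.searchsorted(cuts[1:], s, side="left"))
            frac = (s - cuts[j]) / seg_len[j]
            pts[i] = verts[j] + frac * seg[j]
        return pts

    ventral = outline_sliders(-1.0)
    dorsal = outline_sliders(+1.0)
    coords = np.vstack([fixed, ventral, dorsal])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
    return LandmarkConfiguration(specimen_id, coords)


def width_length_ratio(config: LandmarkConfiguration) -> float:
    """Robustness proportion recomputed from the landmarks: dorsoventral
    width at the reference section over rostrum solidum length (apex to
    reference section)."""
    coords = config.coordinates
    width = coords[2, 0] - coords[1, 0]
    solidum = coords[1, 2] - coords[0, 2]
    return float(width / solidum)


@dataclass
class AssemblageTruth:
    """Ground-truth parameters of a synthetic assemblage.

    ``species_params`` maps species to (base robustness ratio, base solidum
    length mm); ``allometry`` holds the per-regime slope of the robustness
    ratio on size (per mm); ``stage_size_distributions`` gives per-stage
    multiplicative size factors (mean, sd) relative to the species base
    size; ``composition`` per-subzone species probability vectors.
    """

    species_params: dict[str, tuple[float, float]]
    allometry: dict[str, float]
    stage_size_distributions: dict[Stage, tuple[float, float]]
    stage_probabilities: dict[Stage, float]
    composition: dict[str, dict[str, float]]
    proxy_series: pd.DataFrame
    subzone_beds: dict[str, list[str]]
    lithology_map: dict[str, Lithology]
    noise_sd: float = 0.3
    robustness_sd: float = 0.015
    temperature_threshold: float = -0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for subzone, probs in self.composition.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"composition for {subzone!r} sums to {total}, not 1")
        if self.noise_sd < 0 or self.robustness_sd < 0:
            raise ValueError("noise scales must be non-negative")
        for species, (ratio, size) in self.species_params.items():
            if ratio <= 0 or size <= 0:
                raise ValueError(f"non-positive parameters for {species!r}")

    def regime_of_bed(self, bed: str) -> str:
        d18o = float(self.proxy_series.at[bed, "d18O"])
        return "warm" if d18o < self.temperature_threshold else "cold"


@dataclass
class GeneratedAssemblage:
    """One realised synthetic assemblage plus its per-specimen truth table."""

    landmarks: list[LandmarkConfiguration]
    records: list[SpecimenRecord]
    proxies: ProxyTable
    occurrences: OccurrenceTable
    truth_table: pd.DataFrame
    truth: AssemblageTruth


#: default per-bed isotope series: ten beds, two per subzone, with the d18O
#: step at the stage boundary (-0.7 permil background, -1.3 after) so the
#: -0.9 threshold bisects the series cleanly
_BEDS = [f"b{i:02d}" for i in range(1, 11)]
_D18O = [-0.72, -0.65, -0.78, -0.68, -1.35, -1.22, -1.31, -1.18, -1.28, -1.40]
_D13C = [1.2, 0.9, 1.1, 1.0, -0.3, 0.2, 1.1, 1.3, 1.2, 1.4]
_D11B = [38.6, 38.2, 38.4, 37.9, 38.3, 37.5, 37.6, 38.2, 37.8, 38.4]
_LITH = [
    Lithology.MARL, Lithology.LIMESTONE, Lithology.MARL, Lithology.MARLY_LIMESTONE,
    Lithology.MARL, Lithology.LIMESTONE, Lithology.MARL, Lithology.MARLY_LIMESTONE,
    Lithology.LIMESTONE, Lithology.MARL,
]

_DEFAULT_SPECIES = {
    "P. bisulcata": (0.26, 40.0),
    "C. longiforma": (0.17, 45.0),
    "Bairstowius amaliae": (0.15, 38.0),
    "P. milleri": (0.24, 35.0),
}

_OVERALL_COMPOSITION = {
    "P. bisulcata": 0.33,
    "C. longiforma": 0.37,
    "Bairstowius amaliae": 0.14,
    "P. milleri": 0.16,
}


def default_proxy_series() -> pd.DataFrame:
    return pd.DataFrame(
        {"d18O": _D18O, "d13C": _D13C, "d11B": _D11B}, index=pd.Index(_BEDS, name="bed")
    )


def default_truth(seed: int = 0, **overrides) -> AssemblageTruth:
    """The baseline study conditions: four species spanning slender to
    robust, negative allometry steeper in the warm regime, juveniles about
    half adult size, identical composition in every subzone."""
    params = dict(
        species_params=dict(_DEFAULT_SPECIES),
        allometry={"warm": -0.004, "cold": -0.002},
        stage_size_distributions={
            Stage.JUVENILE: (0.55, 0.07),
            Stage.NEANIC: (0.80, 0.07),
            Stage.ADULT: (1.05, 0.08),
        },
        stage_probabilities={Stage.JUVENILE: 0.40, Stage.NEANIC: 0.35, Stage.ADULT: 0.25},
        composition={sz: dict(_OVERALL_COMPOSITION) for sz in SUBZONE_ORDER},
        proxy_series=default_proxy_series(),
        subzone_beds={sz: [_BEDS[2 * i], _BEDS[2 * i + 1]] for i, sz in enumerate(SUBZONE_ORDER)},
        lithology_map=dict(zip(_BEDS, _LITH)),
        seed=seed,
    )
    params.update(overrides)
    return AssemblageTruth(**params)


def null_and_shifted_scenarios(seed: int = 0) -> tuple[AssemblageTruth, AssemblageTruth]:
    """Composition presets for the bootstrap null: a null preset with
    identical composition in every subzone, and a shifted preset in which
    the Mirabile subzone's dominant species is replaced by the most robust
    one (its probability mass moved wholesale)."""
    null = default_truth(seed=seed)
    shifted_comp = {sz: dict(_OVERALL_COMPOSITION) for sz in SUBZONE_ORDER}
    moved = shifted_comp["Mirabile"].pop("C. longiforma")
    shifted_comp["Mirabile"]["P. milleri"] = (
        shifted_comp["Mirabile"].get("P. milleri", 0.0) + moved
    )
    shifted = default_truth(seed=seed, composition=shifted_comp)
    return null, shifted


def generate_assemblage(
    truth: AssemblageTruth, n_per_subzone: int | dict[str, int] = 30
) -> GeneratedAssemblage:
    """Draw a full synthetic assemblage from the ground-truth parameters.

    Per subzone, species are sampled from the composition vector and stages
    from the stage probabilities; each specimen's size comes from its
    stage's factor distribution scaled by the species base size, and its
    robustness ratio from the species base plus the bed regime's allometric
    slope times the size deviation, plus Gaussian scatter.  All outputs are
    deterministic given ``truth.seed``.
    """
    if isinstance(n_per_subzone, int):
        n_map = {sz: n_per_subzone for sz in truth.composition}
    else:
        n_map = dict(n_per_subzone)
    if sum(n_map.values()) <= 0:
        raise ValueError("zero specimens requested")
    rng = np.random.default_rng(truth.seed)
    landmarks: list[LandmarkConfiguration] = []
    records: list[SpecimenRecord] = []
    truth_rows = []
    stage_keys = list(truth.stage_probabilities)
    stage_p = np.array([truth.stage_probabilities[s] for s in stage_keys], dtype=float)
    stage_p = stage_p / stage_p.sum()
    counter = 0
    for subzone in [sz for sz in SUBZONE_ORDER if sz in n_map]:
        comp = truth.composition[subzone]
        species_names = list(comp)
        probs = np.array([comp[s] for s in species_names], dtype=float)
        beds = truth.subzone_beds[subzone]
        for _ in range(n_map[subzone]):
            counter += 1
            sid = f"syn{counter:04d}"
            species = species_names[rng.choice(len(species_names), p=probs)]
            stage = stage_keys[rng.choice(len(stage_keys), p=stage_p)]
            bed = beds[rng.integers(len(beds))]
            regime = truth.regime_of_bed(bed)
            base_ratio, base_size = truth.species_params[species]
            mean_f, sd_f = truth.stage_size_distributions[stage]
            size = base_size * max(rng.normal(mean_f, sd_f), 0.2)
            ratio = (
                base_ratio
                + truth.allometry[regime] * (size - base_size)
                + rng.normal(0.0, truth.robustness_sd)
            )
            ratio = float(np.clip(ratio, 0.05, 0.8))
            lm_seed = int(rng.integers(0, 2**31 - 1))
            diameter = ratio * size
            cfg = generate_rostrum_landmarks(
                length=size,
                max_diameter=diameter,
                wall_thickness=0.15 * diameter / 2.0,
                protoconch_offset=0.1 * diameter / 2.0,
                noise_sd=truth.noise_sd,
                seed=lm_seed,
                specimen_id=sid,
            )
            landmarks.append(cfg)
            # linear measurements with small gauge error, for the
            # geometric-mean body-size proxy
            gauge = rng.normal(1.0, 0.01, 3)
            measurements = {
                "length": size * gauge[0],
                "diameter": ratio * size * gauge[1],
                "cavum_depth": size * CAVUM_FRACTION * gauge[2],
            }
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    taxon=species,
                    stage=stage,
                    bed=bed,
                    subzone=subzone,
                    lithology=truth.lithology_map[bed],
                    measurements=measurements,
                )
            )
            truth_rows.append(
                (sid, species, stage.value, subzone, bed, regime, size, ratio)
            )
    proxies = ProxyTable(truth.proxy_series)
    totals = pd.DataFrame(
        0,
        index=pd.Index([sz for sz in SUBZONE_ORDER if sz in n_map], name="subzone"),
        columns=sorted({r.taxon for r in records}),
        dtype=int,
    )
    stage_counts: dict[tuple[str, str], dict[str, int]] = {}
    for rec in records:
        totals.at[rec.subzone, rec.taxon] += 1
        cell = stage_counts.setdefault((rec.subzone, rec.taxon), {})
        key = rec.stage.value
        cell[key] = cell.get(key, 0) + 1
    occurrences = OccurrenceTable(totals, stage_counts)
    truth_table = pd.DataFrame(
        truth_rows,
        columns=["specimen_id", "species", "stage", "subzone", "bed", "regime", "size", "ratio"],
    ).set_index("specimen_id")
    return GeneratedAssemblage(
        landmarks=landmarks,
        records=records,
        proxies=proxies,
        occurrences=occurrences,
        truth_table=truth_table,
        truth=truth,
    )
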