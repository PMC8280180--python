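"""End-to-end analysis pipeline: align -> ordinate -> contrasts ->
composition bootstrap -> stage analyses -> temperature-split allometry ->
variation partitioning -> GLS model selection.

Every numerical parameter of the published workflow is a named config key
with that value as its default: the 22-landmark scheme, the 1/6 cavum
truncation (generator side), the -0.9 permil temperature threshold, the
29-draw / 500-replicate composition bootstrap, and the < 0.1 marginal
significance tier.  A report is reproducible byte-for-byte from config +
seed; the config hash is embedded in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import bootstrap_composition, classify_subzones, default_draw_n
from .effects import (
    hedges_g,
    mad_envelope,
    mann_whitney_u,
    mood_median_test,
    pairwise_median_tests,
    significance_tier,
    validate_size_proxy,
)
from .envmodels import (
    compare_slopes,
    fit_allometry,
    gls_select,
    lithology_dummies,
    ordinal_stage_model,
    predictor_collinearity_check,
    split_by_temperature,
    variation_partitioning,
)
from .gpa import gpa_align
from .io import (
    LandmarkConfiguration,
    OccurrenceTable,
    ProxyTable,
    SpecimenRecord,
    Stage,
    SUBZONE_ORDER,
    assign_proxies,
    read_landmarks,
    read_occurrence_table,
    read_specimen_records,
)
from .ordination import pca_fit, robustness_scores

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run; unset paths skip loading and
    require in-memory inputs."""

    landmarks_path: str | None = None
    landmarks_format: str | None = None
    records_path: str | None = None
    proxies_path: str | None = None
    occurrences_path: str | None = None
    slide: bool = True
    gpa_tol: float = 1e-8
    gpa_max_iter: int = 100
    tangent: bool = True
    temperature_threshold: float = -0.9
    draw_n: int | str = "auto"
    bootstrap_reps: int = 500
    adjustment: str = "none"
    candidates: tuple[str, ...] = ("d18O", "d13C", "d11B")
    correlation: str = "ar1"
    size_proxy_r2_gate: float = 0.9
    min_species_n: int = 10
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "candidates" in data:
            data["candidates"] = tuple(data["candidates"])
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisReport:
    """Machine-readable record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
            },
            sort_keys=True,
            indent=1,
            default=_jsonify,
        )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, Stage):
        return obj.value
    return str(obj)


def _consecutive_contrasts(
    values_by_subzone: dict[str, np.ndarray], label: str
) -> list[dict[str, Any]]:
    """Hedges' g + Mann-Whitney U between consecutive subzone samples,
    earlier sample first (an increase through time prints negative g)."""
    present = [sz for sz in SUBZONE_ORDER if len(values_by_subzone.get(sz, [])) > 0]
    out = []
    for earlier, later in zip(present, present[1:]):
        a, b = values_by_subzone[earlier], values_by_subzone[later]
        row: dict[str, Any] = {
            "contrast": f"{earlier}-{later}", "variable": label,
            "n1": len(a), "n2": len(b),
        }
        try:
            eff = hedges_g(a, b, ordering=f"{earlier} first")
            row["g"] = eff.g
        except ValueError as exc:
            row["g"] = None
            row["note"] = str(exc)
        try:
            u, p = mann_whitney_u(a, b)
            row.update(U=u, p=p, tier=significance_tier(p))
        except ValueError as exc:
            row.update(U=None, p=None, tier="n.s.", note=str(exc))
        out.append(row)
    return out


def run_analysis(
    landmarks: Sequence[LandmarkConfiguration],
    records: Sequence[SpecimenRecord],
    proxies: ProxyTable,
    occurrences: OccurrenceTable,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis on in-memory inputs.  See module docstring for
    the stage order; any stage failure raises :class:`PipelineError` naming
    the stage, with the partially filled report attached as ``report``."""
    config = config or AnalysisConfig()
    report = AnalysisReport(
        config_hash=config.config_hash(), seed=config.seed, version=__version__
    )
    stage = "validate"
    try:
        records = list(records)
        landmarks = list(landmarks)
        by_id = {c.specimen_id: c for c in landmarks}
        if set(by_id) != {r.specimen_id for r in records}:
            raise ValueError("landmark and record specimen ids disagree")
        ordered = [by_id[r.specimen_id] for r in records]
        report.stages["validate"] = {"n_specimens": len(records)}

        stage = "assign_proxies"
        records = assign_proxies(records, proxies)

        stage = "gpa"
        aligned = gpa_align(
            ordered, slide=config.slide, tol=config.gpa_tol, max_iter=config.gpa_max_iter
        )
        report.stages["gpa"] = {
            "iterations": aligned.iterations,
            "converged": aligned.converged,
            "mean_procrustes_distance": float(aligned.procrustes_distances.mean()),
        }

        stage = "pca"
        model = pca_fit(aligned, tangent=config.tangent)
        pc1 = robustness_scores(model)
        report.stages["pca"] = {
            "n_components": model.n_components,
            "variance_fractions": model.variance_fractions[:5].tolist(),
            "pc1_fraction": float(model.variance_fractions[0]),
            "pc1_flipped_for_robustness": model.pc1_flipped_for_robustness,
        }

        stage = "size_proxy"
        gms = np.array(
            [np.exp(np.mean(np.log(list(r.measurements.values())))) if r.measurements else np.nan
             for r in records]
        )
        if np.isfinite(gms).sum() >= 3:
            mask = np.isfinite(gms)
            slope, intercept, r2, p = validate_size_proxy(
                gms[mask], aligned.centroid_sizes[mask]
            )
            report.stages["size_proxy"] = {
                "slope": slope, "intercept": intercept, "r_squared": r2, "p": p,
                "passes_gate": bool(r2 >= config.size_proxy_r2_gate),
            }
        else:
            report.stages["size_proxy"] = {"note": "no linear measurements available"}

        subzone_of = np.array([r.subzone for r in records])
        taxa = np.array([r.taxon for r in records])
        sizes = aligned.centroid_sizes

        stage = "assemblage_contrasts"
        def group(values: np.ndarray, mask=None) -> dict[str, np.ndarray]:
            mask = np.ones(len(records), bool) if mask is None else mask
            return {
                sz: values[(subzone_of == sz) & mask] for sz in SUBZONE_ORDER
            }

        contrasts = _consecutive_contrasts(group(sizes), "centroid_size")
        contrasts += _consecutive_contrasts(group(pc1), "robustness")
        report.stages["assemblage_contrasts"] = contrasts

        stage = "species_contrasts"
        focus = [
            t for t, n in pd.Series(taxa).value_counts().items()
            if n >= config.min_species_n
            and len({r.subzone for r in records if r.taxon == t}) >= 2
        ][:2]
        species_contrasts = {}
        for taxon in focus:
            m = taxa == taxon
            species_contrasts[taxon] = (
                _consecutive_contrasts(group(sizes, m), "centroid_size")
                + _consecutive_contrasts(group(pc1, m), "robustness")
            )
        report.stages["species_contrasts"] = species_contrasts

        stage = "mad_envelopes"
        report.stages["mad_envelopes"] = {
            "centroid_size": mad_envelope(group(sizes)).to_dict(orient="index"),
            "robustness": mad_envelope(group(pc1)).to_dict(orient="index"),
        }

        stage = "composition_bootstrap"
        draw_n = (
            default_draw_n(occurrences) if config.draw_n == "auto" else int(config.draw_n)
        )
        envelope = bootstrap_composition(
            occurrences.species_totals(), draw_n=draw_n,
            reps=config.bootstrap_reps, seed=config.seed,
        )
        classification = classify_subzones(occurrences, envelope)
        report.stages["composition_bootstrap"] = {
            "draw_n": draw_n,
            "reps": config.bootstrap_reps,
            "subzone_flags": classification.attrs["subzone_flags"],
            "n_outside": int(classification["outside"].sum()),
        }

        stage = "stage_analyses"
        stage_results = {}
        for taxon in focus:
            m = taxa == taxon
            stages_t = [r.stage for r in records if r.taxon == taxon]
            det = [i for i, r in enumerate(records)
                   if r.taxon == taxon and r.stage != Stage.INDETERMINATE]
            entry: dict[str, Any] = {}
            try:
                sel = ordinal_stage_model(
                    pc1[det], [records[i].stage for i in det]
                )
                entry["ordinal_model"] = {
                    "best": sel.best_model,
                    "stage_p": sel.metadata["stage_p"],
                    "table": sel.table.to_dict(orient="list"),
                }
            except ValueError as exc:
                entry["ordinal_model"] = {"note": str(exc)}
            # grouped Mood's median: adults+neanics vs juveniles
            older = pc1[[i for i in det if records[i].stage != Stage.JUVENILE]]
            young = pc1[[i for i in det if records[i].stage == Stage.JUVENILE]]
            if len(older) >= 2 and len(young) >= 2:
                med = mood_median_test([young, older])
                entry["grouped_median"] = {
                    "statistic": med.statistic, "p": med.p, "tier": med.tier,
                }
            pw = pairwise_median_tests(
                {sz: v for sz, v in group(pc1, m).items() if len(v)},
                adjustment=config.adjustment,
            )
            entry["pairwise_median"] = pw.drop(columns=["degenerate"]).to_dict(orient="list")
            stage_results[taxon] = entry
        report.stages["stage_analyses"] = stage_results

        stage = "allometry"
        warm, cold = split_by_temperature(records, config.temperature_threshold)
        warm_ids = {s.specimen_id for s in warm}
        allometry: dict[str, Any] = {
            "n_warm": len(warm), "n_cold": len(cold),
            "threshold": config.temperature_threshold,
        }
        in_warm = np.array([r.specimen_id in warm_ids for r in records])
        for taxon in focus:
            m = taxa == taxon
            entry = {}
            for regime, rmask in (("warm", in_warm & m), ("cold", ~in_warm & m)):
                if rmask.sum() >= 3 and np.var(sizes[rmask]) > 0:
                    fit = fit_allometry(sizes[rmask], pc1[rmask], regime=regime)
                    entry[regime] = {
                        "slope": fit.slope, "adj_r_squared": fit.adj_r_squared,
                        "p": fit.p, "n": fit.n,
                    }
            if (in_warm & m).sum() >= 3 and (~in_warm & m).sum() >= 3:
                f, p = compare_slopes(
                    sizes[in_warm & m], pc1[in_warm & m],
                    sizes[~in_warm & m], pc1[~in_warm & m],
                )
                entry["slope_anova"] = {"F": f, "p": p, "tier": significance_tier(p)}
            allometry[taxon] = entry
        report.stages["allometry"] = allometry

        stage = "variation_partitioning"
        env = pd.DataFrame(
            {c: [r.proxies[c] for r in records] for c in config.candidates}
        )
        liths = [r.lithology for r in records]
        part = variation_partitioning(
            model.scores,
            {**{c: env[c].to_numpy() for c in config.candidates},
             "lithology": lithology_dummies(liths)},
        )
        report.stages["variation_partitioning"] = {
            "fractions": part.fractions, "dropped": part.dropped,
        }

        stage = "gls_selection"
        coll = predictor_collinearity_check(env)
        bed_order = {b: i for i, b in enumerate(proxies.beds)}
        order = np.array([bed_order[r.bed] for r in records])
        gls_results: dict[str, Any] = {
            "collinearity": coll.to_dict(orient="list"),
        }
        targets = {"assemblage": np.ones(len(records), bool)}
        targets.update({t: taxa == t for t in focus})
        for name, m in targets.items():
            if m.sum() < 12:
                gls_results[name] = {"note": "too few specimens"}
                continue
            sel = gls_select(
                pc1[m], env[m].reset_index(drop=True),
                [l for l, keep in zip(liths, m) if keep],
                order[m], candidates=config.candidates,
                correlation=config.correlation,
            )
            gls_results[name] = {
                "best": sel.best_model,
                "phi": sel.metadata["phi"],
                "table": sel.table.to_dict(orient="list"),
                "coefficients": sel.coefficients.to_dict(orient="list"),
            }
        report.stages["gls_selection"] = gls_results
    except Exception as exc:  # noqa: BLE001 - abort carries the stage name
        err = PipelineError(stage, exc)
        err.report = report
        raise err from exc

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Load inputs from the paths in ``config`` and run the analysis."""
    stage = "load"
    try:
        if not config.landmarks_path or not config.records_path:
            raise ValueError("landmarks_path and records_path are required")
        landmarks = read_landmarks(config.landmarks_path, config.landmarks_format)
        records = read_specimen_records(config.records_path)
        proxies = ProxyTable.read_csv(config.proxies_path)
        occurrences = read_occurrence_table(config.occurrences_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc
    return run_analysis(landmarks, records, proxies, occurrences, config)
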