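"""Data model and I/O for belemnite rostrum morphometrics.

Specimens are 22-point 3D landmark configurations digitised on CT models of
belemnite rostra: landmarks 1-10 (1-based) are fixed anatomical points (apex,
alveolar walls at the reference transversal section, protoconch, cavum rim),
landmarks 11-22 are curve-sliding semilandmarks along the ventral and dorsal
flanks of the sagittal section.  Landmark files use 1-based indices; in-memory
arrays are 0-based — the readers/writers are the only place the shift occurs.

Supported landmark dialects: a TPS-like block format (``LM3=22`` records with
``ID=`` lines), a long CSV (``specimen_id,landmark,x,y,z``) which is the
canonical interchange, and a JSON bundle.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_LANDMARKS = 22
N_FIXED = 10
#: default curve membership (0-based): sliders 11-16 ventral, 17-22 dorsal
DEFAULT_VENTRAL = tuple(range(10, 16))
DEFAULT_DORSAL = tuple(range(16, 22))

#: stratigraphic order of the five ammonite subzones, oldest first
SUBZONE_ORDER = ("Solare", "Elisa", "Mirabile", "Semicelatum", "Elegantulum")


class Stage(str, Enum):
    """Ontogenetic stage of a specimen."""

    JUVENILE = "juvenile"
    NEANIC = "neanic"
    ADULT = "adult"
    INDETERMINATE = "indeterminate"


#: ordinal order of determinate stages (young to old)
STAGE_ORDER = (Stage.JUVENILE, Stage.NEANIC, Stage.ADULT)


class Lithology(str, Enum):
    MARL = "marl"
    LIMESTONE = "limestone"
    MARLY_LIMESTONE = "marly_limestone"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed under the named dialect."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's 22 ordered 3D landmarks with fixed/slider roles.

    Parameters
    ----------
    specimen_id : str
    coordinates : (22, 3) float array, length units (mm).
    ventral, dorsal : ordered 0-based index tuples partitioning the sliders.
    """

    specimen_id: str
    coordinates: np.ndarray
    ventral: tuple[int, ...] = DEFAULT_VENTRAL
    dorsal: tuple[int, ...] = DEFAULT_DORSAL

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.shape != (N_LANDMARKS, 3):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: expected {N_LANDMARKS} "
                f"3D landmarks, got array of shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )
        sliders = set(self.ventral) | set(self.dorsal)
        if len(self.ventral) + len(self.dorsal) != len(sliders):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: ventral/dorsal curves overlap"
            )
        if sliders != set(range(N_FIXED, N_LANDMARKS)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: curves must jointly contain "
                f"exactly landmarks {N_FIXED + 1}-{N_LANDMARKS} (1-based)"
            )

    @property
    def roles(self) -> np.ndarray:
        """Boolean mask, True where the landmark is fixed."""
        mask = np.zeros(N_LANDMARKS, dtype=bool)
        mask[:N_FIXED] = True
        return mask

    @property
    def sliders(self) -> tuple[int, ...]:
        return tuple(self.ventral) + tuple(self.dorsal)


@dataclass
class SpecimenRecord:
    """Metadata for one specimen, optionally enriched with bed-level proxies."""

    specimen_id: str
    taxon: str
    stage: Stage
    bed: str
    subzone: str
    lithology: Lithology
    measurements: dict[str, float] = field(default_factory=dict)
    proxies: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.subzone not in SUBZONE_ORDER:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: unknown subzone {self.subzone!r}"
            )
        self.stage = Stage(self.stage)
        self.lithology = Lithology(self.lithology)


PROXY_COLUMNS = ("d18O", "d13C", "d11B")


class ProxyTable:
    """Bed-level stable-isotope proxies: d18O (temperature), d13C (carbon
    cycle), d11B (seawater pH), one row per sampled bed, values in permil."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in PROXY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"proxy table missing columns: {missing}")
        vals = frame[list(PROXY_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("proxy table contains non-finite values")
        if frame.index.has_duplicates:
            raise ValidationError("proxy table has duplicate bed rows")
        self.frame = frame[list(PROXY_COLUMNS)].astype(float)

    @property
    def beds(self) -> list[str]:
        return list(self.frame.index)

    def lookup(self, bed: str) -> dict[str, float]:
        row = self.frame.loc[bed]
        return {c: float(row[c]) for c in PROXY_COLUMNS}

    @classmethod
    def read_csv(cls, path: str | Path) -> "ProxyTable":
        return cls(pd.read_csv(path, index_col=0))

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="bed")


class OccurrenceTable:
    """Subzone x species occurrence counts with per-cell ontogenetic-stage
    breakdowns (adult | neanic | juvenile, or indeterminate)."""

    def __init__(
        self,
        totals: pd.DataFrame,
        stages: Mapping[tuple[str, str], dict[str, int]] | None = None,
    ):
        totals = totals.fillna(0).astype(int)
        if (totals.to_numpy() < 0).any():
            raise ValidationError("occurrence counts must be non-negative")
        self.totals = totals
        self.stages = dict(stages or {})
        for (subzone, species), breakdown in self.stages.items():
            cell = int(totals.at[subzone, species])
            known = sum(v for k, v in breakdown.items() if k != "indeterminate")
            if known > cell:
                raise ValidationError(
                    f"stage counts exceed cell total for {subzone}/{species}: "
                    f"{known} > {cell}"
                )
            if "indeterminate" not in breakdown and known != cell:
                raise ValidationError(
                    f"stage counts inconsistent for {subzone}/{species}: "
                    f"{known} != {cell}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.totals.columns)

    @property
    def subzones(self) -> list[str]:
        return list(self.totals.index)

    def grand_total(self) -> int:
        return int(self.totals.to_numpy().sum())

    def species_totals(self) -> pd.Series:
        return self.totals.sum(axis=0)

    def subzone_totals(self) -> pd.Series:
        return self.totals.sum(axis=1)

    def relative_abundances(self) -> pd.DataFrame:
        """Per-subzone relative abundance of each species (rows sum to 1;
        empty subzones yield all-NaN rows)."""
        row_sums = self.totals.sum(axis=1)
        return self.totals.div(row_sums.replace(0, np.nan), axis=0)


def _parse_cell(text: str, subzone: str, species: str) -> tuple[int, dict[str, int]]:
    """Parse an occurrence cell like ``17 (2|10|5)`` or ``3 (indet.)``."""
    text = text.strip()
    if not text or text in {"-", "–", "—"}:
        return 0, {}
    if "(" in text:
        total_part, _, rest = text.partition("(")
        detail = rest.rstrip(")").strip()
    else:
        total_part, detail = text, ""
    try:
        total = int(total_part.strip())
    except ValueError as exc:
        raise ParseError(
            f"cannot parse occurrence cell {text!r} at {subzone}/{species}"
        ) from exc
    if not detail:
        return total, {}
    if detail.startswith("indet"):
        return total, {"indeterminate": total}
    parts = detail.split("|")
    if len(parts) != 3:
        raise ParseError(
            f"stage breakdown {detail!r} at {subzone}/{species} must be a|n|j"
        )
    adult, neanic, juvenile = (int(p.strip()) for p in parts)
    return total, {"adult": adult, "neanic": neanic, "juvenile": juvenile}


def read_occurrence_table(path: str | Path) -> OccurrenceTable:
    """Read a subzone x species occurrence CSV with ``total (a|n|j)`` cells."""
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    totals = pd.DataFrame(0, index=raw.index, columns=raw.columns, dtype=int)
    stages: dict[tuple[str, str], dict[str, int]] = {}
    for subzone in raw.index:
        for species in raw.columns:
            total, breakdown = _parse_cell(str(raw.at[subzone, species]), subzone, species)
            totals.at[subzone, species] = total
            if breakdown:
                stages[(subzone, species)] = breakdown
    return OccurrenceTable(totals, stages)


def load_table1() -> OccurrenceTable:
    """The packaged transcription of the Peniche belemnite occurrence table
    (five ammonite subzones, seven species plus indeterminate Hastitidae;
    144 specimens in total)."""
    ref = resources.files("rostrumorph.data") / "peniche_occurrences.csv"
    with resources.as_file(ref) as path:
        return read_occurrence_table(path)


# ---------------------------------------------------------------------------
# landmark file readers / writers

def read_landmarks(path: str | Path, format: str | None = None) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS, CSV or JSON file.

    ``format`` defaults to the file suffix. One configuration per specimen;
    landmark count is validated and specimen ids must be unique.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "tps":
        configs = _read_tps(path)
    elif fmt == "csv":
        configs = _read_landmark_csv(path)
    elif fmt == "json":
        configs = _read_landmark_json(path)
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")
    ids = [c.specimen_id for c in configs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate specimen ids: {dupes}")
    return configs


def write_landmarks(
    configs: Sequence[LandmarkConfiguration], path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "tps":
        _write_tps(configs, path)
    elif fmt == "csv":
        _write_landmark_csv(configs, path)
    elif fmt == "json":
        _write_landmark_json(configs, path)
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")


def _read_tps(path: Path) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    points: list[list[float]] | None = None
    expected = 0
    spec_id: str | None = None
    anon = 0

    def flush(lineno: int) -> None:
        nonlocal points, spec_id, anon
        if points is None:
            return
        if len(points) != expected:
            raise ParseError(
                f"{path}:{lineno}: record declares LM3={expected} but has "
                f"{len(points)} points"
            )
        if spec_id is None:
            anon += 1
            spec_id = f"specimen_{anon}"
        configs.append(LandmarkConfiguration(spec_id, np.array(points)))
        points, spec_id = None, None

    lineno = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush(lineno)
                try:
                    expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad LM3 line {line!r}") from exc
                points = []
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                continue  # other TPS keywords (IMAGE=, SCALE=) are ignored
            else:
                if points is None:
                    raise ParseError(f"{path}:{lineno}: coordinates before LM3 header")
                vals = line.split()
                if len(vals) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 coordinates")
                points.append([float(v) for v in vals])
    flush(lineno)
    return configs


def _write_tps(configs: Sequence[LandmarkConfiguration], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cfg in configs:
            fh.write(f"LM3={N_LANDMARKS}\n")
            for x, y, z in cfg.coordinates:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


def _read_landmark_csv(path: Path) -> list[LandmarkConfiguration]:
    order: list[str] = []
    rows: dict[str, list[tuple[int, float, float, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        needed = {"specimen_id", "landmark", "x", "y", "z"}
        if reader.fieldnames is None or not needed.issubset(reader.fieldnames):
            raise ParseError(f"{path}: landmark CSV must have columns {sorted(needed)}")
        for rec_no, rec in enumerate(reader, start=2):
            try:
                sid = rec["specimen_id"]
                entry = (int(rec["landmark"]), float(rec["x"]), float(rec["y"]), float(rec["z"]))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: malformed record at line {rec_no}") from exc
            if sid not in rows:
                order.append(sid)
                rows[sid] = []
            rows[sid].append(entry)
    configs = []
    for sid in order:
        entries = sorted(rows[sid])
        indices = [e[0] for e in entries]
        if indices != list(range(1, N_LANDMARKS + 1)):
            raise ValidationError(
                f"specimen {sid!r}: expected landmark indices 1-{N_LANDMARKS}, got {indices}"
            )
        coords = np.array([[e[1], e[2], e[3]] for e in entries])
        configs.append(LandmarkConfiguration(sid, coords))
    return configs


def _write_landmark_csv(configs: Sequence[LandmarkConfiguration], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "landmark", "x", "y", "z"])
        for cfg in configs:
            for i, (x, y, z) in enumerate(cfg.coordinates, start=1):
                writer.writerow([cfg.specimen_id, i, repr(float(x)), repr(float(y)), repr(float(z))])


def _read_landmark_json(path: Path) -> list[LandmarkConfiguration]:
    with open(path, encoding="utf-8") as fh:
        bundle = json.load(fh)
    configs = []
    for entry in bundle["specimens"]:
        ventral = tuple(i - 1 for i in entry.get("ventral", [i + 1 for i in DEFAULT_VENTRAL]))
        dorsal = tuple(i - 1 for i in entry.get("dorsal", [i + 1 for i in DEFAULT_DORSAL]))
        configs.append(
            LandmarkConfiguration(entry["id"], np.array(entry["coordinates"]), ventral, dorsal)
        )
    return configs


def _write_landmark_json(configs: Sequence[LandmarkConfiguration], path: Path) -> None:
    bundle = {
        "specimens": [
            {
                "id": cfg.specimen_id,
                "coordinates": cfg.coordinates.tolist(),
                "ventral": [i + 1 for i in cfg.ventral],
                "dorsal": [i + 1 for i in cfg.dorsal],
            }
            for cfg in configs
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=1)


# ---------------------------------------------------------------------------
# specimen metadata

def read_specimen_records(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen metadata CSV (specimen_id, taxon, stage, bed, subzone,
    lithology, plus optional ``m_*`` linear-measurement columns in mm)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in frame.iterrows():
        measurements = {
            c[2:]: float(row[c]) for c in frame.columns if c.startswith("m_") and row[c] != ""
        }
        records.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                taxon=row["taxon"],
                stage=Stage(row["stage"]),
                bed=row["bed"],
                subzone=row["subzone"],
                lithology=Lithology(row["lithology"]),
                measurements=measurements,
            )
        )
    return records


def write_specimen_records(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    keys = sorted({k for r in records for k in r.measurements})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["specimen_id", "taxon", "stage", "bed", "subzone", "lithology"]
            + [f"m_{k}" for k in keys]
        )
        for r in records:
            writer.writerow(
                [r.specimen_id, r.taxon, r.stage.value, r.bed, r.subzone, r.lithology.value]
                + [repr(float(r.measurements[k])) if k in r.measurements else "" for k in keys]
            )


def assign_proxies(
    specimens: Iterable[SpecimenRecord], proxies: ProxyTable
) -> list[SpecimenRecord]:
    """Attach each specimen's bed-level d18O/d13C/d11B values.

    Returns new records in input order; never drops or duplicates specimens.
    Raises :class:`ValidationError` listing specimens whose bed is absent
    from the proxy table.
    """
    specimens = list(specimens)
    known = set(proxies.beds)
    missing = [s.specimen_id for s in specimens if s.bed not in known]
    if missing:
        raise ValidationError(f"beds unresolvable in proxy table for specimens: {missing}")
    return [replace(s, proxies=proxies.lookup(s.bed)) for s in specimens]
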