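"""Domain model for ETDRS-grid retinal layer thickness cohorts.

The macular thickness map is reported on the 9-sector ETDRS grid (a central
subfield, four inner-ring sectors at 1-3 mm from the fovea, four outer-ring
sectors at 3-6 mm) for each of 7 segmented retinal layers, giving 63
(layer, sector) measurements per eye.  A cohort table holds one row per eye
with the subject id, laterality, group label (healthy control ``HC`` or
diabetic-without-retinopathy ``DWOR``), age in years and the 63 thicknesses
in micrometres.  Eyes, not subjects, are the sampling unit; an optional
per-subject averaging mode is provided for sensitivity analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A cell value violates the cohort contract (range, label, type)."""


class ConfigError(ValueError):
    """A configuration mapping references unknown layers or sectors."""


class Ring(str, enum.Enum):
    CENTRAL = "central"
    INNER = "inner"
    OUTER = "outer"


class Sector(str, enum.Enum):
    """The nine ETDRS macular sectors."""

    C = "C"    # central subfield
    IS = "IS"  # inner superior
    II = "II"  # inner inferior
    IN = "IN"  # inner nasal
    IT = "IT"  # inner temporal
    OS = "OS"  # outer superior
    OI = "OI"  # outer inferior
    ON = "ON"  # outer nasal
    OT = "OT"  # outer temporal

    @property
    def ring(self) -> Ring:
        if self is Sector.C:
            return Ring.CENTRAL
        return Ring.INNER if self.value.startswith("I") else Ring.OUTER


class Layer(str, enum.Enum):
    """Retinal layers: seven segmented primaries plus three composites.

    Only the primary layers are network nodes; the composites (inner retina,
    outer retina, total retinal thickness) are derived sums used in the
    thickness and age-trajectory statistics.
    """

    RNFL = "RNFL"
    GCL = "GCL"
    IPL = "IPL"
    INL = "INL"
    OPL = "OPL"
    ONL = "ONL"
    RPE = "RPE"
    IR = "IR"
    OR = "OR"
    TRT = "TRT"

    @property
    def is_composite(self) -> bool:
        return self in (Layer.IR, Layer.OR, Layer.TRT)


class Eye(str, enum.Enum):
    OD = "OD"
    OS = "OS"


class Group(str, enum.Enum):
    HC = "HC"
    DWOR = "DWOR"


PRIMARY_LAYERS: tuple[Layer, ...] = (
    Layer.RNFL, Layer.GCL, Layer.IPL, Layer.INL, Layer.OPL, Layer.ONL, Layer.RPE,
)
SECTORS: tuple[Sector, ...] = tuple(Sector)
INNER_SECTORS: tuple[Sector, ...] = (Sector.IS, Sector.II, Sector.IN, Sector.IT)
OUTER_SECTORS: tuple[Sector, ...] = (Sector.OS, Sector.OI, Sector.ON, Sector.OT)

#: Network node order: layer-major over the 7 primaries, then the 9 sectors.
NODES: tuple[tuple[Layer, Sector], ...] = tuple(
    (layer, sector) for layer in PRIMARY_LAYERS for sector in SECTORS
)
N_NODES = len(NODES)  # 63


def node_label(layer: Layer, sector: Sector) -> str:
    return f"{layer.value}_{sector.value}"


NODE_LABELS: tuple[str, ...] = tuple(node_label(l, s) for l, s in NODES)

#: Default composite scheme.  The source tables report IR/OR/TRT composites
#: without stating their anatomical boundaries, so the mapping is an explicit,
#: configurable choice: inner retina = RNFL..INL, outer retina = OPL..RPE.
DEFAULT_COMPOSITE_SCHEME: dict[Layer, tuple[Layer, ...]] = {
    Layer.IR: (Layer.RNFL, Layer.GCL, Layer.IPL, Layer.INL),
    Layer.OR: (Layer.OPL, Layer.ONL, Layer.RPE),
    Layer.TRT: PRIMARY_LAYERS,
}

META_COLUMNS = ("subject_id", "eye", "group", "age")


@dataclass
class EyeRecord:
    """One eye's demographic fields and 7x9 thickness grid (micrometres)."""

    subject_id: str
    eye: Eye
    group: Group
    age: float
    thickness: dict[tuple[Layer, Sector], float] = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValidationError(f"age must be a positive finite number, got {self.age}")
        for node in NODES:
            if node not in self.thickness:
                raise ValidationError(f"missing thickness cell {node_label(*node)}")
            v = self.thickness[node]
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"thickness {node_label(*node)} must be positive and finite, got {v}"
                )

    def values(self) -> np.ndarray:
        """Thicknesses in canonical node order (length 63)."""
        return np.array([self.thickness[n] for n in NODES], dtype=float)


@dataclass
class CohortTable:
    """Ordered collection of eye records; the pipeline's sole input."""

    records: list[EyeRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if not isinstance(rec.group, Group):
                raise ValidationError(f"unknown group label {rec.group!r}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, group: Group) -> "CohortTable":
        return CohortTable([r for r in self.records if r.group is group])

    def ages(self, group: Group | None = None) -> np.ndarray:
        recs = self.records if group is None else self.subset(group).records
        return np.array([r.age for r in recs], dtype=float)

    def matrix(self, group: Group | None = None) -> np.ndarray:
        """(n_eyes, 63) thickness matrix in canonical node order."""
        recs = self.records if group is None else self.subset(group).records
        return np.array([r.values() for r in recs], dtype=float)

    def require_min_group_size(self, n_min: int = 4) -> None:
        for g in Group:
            n = len(self.subset(g))
            if 0 < n < n_min:
                raise ValidationError(
                    f"group {g.value} has {n} eyes; at least {n_min} required"
                )

    def average_by_subject(self) -> "CohortTable":
        """Collapse to one record per subject by averaging the subject's eyes.

        Mitigates inter-eye dependence when both eyes of a subject are
        enrolled.  Off by default everywhere; the eye-level table mirrors the
        study design.
        """
        out: list[EyeRecord] = []
        seen: dict[tuple[str, str], list[EyeRecord]] = {}
        for rec in self.records:
            seen.setdefault((rec.subject_id, rec.group.value), []).append(rec)
        for (sid, grp), recs in seen.items():
            thick = {
                n: float(np.mean([r.thickness[n] for r in recs])) for n in NODES
            }
            out.append(
                EyeRecord(
                    subject_id=sid,
                    eye=recs[0].eye,
                    group=Group(grp),
                    age=float(np.mean([r.age for r in recs])),
                    thickness=thick,
                )
            )
        return CohortTable(out)


# ---------------------------------------------------------------------------
# Derived quantities


def ring_average(record: EyeRecord, layer: Layer, ring: Ring) -> float:
    """Mean thickness over the 4 sectors of the inner (1-3 mm) or outer
    (3-6 mm) ring for one layer.  The central subfield is a single sector and
    has no ring average."""
    if ring is Ring.CENTRAL:
        raise ValueError("central subfield is a single sector, not a ring average")
    sectors = INNER_SECTORS if ring is Ring.INNER else OUTER_SECTORS
    if layer.is_composite:
        return float(np.mean([composite_layer(record, layer, s) for s in sectors]))
    return float(np.mean([record.thickness[(layer, s)] for s in sectors]))


def composite_layer(
    record: EyeRecord,
    composite: Layer,
    sector: Sector,
    scheme: Mapping[Layer, Sequence[Layer]] | None = None,
) -> float:
    """Composite thickness (sum of a scheme's primary layers) in one sector."""
    scheme = DEFAULT_COMPOSITE_SCHEME if scheme is None else dict(scheme)
    if composite not in scheme:
        raise ConfigError(f"{composite.value} is not defined by the composite scheme")
    total = 0.0
    for layer in scheme[composite]:
        layer = Layer(layer)
        if layer.is_composite:
            raise ConfigError(
                f"composite scheme for {composite.value} references non-primary layer {layer.value}"
            )
        total += record.thickness[(layer, sector)]
    return float(total)


def region_value(
    record: EyeRecord,
    layer: Layer,
    region: str,
    scheme: Mapping[Layer, Sequence[Layer]] | None = None,
) -> float:
    """Thickness of ``layer`` in a named region: a sector code, ``Avg_I`` or
    ``Avg_O``.  Handles composite layers through the scheme."""
    if region == "Avg_I":
        if layer.is_composite:
            return float(
                np.mean([composite_layer(record, layer, s, scheme) for s in INNER_SECTORS])
            )
        return ring_average(record, layer, Ring.INNER)
    if region == "Avg_O":
        if layer.is_composite:
            return float(
                np.mean([composite_layer(record, layer, s, scheme) for s in OUTER_SECTORS])
            )
        return ring_average(record, layer, Ring.OUTER)
    sector = Sector(region)
    if layer.is_composite:
        return composite_layer(record, layer, sector, scheme)
    return record.thickness[(layer, sector)]


# ---------------------------------------------------------------------------
# I/O (CSV/TSV, one row per eye, columns LAYER_SECTOR)


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def to_frame(table: CohortTable, derived: bool = False) -> pd.DataFrame:
    rows = []
    for rec in table.records:
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "eye": rec.eye.value,
            "group": rec.group.value,
            "age": rec.age,
        }
        for layer, sector in NODES:
            row[node_label(layer, sector)] = rec.thickness[(layer, sector)]
        if derived:
            for layer in PRIMARY_LAYERS:
                row[f"{layer.value}_AVG_I"] = ring_average(rec, layer, Ring.INNER)
                row[f"{layer.value}_AVG_O"] = ring_average(rec, layer, Ring.OUTER)
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(
    table: CohortTable, path: str | Path, sep: str | None = None, derived: bool = False
) -> None:
    path = Path(path)
    to_frame(table, derived=derived).to_csv(path, sep=_sep_for(path, sep), index=False)


def load_cohort(
    path: str | Path,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> CohortTable:
    """Read a cohort table, validating schema and cell values.

    ``column_map`` renames foreign headers to the canonical dialect
    (``{"their_name": "RNFL_IS", ...}``) before validation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    for label in NODE_LABELS:
        if label not in df.columns:
            raise SchemaError(f"missing required column {label!r}")
    records: list[EyeRecord] = []
    for idx, row in df.iterrows():
        try:
            group = Group(str(row["group"]))
        except ValueError:
            raise ValidationError(
                f"row {idx}: unknown group label {row['group']!r}"
            ) from None
        try:
            eye = Eye(str(row["eye"]))
        except ValueError:
            raise ValidationError(f"row {idx}: unknown eye label {row['eye']!r}") from None
        thickness: dict[tuple[Layer, Sector], float] = {}
        for node, label in zip(NODES, NODE_LABELS):
            raw = row[label]
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {idx}: non-numeric thickness in {label}: {raw!r}"
                ) from None
            thickness[node] = v
        try:
            age = float(row["age"])
            rec = EyeRecord(str(row["subject_id"]), eye, group, age, thickness)
        except (TypeError, ValidationError, ValueError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
        records.append(rec)
    return CohortTable(records)


def records_from_arrays(
    subject_ids: Iterable[str],
    eyes: Iterable[Eye],
    groups: Iterable[Group],
    ages: Iterable[float],
    values: np.ndarray,
) -> CohortTable:
    """Assemble a cohort from parallel arrays; ``values`` is (n_eyes, 63) in
    canonical node order."""
    values = np.asarray(values, dtype=float)
    records = []
    for sid, eye, grp, age, row in zip(subject_ids, eyes, groups, ages, values):
        records.append(
            EyeRecord(sid, eye, grp, float(age), dict(zip(NODES, row.tolist())))
        )
    return CohortTable(records)
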