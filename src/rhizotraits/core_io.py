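"""Data model and tabular I/O for the trait-profiling pipeline.

All on-disk tables are UTF-8, tab-separated, single header row, ``.``
decimal.  Blank (negative-control) wells share the plate-reading schema and
are identified by the literal isolate id ``BLANK``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("rhizotraits")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class RhizotraitsError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(RhizotraitsError):
    """A value in an input table violates the column's domain."""


class IntegrityError(RhizotraitsError):
    """Cross-record consistency violated (duplicates, dangling references)."""


class InsufficientDataError(RhizotraitsError):
    """Too few observations for the requested computation."""


class DegenerateDesignError(RhizotraitsError):
    """Design matrix carries no usable variation."""


class NoGrowthError(RhizotraitsError):
    """LB reference growth below the no-growth threshold."""


class ConfigError(RhizotraitsError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# Enumerations and design constants
# ---------------------------------------------------------------------------

STAGES: tuple[int, ...] = (5, 15, 35, 65, 105)

BLANK_ID = "BLANK"


class PlantSpecies(str, Enum):
    A_MARITIMA = "A_maritima"
    L_VULGARE = "L_vulgare"


class Compartment(str, Enum):
    RHIZOSPHERE = "rhizosphere"
    ENDOSPHERE = "endosphere"


class AssayCategory(str, Enum):
    PGP = "pgp"
    FITNESS_ABIOTIC = "fitness_abiotic"
    FITNESS_BIOTIC = "fitness_biotic"
    METABOLIC = "metabolic"
    GROWTH_REFERENCE = "growth_reference"


class BlankPolicy(str, Enum):
    SUBTRACT = "subtract_negative_control"
    NONE = "none"


class NormalizationPolicy(str, Enum):
    BY_LB_GROWTH = "by_lb_growth"
    SUPERNATANT_ONLY = "supernatant_only"


class MatrixState(str, Enum):
    RAW = "raw"
    BLANK_CORRECTED = "blank_corrected"
    NORMALIZED = "normalized"
    WEIGHTED = "weighted"
    STANDARDIZED = "standardized"


#: The 14 single-carbon-source growth assays used for metabolic potential.
CARBON_SOURCES: tuple[str, ...] = (
    "alanine",
    "arabinose",
    "butyrolactam",
    "fructose",
    "galactose",
    "glucose",
    "glycerol",
    "glycine",
    "lactic_acid",
    "putrescine",
    "serine",
    "succinic_acid",
    "threonine",
    "valine",
)

# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsolateRecord:
    """One bacterial strain with its treatment membership and colony count."""

    isolate_id: str
    stage_years: int
    plant_species: PlantSpecies
    compartment: Compartment
    plot_id: str
    taxon_label: str
    colony_count: int

    def __post_init__(self) -> None:
        if self.stage_years not in STAGES:
            raise SchemaError(
                f"isolate {self.isolate_id!r}: stage_years {self.stage_years} "
                f"not in {STAGES}"
            )
        if self.colony_count < 1:
            raise SchemaError(
                f"isolate {self.isolate_id!r}: colony_count must be >= 1"
            )

    @property
    def treatment(self) -> tuple[int, str, str]:
        """(stage, plant, compartment) key; abundances are defined within it."""
        return (self.stage_years, self.plant_species.value, self.compartment.value)


@dataclass(frozen=True)
class AssayDefinition:
    assay_id: str
    category: AssayCategory
    wavelength_nm: int
    blank_policy: BlankPolicy
    normalization_policy: NormalizationPolicy


@dataclass(frozen=True)
class PlateReading:
    """One raw absorbance read; ``isolate_id`` may be the BLANK sentinel."""

    isolate_id: str
    assay_id: str
    replicate: int
    absorbance: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.absorbance) or self.absorbance < 0:
            raise SchemaError(
                f"reading ({self.isolate_id}, {self.assay_id}, rep "
                f"{self.replicate}): absorbance must be finite and >= 0, got "
                f"{self.absorbance}"
            )
        if self.replicate < 1:
            raise SchemaError("replicate index must be >= 1")


@dataclass(frozen=True)
class CfuRecord:
    stage_years: int
    plant_species: PlantSpecies
    compartment: Compartment
    plot_id: str
    cfu_per_g: float

    def __post_init__(self) -> None:
        if self.stage_years not in STAGES:
            raise SchemaError(f"cfu record: stage_years {self.stage_years} not in {STAGES}")
        if not np.isfinite(self.cfu_per_g) or self.cfu_per_g <= 0:
            raise SchemaError("cfu_per_g must be finite and > 0")


# ---------------------------------------------------------------------------
# Default assay panel
# ---------------------------------------------------------------------------


def default_assays() -> list[AssayDefinition]:
    """The study's assay panel.

    One LB stationary-phase growth reference (600 nm), four supernatant-based
    plant-growth-promotion assays, five whole-culture fitness assays and the
    14 carbon-source growth assays.
    """
    pgp = [
        ("siderophore", 630),
        ("iaa", 535),
        ("exoprotease", 440),
        ("biofilm", 590),
    ]
    abiotic = [("salinity", 600), ("oxidative", 600), ("osmotic", 600)]
    biotic = [("penicillin", 600), ("streptomycin", 600)]
    assays = [
        AssayDefinition(
            "lb_growth",
            AssayCategory.GROWTH_REFERENCE,
            600,
            BlankPolicy.SUBTRACT,
            NormalizationPolicy.SUPERNATANT_ONLY,
        )
    ]
    assays += [
        AssayDefinition(a, AssayCategory.PGP, wl, BlankPolicy.SUBTRACT,
                        NormalizationPolicy.SUPERNATANT_ONLY)
        for a, wl in pgp
    ]
    assays += [
        AssayDefinition(a, AssayCategory.FITNESS_ABIOTIC, wl, BlankPolicy.SUBTRACT,
                        NormalizationPolicy.BY_LB_GROWTH)
        for a, wl in abiotic
    ]
    assays += [
        AssayDefinition(a, AssayCategory.FITNESS_BIOTIC, wl, BlankPolicy.SUBTRACT,
                        NormalizationPolicy.BY_LB_GROWTH)
        for a, wl in biotic
    ]
    assays += [
        AssayDefinition(f"c_{src}", AssayCategory.METABOLIC, 600,
                        BlankPolicy.SUBTRACT, NormalizationPolicy.BY_LB_GROWTH)
        for src in CARBON_SOURCES
    ]
    return assays


def validate_assay_panel(assays: Sequence[AssayDefinition]) -> None:
    ids = [a.assay_id for a in assays]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate assay_id in assay panel")
    n_ref = sum(a.category is AssayCategory.GROWTH_REFERENCE for a in assays)
    if n_ref != 1:
        raise IntegrityError(
            f"assay panel must contain exactly one growth_reference assay, got {n_ref}"
        )


def growth_reference_assay(assays: Sequence[AssayDefinition]) -> AssayDefinition:
    for a in assays:
        if a.category is AssayCategory.GROWTH_REFERENCE:
            return a
    raise IntegrityError("no growth_reference assay in panel")


# ---------------------------------------------------------------------------
# TraitMatrix
# ---------------------------------------------------------------------------


@dataclass
class TraitMatrix:
    """Isolates x traits matrix with an explicit processing state.

    ``values`` is a pandas DataFrame indexed by isolate id with trait ids as
    columns.  ``provenance_log`` records every transformation in application
    order; ``write_matrix`` serializes it in a ``#`` header block so the
    round trip is lossless.
    """

    values: pd.DataFrame
    state: MatrixState
    provenance_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise IntegrityError("trait matrix contains missing cells")
        if self.state is not MatrixState.RAW and (self.values.values < 0).any():
            raise IntegrityError(
                f"trait matrix in state {self.state.value} has negative cells"
            )

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def evolve(self, values: pd.DataFrame, state: MatrixState, step: str) -> "TraitMatrix":
        """Return a new matrix with one more provenance entry."""
        return TraitMatrix(values, state, [*self.provenance_log, step])


def write_matrix(matrix: TraitMatrix, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# state: {matrix.state.value}"]
    lines += [f"# provenance: {step}" for step in matrix.provenance_log]
    body = matrix.values.to_csv(sep="\t", float_format="%.17g", index_label="isolate_id")
    try:
        path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")
    except OSError as exc:  # unwritable path
        raise RhizotraitsError(f"cannot write matrix to {path}: {exc}") from exc


def read_matrix(path: str | Path) -> TraitMatrix:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header: list[str] = []
    data_lines: list[str] = []
    for line in text.splitlines():
        (header if line.startswith("#") else data_lines).append(line)
    state: MatrixState | None = None
    provenance: list[str] = []
    for line in header:
        content = line.lstrip("#").strip()
        if content.startswith("state:"):
            state = MatrixState(content.split(":", 1)[1].strip())
        elif content.startswith("provenance:"):
            provenance.append(content.split(":", 1)[1].strip())
    if state is None:
        raise SchemaError(f"{path}: missing '# state:' header block")
    from io import StringIO

    frame = pd.read_csv(StringIO("\n".join(data_lines)), sep="\t", index_col="isolate_id")
    frame.index = frame.index.astype(str)
    return TraitMatrix(frame, state, provenance)


# ---------------------------------------------------------------------------
# Table readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise RhizotraitsError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return frame


def _parse_enum(enum_cls, raw: str, row: int, path, column: str):
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = [e.value for e in enum_cls]
        raise SchemaError(
            f"{path} row {row}: unknown {column} value {raw!r}; allowed {allowed}"
        ) from None


def read_isolates(path: str | Path) -> list[IsolateRecord]:
    frame = _read_table(
        path,
        ["isolate_id", "stage_years", "plant_species", "compartment",
         "plot_id", "taxon_label", "colony_count"],
    )
    records: list[IsolateRecord] = []
    seen: set[str] = set()
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        iso = str(rec.isolate_id)
        if iso in seen:
            raise IntegrityError(f"{path}: duplicate isolate_id {iso!r}")
        seen.add(iso)
        try:
            stage = int(rec.stage_years)
            count = int(rec.colony_count)
        except ValueError as exc:
            raise SchemaError(f"{path} row {row}: {exc}") from None
        records.append(
            IsolateRecord(
                isolate_id=iso,
                stage_years=stage,
                plant_species=_parse_enum(PlantSpecies, rec.plant_species, row, path,
                                          "plant_species"),
                compartment=_parse_enum(Compartment, rec.compartment, row, path,
                                        "compartment"),
                plot_id=str(rec.plot_id),
                taxon_label=str(rec.taxon_label),
                colony_count=count,
            )
        )
    return records


def read_assays(path: str | Path) -> list[AssayDefinition]:
    frame = _read_table(
        path, ["assay_id", "category", "wavelength_nm", "blank_policy",
               "normalization_policy"]
    )
    assays = [
        AssayDefinition(
            assay_id=str(rec.assay_id),
            category=_parse_enum(AssayCategory, rec.category, row, path, "category"),
            wavelength_nm=int(rec.wavelength_nm),
            blank_policy=_parse_enum(BlankPolicy, rec.blank_policy, row, path,
                                     "blank_policy"),
            normalization_policy=_parse_enum(
                NormalizationPolicy, rec.normalization_policy, row, path,
                "normalization_policy"),
        )
        for row, rec in enumerate(frame.itertuples(index=False), start=2)
    ]
    validate_assay_panel(assays)
    return assays


def read_plate_readings(
    path: str | Path, assays: Sequence[AssayDefinition]
) -> list[PlateReading]:
    frame = _read_table(path, ["isolate_id", "assay_id", "replicate", "absorbance"])
    known = {a.assay_id for a in assays}
    readings: list[PlateReading] = []
    seen: set[tuple[str, str, int]] = set()
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        assay = str(rec.assay_id)
        if assay not in known:
            raise IntegrityError(
                f"{path} row {row}: assay_id {assay!r} absent from assay table"
            )
        try:
            absorbance = float(rec.absorbance)
            replicate = int(rec.replicate)
        except ValueError as exc:
            raise SchemaError(f"{path} row {row}: {exc}") from None
        key = (str(rec.isolate_id), assay, replicate)
        if key in seen:
            raise IntegrityError(f"{path} row {row}: duplicate reading key {key}")
        seen.add(key)
        try:
            readings.append(PlateReading(str(rec.isolate_id), assay, replicate, absorbance))
        except SchemaError as exc:
            raise SchemaError(f"{path} row {row}: {exc}") from None
    return readings


def read_cfu(path: str | Path, detection_limit: float = 1.0) -> list[CfuRecord]:
    """Read the CFU table; zero counts become (detection limit)/2."""
    frame = _read_table(
        path, ["stage_years", "plant_species", "compartment", "plot_id", "cfu_per_g"]
    )
    records = []
    for row, rec in enumerate(frame.itertuples(index=False), start=2):
        cfu = float(rec.cfu_per_g)
        if cfu == 0:
            cfu = detection_limit / 2.0
        records.append(
            CfuRecord(
                stage_years=int(rec.stage_years),
                plant_species=_parse_enum(PlantSpecies, rec.plant_species, row, path,
                                          "plant_species"),
                compartment=_parse_enum(Compartment, rec.compartment, row, path,
                                        "compartment"),
                plot_id=str(rec.plot_id),
                cfu_per_g=cfu,
            )
        )
    return records


def read_standards(path: str | Path) -> pd.DataFrame:
    """Calibration standards: columns analyte, concentration, absorbance."""
    frame = _read_table(path, ["analyte", "concentration", "absorbance"])
    frame["concentration"] = frame["concentration"].astype(float)
    frame["absorbance"] = frame["absorbance"].astype(float)
    return frame


def isolates_to_frame(isolates: Iterable[IsolateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "isolate_id": i.isolate_id,
                "stage_years": i.stage_years,
                "plant_species": i.plant_species.value,
                "compartment": i.compartment.value,
                "plot_id": i.plot_id,
                "taxon_label": i.taxon_label,
                "colony_count": i.colony_count,
            }
            for i in isolates
        ]
    )


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def render(self) -> str:
        lines = ["validation report", "================="]
        lines.append(f"fatal items: {len(self.fatal)}")
        lines += [f"  FATAL: {item}" for item in self.fatal]
        lines.append(f"warnings: {len(self.warnings)}")
        lines += [f"  warn: {item}" for item in self.warnings]
        return "\n".join(lines) + "\n"


def validate_dataset(
    isolates: Sequence[IsolateRecord],
    readings: Sequence[PlateReading],
    assays: Sequence[AssayDefinition],
    cfu: Sequence[CfuRecord] | None = None,
) -> ValidationReport:
    """Check cross-table consistency; never raises, always returns a report."""
    report = ValidationReport()
    validate_assay_panel(assays)
    ref = growth_reference_assay(assays)

    by_isolate_assay: dict[str, set[str]] = {}
    blanks_by_assay: dict[str, int] = {}
    for r in readings:
        if r.isolate_id == BLANK_ID:
            blanks_by_assay[r.assay_id] = blanks_by_assay.get(r.assay_id, 0) + 1
        else:
            by_isolate_assay.setdefault(r.isolate_id, set()).add(r.assay_id)

    known_isolates = {i.isolate_id for i in isolates}
    for iso_id in sorted(by_isolate_assay):
        if iso_id not in known_isolates:
            report.fatal.append(f"plate readings reference unknown isolate {iso_id!r}")

    for iso in isolates:
        assay_set = by_isolate_assay.get(iso.isolate_id, set())
        if ref.assay_id not in assay_set:
            report.fatal.append(
                f"isolate {iso.isolate_id!r} lacks the growth reference read "
                f"({ref.assay_id})"
            )
        missing = sorted(
            a.assay_id for a in assays
            if a.category is not AssayCategory.GROWTH_REFERENCE
            and a.assay_id not in assay_set
        )
        if missing:
            report.fatal.append(
                f"isolate {iso.isolate_id!r} missing readings for assay(s) {missing}"
            )

    for a in assays:
        if a.blank_policy is BlankPolicy.SUBTRACT and not blanks_by_assay.get(a.assay_id):
            report.fatal.append(
                f"assay {a.assay_id!r} requires a negative control but has no "
                f"BLANK reading"
            )

    treatment_counts: dict[tuple, int] = {}
    for iso in isolates:
        treatment_counts[iso.treatment] = treatment_counts.get(iso.treatment, 0) + 1
    for key in sorted(treatment_counts):
        if treatment_counts[key] < 2:
            report.warnings.append(
                f"treatment {key} has a single isolate; its functional diversity "
                f"is undefined (reported as N.A.)"
            )
    if not isolates:
        report.fatal.append("no isolates in dataset")
    if cfu is not None and not cfu:
        report.warnings.append("CFU table is empty; CFU trend analysis will be skipped")
    return report


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Run-wide knobs; every CLI flag has a field here."""

    seed: int = 0
    detection_limit: float = 1.0
    no_growth_threshold: float = 0.05
    metabolic_standardization_scope: str = "per_isolate"  # or "global"
    diversity_input_state: str = "weighted"  # or "normalized"
    pca_log_offset: float = 1.0
    trend_degree: int = 2
    significance_level: float = 0.05
    reference_fe_mM: float = 0.015

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"synthetic"}
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**{k: v for k, v in raw.items() if k in known})


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
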