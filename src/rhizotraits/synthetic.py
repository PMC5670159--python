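"""Seeded synthetic datasets that emulate the chronosequence study design.

The generator reproduces the sampling layout — 5 successional stages (5, 15,
35, 65, 105 years) x 3 plots x 2 plant species x 2 root compartments, with
at most 32 morphotype colonies per treatment — and emits *raw plate
absorbances*, not trait values: every strain's true trait value is pushed
backwards through the normalization chain (multiplied by its LB growth OD,
blank offsets added, standard-curve forward transform applied) so that the
analysis pipeline's forward pass recovers the truth up to the configured
noise.  That inversion is what lets every pipeline stage be verified
end-to-end without the undeposited laboratory data.

Noise model: strain-level trait heterogeneity and plate measurement error
are both multiplicative lognormal (plate reads are nonnegative and their
error scales with signal).  Measurement noise sd defaults to 0.15; the
strain-level sd defaults to 0.45, which puts the quadratic stage trends at
coefficients of determination around 0.4, the upper end of the magnitudes
the screening data showed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    BLANK_ID,
    CARBON_SOURCES,
    STAGES,
    AssayCategory,
    AssayDefinition,
    Compartment,
    ConfigError,
    IsolateRecord,
    PlantSpecies,
    PlateReading,
    CfuRecord,
    default_assays,
)

# ---------------------------------------------------------------------------
# Trait and CFU models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitModel:
    """Quadratic stage-response of one trait on its natural measurement scale.

    mean(age) = baseline + linear*age + quadratic*age^2 (+ offsets); the
    scale is the *normalized* trait scale the pipeline recovers: an OD ratio
    for fitness and carbon-source growth, AU for supernatant dye assays,
    consumed FeCl3 (mM) for siderophore, uM for IAA.
    """

    baseline: float
    linear: float = 0.0
    quadratic: float = 0.0
    plant_offset: float = 0.0  # added for L. vulgare
    compartment_offset: float = 0.0  # added for endosphere
    floor: float = 0.02
    ceiling: float | None = None

    def mean(self, stage: int, plant: PlantSpecies, comp: Compartment) -> float:
        value = self.baseline + self.linear * stage + self.quadratic * stage**2
        if plant is PlantSpecies.L_VULGARE:
            value += self.plant_offset
        if comp is Compartment.ENDOSPHERE:
            value += self.compartment_offset
        value = max(self.floor, value)
        if self.ceiling is not None:
            value = min(self.ceiling, value)
        return value

    @property
    def vertex(self) -> float | None:
        if self.quadratic == 0:
            return None
        return -self.linear / (2.0 * self.quadratic)

    @property
    def curvature_sign(self) -> int:
        return int(np.sign(self.quadratic))

    def flattened(self) -> "TraitModel":
        return replace(self, linear=0.0, quadratic=0.0, plant_offset=0.0,
                       compartment_offset=0.0)


def hump(peak_age: float, peak_value: float, curvature: float, **kw) -> TraitModel:
    """Concave parabola with its maximum ``peak_value`` at ``peak_age``."""
    return TraitModel(
        baseline=peak_value - curvature * peak_age**2,
        linear=2.0 * curvature * peak_age,
        quadratic=-curvature,
        **kw,
    )


def u_shape(trough_age: float, trough_value: float, curvature: float, **kw) -> TraitModel:
    return TraitModel(
        baseline=trough_value + curvature * trough_age**2,
        linear=-2.0 * curvature * trough_age,
        quadratic=curvature,
        **kw,
    )


def default_trait_models() -> dict[str, TraitModel]:
    """Stage-response shapes mirroring the study's reported trends.

    Salinity resistance and siderophore production hump at the 35-year
    stage; penicillin and streptomycin resistance hump at 65 years; osmotic
    stress follows a shallow U; the remaining traits are stage-flat.
    """
    models: dict[str, TraitModel] = {
        "salinity": hump(35.0, 0.80, 1.8e-4, compartment_offset=-0.05),
        "oxidative": TraitModel(baseline=0.50),
        "osmotic": u_shape(65.0, 0.35, 6.0e-5, compartment_offset=0.05),
        "penicillin": hump(65.0, 0.70, 8.0e-5),
        "streptomycin": hump(65.0, 0.65, 7.0e-5),
        "siderophore": hump(35.0, 0.011, 1.5e-6, floor=0.0005, ceiling=0.0149),
        "iaa": TraitModel(baseline=15.0, linear=0.05, floor=1.0),
        "exoprotease": TraitModel(baseline=0.40),
        "biofilm": TraitModel(baseline=0.60),
    }
    # carbon sources: stage-flat, substrate-specific baselines spreading the
    # metabolic profiles so niche breadths vary between strains
    substrate_levels = [0.9, 0.3, 0.15, 0.85, 0.6, 0.95, 0.7, 0.25, 0.5,
                        0.2, 0.45, 0.65, 0.35, 0.4]
    for src, level in zip(CARBON_SOURCES, substrate_levels):
        models[f"c_{src}"] = TraitModel(baseline=level, floor=0.01)
    return models


@dataclass(frozen=True)
class CfuModel:
    """log10 CFU/g as a quadratic in stage age plus design offsets."""

    baseline: float = 6.8
    linear: float = -0.045
    quadratic: float = 5.0e-4
    plant_offset: float = 0.1
    compartment_offset: float = -0.8
    noise_sd: float = 0.15

    def mean_log10(self, stage: int, plant: PlantSpecies, comp: Compartment) -> float:
        value = self.baseline + self.linear * stage + self.quadratic * stage**2
        if plant is PlantSpecies.L_VULGARE:
            value += self.plant_offset
        if comp is Compartment.ENDOSPHERE:
            value += self.compartment_offset
        return value

    def flattened(self) -> "CfuModel":
        return replace(self, linear=0.0, quadratic=0.0, plant_offset=0.0,
                       compartment_offset=0.0)


@dataclass(frozen=True)
class StandardsModel:
    """Linear responses of the two calibration curves."""

    cas_slope: float = 30.0
    cas_intercept: float = 0.05
    cas_concentrations: tuple[float, ...] = (0.0, 0.005, 0.01, 0.015, 0.03)
    iaa_slope: float = 0.45  # per log10 molar unit
    iaa_intercept: float = 3.0
    iaa_concentrations: tuple[float, ...] = (1e-6, 10**-5.5, 1e-5, 10**-4.5, 1e-4)

    def cas_absorbance(self, conc_mM: float) -> float:
        return self.cas_intercept + self.cas_slope * conc_mM

    def iaa_absorbance(self, conc_M: float) -> float:
        return self.iaa_intercept + self.iaa_slope * np.log10(conc_M)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    stages: tuple[int, ...] = STAGES
    plots_per_stage: int = 3
    plants: tuple[PlantSpecies, ...] = (PlantSpecies.A_MARITIMA, PlantSpecies.L_VULGARE)
    compartments: tuple[Compartment, ...] = (Compartment.RHIZOSPHERE, Compartment.ENDOSPHERE)
    max_colonies_per_sample: int = 32
    min_colonies_per_sample: int = 16
    strains_per_treatment: tuple[int, int] = (3, 16)
    strain_plan: tuple[int, ...] | None = None  # explicit per-treatment counts
    trait_models: dict[str, TraitModel] = field(default_factory=default_trait_models)
    cfu_model: CfuModel = field(default_factory=CfuModel)
    standards: StandardsModel = field(default_factory=StandardsModel)
    lb_od_mean: float = 1.2
    lb_od_sd: float = 0.10  # lognormal sd of strain LB growth
    blank_od: float = 0.04  # negative-control OD600 for growth-based assays
    blank_dye: float = 0.05  # negative-control AU for dye-based PGP assays
    noise_sd: float = 0.15  # plate measurement noise (lognormal sd)
    strain_sd: float = 0.45  # strain-level trait heterogeneity (lognormal sd)
    stage_dispersion: dict[int, float] = field(default_factory=dict)
    dirichlet_alpha: float = 1.0
    replicates: int = 1
    blank_replicates: int = 3

    def validate(self) -> None:
        if not self.stages or any(s not in STAGES for s in self.stages):
            raise ConfigError(f"stages must be a nonempty subset of {STAGES}")
        if self.plots_per_stage < 1 or self.max_colonies_per_sample < 1:
            raise ConfigError("design counts must be positive")
        if self.noise_sd < 0 or self.strain_sd < 0 or self.lb_od_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        lo, hi = self.strains_per_treatment
        if lo < 1 or hi < lo:
            raise ConfigError("strains_per_treatment range invalid")
        n_treatments = len(self.stages) * len(self.plants) * len(self.compartments)
        if self.strain_plan is not None and len(self.strain_plan) != n_treatments:
            raise ConfigError(
                f"strain_plan length {len(self.strain_plan)} != number of "
                f"treatments {n_treatments}"
            )

    def noiseless(self) -> "SyntheticConfig":
        """Same design with zero measurement noise (strain values remain)."""
        return dataclasses.replace(self, noise_sd=0.0, lb_od_sd=0.0)

    def nulled(self) -> "SyntheticConfig":
        """All stage / plant / compartment effects removed."""
        return dataclasses.replace(
            self,
            trait_models={k: m.flattened() for k, m in self.trait_models.items()},
            cfu_model=self.cfu_model.flattened(),
            stage_dispersion={},
        )


_TAXA = (
    "Pseudomonas sp.", "Serratia sp.", "Erwinia sp.", "Stenotrophomonas sp.",
    "Microbacterium sp.", "Bacillus sp.", "Flavobacterium sp.", "Rahnella sp.",
)


# ---------------------------------------------------------------------------
# Study container
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Pre-noise strain trait values plus the generating trait shapes."""

    strain_values: pd.DataFrame  # isolate x trait, normalized scale
    trait_meta: pd.DataFrame  # trait_id, vertex, curvature_sign


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    seed: int
    isolates: list[IsolateRecord]
    plate_readings: list[PlateReading]
    assays: list[AssayDefinition]
    standards: pd.DataFrame
    cfu: list[CfuRecord]
    ground_truth: GroundTruth

    def isolates_frame(self) -> pd.DataFrame:
        from .core_io import isolates_to_frame

        return isolates_to_frame(self.isolates)

    def plates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isolate_id": [r.isolate_id for r in self.plate_readings],
                "assay_id": [r.assay_id for r in self.plate_readings],
                "replicate": [r.replicate for r in self.plate_readings],
                "absorbance": [r.absorbance for r in self.plate_readings],
            }
        )

    def assays_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assay_id": [a.assay_id for a in self.assays],
                "category": [a.category.value for a in self.assays],
                "wavelength_nm": [a.wavelength_nm for a in self.assays],
                "blank_policy": [a.blank_policy.value for a in self.assays],
                "normalization_policy": [a.normalization_policy.value for a in self.assays],
            }
        )

    def cfu_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage_years": [r.stage_years for r in self.cfu],
                "plant_species": [r.plant_species.value for r in self.cfu],
                "compartment": [r.compartment.value for r in self.cfu],
                "plot_id": [r.plot_id for r in self.cfu],
                "cfu_per_g": [r.cfu_per_g for r in self.cfu],
            }
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "isolates.tsv": self.isolates_frame(),
            "plates.tsv": self.plates_frame(),
            "assays.tsv": self.assays_frame(),
            "standards.tsv": self.standards,
            "cfu.tsv": self.cfu_frame(),
            "ground_truth.tsv": self.ground_truth.strain_values.reset_index(
                names="isolate_id"
            ),
            "ground_truth_traits.tsv": self.ground_truth.trait_meta,
        }
        for name, frame in tables.items():
            path = outdir / name
            frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
            paths[name] = path
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _default_panel_for_generator() -> list[AssayDefinition]:
    """Default panel with curve-calibrated assays exempt from blanking.

    The siderophore and IAA reads are interpreted through standard curves
    measured in the same reaction mixture, so their zero point is anchored
    by the curve itself rather than by a subtracted negative control.
    """
    from .core_io import BlankPolicy

    panel = []
    for a in default_assays():
        if a.assay_id in ("siderophore", "iaa"):
            a = dataclasses.replace(a, blank_policy=BlankPolicy.NONE)
        panel.append(a)
    return panel


def generate_study(config: SyntheticConfig, seed: int) -> SyntheticStudy:
    """Draw one complete dataset; identical (config, seed) -> identical data."""
    config.validate()
    rng = np.random.default_rng(seed)
    assays = _default_panel_for_generator()
    trait_ids = [a.assay_id for a in assays
                 if a.category is not AssayCategory.GROWTH_REFERENCE]
    missing_models = [t for t in trait_ids if t not in config.trait_models]
    if missing_models:
        raise ConfigError(f"no trait model for assay(s) {missing_models}")

    treatments = [
        (stage, plant, comp)
        for stage in config.stages
        for plant in config.plants
        for comp in config.compartments
    ]
    if config.strain_plan is not None:
        counts = list(config.strain_plan)
    else:
        lo, hi = config.strains_per_treatment
        counts = [int(rng.integers(lo, hi + 1)) for _ in treatments]

    isolates: list[IsolateRecord] = []
    truth_rows: list[dict] = []
    lb_by_isolate: dict[str, float] = {}
    idx = 0
    for (stage, plant, comp), n_strains in zip(treatments, counts):
        # colony totals within the treatment sample, Dirichlet-multinomial
        total = int(
            rng.integers(
                max(n_strains, config.min_colonies_per_sample),
                config.max_colonies_per_sample + 1,
            )
        )
        weights = rng.dirichlet(np.full(n_strains, config.dirichlet_alpha))
        extra = rng.multinomial(total - n_strains, weights)
        colony_counts = 1 + extra
        disp = config.stage_dispersion.get(stage, 1.0)
        for j in range(n_strains):
            idx += 1
            iso_id = f"S{idx:03d}"
            isolates.append(
                IsolateRecord(
                    isolate_id=iso_id,
                    stage_years=stage,
                    plant_species=plant,
                    compartment=comp,
                    plot_id=f"p{int(rng.integers(1, config.plots_per_stage + 1))}",
                    taxon_label=f"{_TAXA[idx % len(_TAXA)]} {iso_id}",
                    colony_count=int(colony_counts[j]),
                )
            )
            lb = config.lb_od_mean * float(
                np.exp(rng.normal(0.0, config.lb_od_sd))
            ) if config.lb_od_sd > 0 else config.lb_od_mean
            lb_by_isolate[iso_id] = lb
            row = {"isolate_id": iso_id}
            for trait in trait_ids:
                model = config.trait_models[trait]
                mu = model.mean(stage, plant, comp)
                value = mu * float(np.exp(rng.normal(0.0, config.strain_sd * disp)))
                value = max(model.floor, value)
                if model.ceiling is not None:
                    value = min(model.ceiling, value)
                row[trait] = value
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows).set_index("isolate_id")

    # --- plate readings: push truth backwards through the chain -----------
    readings: list[PlateReading] = []
    std = config.standards

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, config.noise_sd))) if config.noise_sd > 0 else 1.0

    for iso in isolates:
        lb = lb_by_isolate[iso.isolate_id]
        for rep in range(1, config.replicates + 1):
            readings.append(
                PlateReading(iso.isolate_id, "lb_growth", rep,
                             max(0.0, lb * noise() + config.blank_od))
            )
        for a in assays:
            if a.category is AssayCategory.GROWTH_REFERENCE:
                continue
            value = float(truth.loc[iso.isolate_id, a.assay_id])
            for rep in range(1, config.replicates + 1):
                observed = value * noise()
                if a.assay_id == "siderophore":
                    consumed = min(observed, 0.015)
                    raw = std.cas_absorbance(0.015 - consumed)
                elif a.assay_id == "iaa":
                    raw = std.iaa_absorbance(max(observed, 1e-9) * 1e-6)
                elif a.category in (AssayCategory.FITNESS_ABIOTIC,
                                    AssayCategory.FITNESS_BIOTIC,
                                    AssayCategory.METABOLIC):
                    raw = observed * lb + config.blank_od
                else:  # supernatant dye assays (exoprotease, biofilm)
                    raw = observed + config.blank_dye
                readings.append(
                    PlateReading(iso.isolate_id, a.assay_id, rep, max(0.0, raw))
                )

    from .core_io import BlankPolicy

    for a in assays:
        if a.blank_policy is BlankPolicy.SUBTRACT:
            blank = (config.blank_od
                     if a.normalization_policy.value == "by_lb_growth"
                     or a.category is AssayCategory.GROWTH_REFERENCE
                     else config.blank_dye)
            for rep in range(1, config.blank_replicates + 1):
                readings.append(PlateReading(BLANK_ID, a.assay_id, rep, blank))

    # --- standards ---------------------------------------------------------
    standards = pd.DataFrame(
        [
            {"analyte": "fecl3_cas", "concentration": c,
             "absorbance": std.cas_absorbance(c)}
            for c in std.cas_concentrations
        ]
        + [
            {"analyte": "iaa", "concentration": c,
             "absorbance": std.iaa_absorbance(c)}
            for c in std.iaa_concentrations
        ]
    )

    # --- CFU ---------------------------------------------------------------
    cfu_records = []
    for stage in config.stages:
        for plot in range(1, config.plots_per_stage + 1):
            for plant in config.plants:
                for comp in config.compartments:
                    mu = config.cfu_model.mean_log10(stage, plant, comp)
                    eps = (rng.normal(0.0, config.cfu_model.noise_sd)
                           if config.cfu_model.noise_sd > 0 else 0.0)
                    cfu_records.append(
                        CfuRecord(stage, plant, comp, f"p{plot}",
                                  float(10.0 ** (mu + eps)))
                    )

    trait_meta = pd.DataFrame(
        [
            {
                "trait_id": t,
                "vertex": (config.trait_models[t].vertex
                           if config.trait_models[t].vertex is not None else np.nan),
                "curvature_sign": config.trait_models[t].curvature_sign,
            }
            for t in trait_ids
        ]
    )
    return SyntheticStudy(
        config=config,
        seed=seed,
        isolates=isolates,
        plate_readings=readings,
        assays=assays,
        standards=standards,
        cfu=cfu_records,
        ground_truth=GroundTruth(truth, trait_meta),
    )


def generate_null(config: SyntheticConfig, seed: int) -> SyntheticStudy:
    """Same machinery with every stage/plant/compartment effect set to zero."""
    return generate_study(config.nulled(), seed)


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

FIXTURES = ("tiny", "paper_like", "null", "hump35")


def fixture_config(name: str) -> SyntheticConfig:
    """Named study designs used across the test suite and CLI.

    tiny        8 isolates on a 2-stage sub-design; fast end-to-end smoke runs.
    paper_like  full 5x3x2x2 design with a fixed strain plan totalling 59
                strains, the study's screening scale.
    null        20 single-strain treatments with all effects zeroed;
                type-I-error calibration.
    hump35      paper-scale design whose salinity and siderophore traits
                peak at the 35-year stage (the generating truth for
                parameter-recovery checks).
    """
    if name == "tiny":
        return SyntheticConfig(
            stages=(5, 35),
            plots_per_stage=1,
            plants=(PlantSpecies.A_MARITIMA,),
            strain_plan=(2, 2, 2, 2),
        )
    if name == "paper_like":
        return SyntheticConfig(strain_plan=tuple([3] * 19 + [2]))  # 59 strains
    if name == "null":
        return SyntheticConfig(strain_plan=tuple([1] * 20)).nulled()
    if name == "hump35":
        return SyntheticConfig(strain_plan=tuple([6] * 20))
    raise ConfigError(f"unknown fixture {name!r}; registry: {FIXTURES}")


def make_fixture(name: str, seed: int = 0) -> SyntheticStudy:
    return generate_study(fixture_config(name), seed)
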