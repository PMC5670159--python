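"""Raw plate readings -> the normalized / weighted trait matrix.

The transformation chain applied by :func:`assemble_trait_matrix` runs, in
order:

1. blank correction       — mean negative-control absorbance subtracted per
                            assay, negatives clipped at 0;
2. calibration            — siderophore absorbance converted to consumed
                            FeCl3 (mM) and IAA absorbance to concentration
                            (uM) via the fitted standard curves;
3. growth normalization   — fitness and carbon-source reads divided by the
                            isolate's LB stationary-phase OD600 (supernatant
                            based PGP assays pass through unchanged);
4. metabolic standardization — each isolate's 14 carbon-source values scaled
                            by their maximum, summed into the niche breadth
                            (0..14);
5. abundance weighting    — PGP and fitness traits multiplied by the strain's
                            relative colony abundance within its treatment.

Weighting is deliberately last so that every "further weighted" value is a
rescaling of an already normalized trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, invert_curve, siderophore_consumed_fe
from .core_io import (
    BLANK_ID,
    AssayCategory,
    AssayDefinition,
    BlankPolicy,
    IntegrityError,
    IsolateRecord,
    MatrixState,
    NoGrowthError,
    NormalizationPolicy,
    PlateReading,
    RhizotraitsError,
    TraitMatrix,
    growth_reference_assay,
)

#: Trait categories weighted by relative strain abundance by default.
DEFAULT_WEIGHT_CATEGORIES = frozenset(
    {AssayCategory.PGP, AssayCategory.FITNESS_ABIOTIC, AssayCategory.FITNESS_BIOTIC}
)


# ---------------------------------------------------------------------------
# Abundance
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Relative colony abundance of each strain within its treatment."""

    frame: pd.DataFrame  # isolate_id, stage_years, plant_species, compartment, relative_abundance

    def abundance_of(self, isolate_id: str) -> float:
        sel = self.frame.loc[self.frame["isolate_id"] == isolate_id, "relative_abundance"]
        if sel.empty:
            raise IntegrityError(f"no abundance entry for isolate {isolate_id!r}")
        return float(sel.iloc[0])

    def as_series(self) -> pd.Series:
        return self.frame.set_index("isolate_id")["relative_abundance"]


def compute_relative_abundance(isolates: Sequence[IsolateRecord]) -> AbundanceTable:
    """abundance_i = colony_count_i / sum of counts in the same treatment."""
    rows = []
    by_treatment: dict[tuple, int] = {}
    for iso in isolates:
        by_treatment[iso.treatment] = by_treatment.get(iso.treatment, 0) + iso.colony_count
    for iso in isolates:
        rows.append(
            {
                "isolate_id": iso.isolate_id,
                "stage_years": iso.stage_years,
                "plant_species": iso.plant_species.value,
                "compartment": iso.compartment.value,
                "relative_abundance": iso.colony_count / by_treatment[iso.treatment],
            }
        )
    frame = pd.DataFrame(rows)
    # simplex check per treatment
    sums = frame.groupby(["stage_years", "plant_species", "compartment"])[
        "relative_abundance"
    ].sum()
    if not np.allclose(sums.values, 1.0, atol=1e-9):
        raise IntegrityError("relative abundances do not sum to 1 within a treatment")
    return AbundanceTable(frame)


# ---------------------------------------------------------------------------
# Step 1: replicate averaging + blank correction
# ---------------------------------------------------------------------------


def _replicate_means(readings: Sequence[PlateReading]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "isolate_id": [r.isolate_id for r in readings],
            "assay_id": [r.assay_id for r in readings],
            "absorbance": [r.absorbance for r in readings],
        }
    )
    return frame.groupby(["isolate_id", "assay_id"], sort=True)["absorbance"].mean()


def blank_correct(
    readings: Sequence[PlateReading], assays: Sequence[AssayDefinition]
) -> TraitMatrix:
    """Average replicates, subtract per-assay mean blanks, clip at zero."""
    means = _replicate_means(readings)
    wide = means.unstack("assay_id")
    blanks = wide.loc[BLANK_ID] if BLANK_ID in wide.index else pd.Series(dtype=float)
    samples = wide.drop(index=BLANK_ID, errors="ignore")
    assay_order = [a.assay_id for a in assays if a.assay_id in samples.columns]
    samples = samples[assay_order]
    if samples.isna().any().any():
        missing = samples.stack(future_stack=True)
        missing = missing[missing.isna()]
        raise IntegrityError(
            f"missing raw readings for isolate/assay pairs: "
            f"{list(missing.index[:5])}"
        )
    corrected = samples.copy()
    for a in assays:
        if a.assay_id not in corrected.columns:
            continue
        if a.blank_policy is BlankPolicy.SUBTRACT:
            if a.assay_id not in blanks.index or pd.isna(blanks[a.assay_id]):
                raise IntegrityError(
                    f"assay {a.assay_id!r} requires a blank but none present"
                )
            corrected[a.assay_id] = (corrected[a.assay_id] - blanks[a.assay_id]).clip(lower=0.0)
    return TraitMatrix(corrected, MatrixState.BLANK_CORRECTED, ["blank_correct"])


# ---------------------------------------------------------------------------
# Step 2: calibration conversion
# ---------------------------------------------------------------------------


def apply_calibration(
    matrix: TraitMatrix,
    curves: Mapping[str, CalibrationCurve],
    reference_fe_mM: float = 0.015,
) -> TraitMatrix:
    """Convert siderophore and IAA columns from absorbance to concentration.

    Siderophore becomes consumed FeCl3 in mM; IAA becomes concentration in
    uM (the standards span 1e-6 to 1e-4 M, i.e. 1-100 uM).  Negative
    inferred IAA concentrations cannot occur (log-scale inversion); consumed
    Fe is clipped to [0, reference].
    """
    values = matrix.values.copy()
    if "siderophore" in values.columns:
        if "fecl3_cas" not in curves:
            raise RhizotraitsError("siderophore column present but no fecl3_cas curve")
        cas = curves["fecl3_cas"]
        values["siderophore"] = [
            siderophore_consumed_fe(v, cas, reference_fe_mM)
            for v in values["siderophore"]
        ]
    if "iaa" in values.columns:
        if "iaa" not in curves:
            raise RhizotraitsError("iaa column present but no iaa curve")
        iaa = curves["iaa"]
        values["iaa"] = [invert_curve(iaa, v) * 1e6 for v in values["iaa"]]
    return matrix.evolve(values, MatrixState.BLANK_CORRECTED, "apply_calibration")


# ---------------------------------------------------------------------------
# Step 3: growth normalization
# ---------------------------------------------------------------------------


def growth_normalize(
    matrix: TraitMatrix,
    assays: Sequence[AssayDefinition],
    no_growth_threshold: float = 0.05,
) -> TraitMatrix:
    """Divide by-LB-growth assays by the isolate's LB OD600 reference.

    The growth-reference column is consumed here and dropped from the output
    matrix.  An isolate whose LB absorbance falls below the threshold never
    grew, so every ratio would blow up: that is an error, not a big trait.
    """
    ref = growth_reference_assay(assays)
    if ref.assay_id not in matrix.values.columns:
        raise IntegrityError(f"growth reference column {ref.assay_id!r} missing")
    lb = matrix.values[ref.assay_id]
    weak = lb[lb < no_growth_threshold]
    if not weak.empty:
        raise NoGrowthError(
            f"isolate(s) {list(weak.index)} have LB growth < {no_growth_threshold} AU"
        )
    values = matrix.values.drop(columns=[ref.assay_id])
    for a in assays:
        if (
            a.assay_id in values.columns
            and a.normalization_policy is NormalizationPolicy.BY_LB_GROWTH
        ):
            values[a.assay_id] = values[a.assay_id] / lb
    return matrix.evolve(values, MatrixState.NORMALIZED, "growth_normalize")


# ---------------------------------------------------------------------------
# Step 4: metabolic standardization + niche breadth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NicheBreadthResult:
    """Per-isolate metabolic versatility on the 0-14 scale."""

    isolate_id: str
    breadth: float
    standardized_profile: tuple[float, ...]


def standardize_metabolic(
    profiles: pd.DataFrame, scope: str = "per_isolate"
) -> list[NicheBreadthResult]:
    """Scale each 14-source growth profile by its maximum and sum it.

    ``scope='per_isolate'`` (default) uses each isolate's own maximum, so the
    breadth measures how evenly a strain grows across substrates relative to
    its best one; ``scope='global'`` uses the single maximum over the whole
    table.  An all-zero profile has breadth 0.
    """
    if (profiles.values < 0).any():
        raise RhizotraitsError("metabolic profiles must be nonnegative")
    if scope not in ("per_isolate", "global"):
        raise RhizotraitsError(f"unknown standardization scope {scope!r}")
    global_max = float(profiles.values.max()) if scope == "global" else None
    results = []
    for iso_id, row in profiles.iterrows():
        denom = global_max if scope == "global" else float(row.max())
        if denom is None or denom == 0:
            profile = tuple(0.0 for _ in row)
        else:
            profile = tuple(float(v) / denom for v in row)
        results.append(
            NicheBreadthResult(str(iso_id), float(sum(profile)), profile)
        )
    return results


def niche_breadth_frame(results: Sequence[NicheBreadthResult], columns) -> pd.DataFrame:
    frame = pd.DataFrame(
        [r.standardized_profile for r in results],
        index=[r.isolate_id for r in results],
        columns=list(columns),
    )
    frame["niche_breadth"] = [r.breadth for r in results]
    return frame


# ---------------------------------------------------------------------------
# Step 5: abundance weighting
# ---------------------------------------------------------------------------


def weight_by_abundance(
    matrix: TraitMatrix,
    abundance: AbundanceTable,
    assays: Sequence[AssayDefinition],
    categories: frozenset[AssayCategory] = DEFAULT_WEIGHT_CATEGORIES,
) -> TraitMatrix:
    """Multiply the selected trait categories by relative strain abundance."""
    weights = abundance.as_series()
    missing = [i for i in matrix.isolate_ids if i not in weights.index]
    if missing:
        raise IntegrityError(f"no abundance entry for isolate(s) {missing}")
    weights = weights.reindex(matrix.values.index)
    values = matrix.values.copy()
    weighted_cols = [
        a.assay_id
        for a in assays
        if a.assay_id in values.columns and a.category in categories
    ]
    values[weighted_cols] = values[weighted_cols].mul(weights, axis=0)
    return matrix.evolve(values, MatrixState.WEIGHTED, "weight_by_abundance")


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def assemble_trait_matrix(
    readings: Sequence[PlateReading],
    assays: Sequence[AssayDefinition],
    isolates: Sequence[IsolateRecord],
    curves: Mapping[str, CalibrationCurve],
    *,
    weight: bool = True,
    metabolic_scope: str = "per_isolate",
    no_growth_threshold: float = 0.05,
    reference_fe_mM: float = 0.015,
) -> TraitMatrix:
    """Run the five-step chain and return the final trait matrix.

    Metabolic columns are replaced by their max-standardized values and the
    niche breadth is appended as a derived trait.  With ``weight=False`` the
    chain stops after standardization (state ``normalized``), the variant
    used when an unweighted matrix should feed the diversity analysis.
    """
    matrix = blank_correct(readings, assays)
    matrix = apply_calibration(matrix, curves, reference_fe_mM)
    matrix = growth_normalize(matrix, assays, no_growth_threshold)

    metabolic_cols = [
        a.assay_id
        for a in assays
        if a.category is AssayCategory.METABOLIC and a.assay_id in matrix.values.columns
    ]
    if metabolic_cols:
        breadth = standardize_metabolic(matrix.values[metabolic_cols], metabolic_scope)
        std = niche_breadth_frame(breadth, metabolic_cols)
        values = matrix.values.copy()
        values[metabolic_cols] = std[metabolic_cols]
        values["niche_breadth"] = std["niche_breadth"]
        matrix = matrix.evolve(
            values, MatrixState.NORMALIZED, f"standardize_metabolic({metabolic_scope})"
        )

    # order rows by isolate table for stable output
    order = [i.isolate_id for i in isolates if i.isolate_id in matrix.values.index]
    matrix = TraitMatrix(matrix.values.loc[order], matrix.state, matrix.provenance_log)

    if weight:
        abundance = compute_relative_abundance(isolates)
        matrix = weight_by_abundance(matrix, abundance, assays)
    return matrix


def trait_category_columns(
    assays: Sequence[AssayDefinition], matrix: TraitMatrix
) -> dict[str, list[str]]:
    """Column groups used for the per-category diversity and cluster views."""
    by_cat: dict[str, list[str]] = {
        "total": [c for c in matrix.trait_ids if c != "niche_breadth"],
        "pgp": [],
        "abiotic": [],
        "antibiotic": [],
        "metabolic": [],
    }
    for a in assays:
        if a.assay_id not in matrix.values.columns:
            continue
        if a.category is AssayCategory.PGP:
            by_cat["pgp"].append(a.assay_id)
        elif a.category is AssayCategory.FITNESS_ABIOTIC:
            by_cat["abiotic"].append(a.assay_id)
        elif a.category is AssayCategory.FITNESS_BIOTIC:
            by_cat["antibiotic"].append(a.assay_id)
        elif a.category is AssayCategory.METABOLIC:
            by_cat["metabolic"].append(a.assay_id)
    return by_cat
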