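"""The five-step normalization chain and niche breadth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizotraits.calibration import fit_standard_curve
from rhizotraits.core_io import (
    AssayCategory,
    AssayDefinition,
    BlankPolicy,
    Compartment,
    IntegrityError,
    IsolateRecord,
    MatrixState,
    NoGrowthError,
    NormalizationPolicy,
    PlantSpecies,
    PlateReading,
    RhizotraitsError,
)
from rhizotraits.normalization import (
    assemble_trait_matrix,
    blank_correct,
    compute_relative_abundance,
    growth_normalize,
    standardize_metabolic,
    weight_by_abundance,
)


def _assay(assay_id, category, blank=BlankPolicy.SUBTRACT,
           policy=NormalizationPolicy.BY_LB_GROWTH):
    return AssayDefinition(assay_id, category, 600, blank, policy)


SMALL_PANEL = [
    _assay("lb_growth", AssayCategory.GROWTH_REFERENCE,
           policy=NormalizationPolicy.SUPERNATANT_ONLY),
    _assay("salinity", AssayCategory.FITNESS_ABIOTIC),
    _assay("siderophore", AssayCategory.PGP, blank=BlankPolicy.NONE,
           policy=NormalizationPolicy.SUPERNATANT_ONLY),
    _assay("c_glucose", AssayCategory.METABOLIC),
    _assay("c_alanine", AssayCategory.METABOLIC),
]


def _isolate(iso_id, count):
    return IsolateRecord(iso_id, 5, PlantSpecies.A_MARITIMA,
                         Compartment.RHIZOSPHERE, "p1", "x", count)


def small_dataset():
    """Two isolates whose chain output is computable by hand.

    A: LB OD 1.2, salinity ratio 0.6, consumed Fe 0.010 mM, glucose 0.8,
       alanine 0.4, 5 colonies.  B: LB OD 0.8, salinity 0.5, consumed 0,
       glucose 0.2, alanine 0.2, 15 colonies.  Blanks all 0.04; CAS curve
       absorbance = 0.05 + 30 * concentration.
    """
    curve = fit_standard_curve(
        [(c, 0.05 + 30.0 * c) for c in (0.0, 0.005, 0.01, 0.015, 0.03)], "fecl3_cas"
    )
    isolates = [_isolate("A", 5), _isolate("B", 15)]
    rows = {
        "A": {"lb_growth": 1.2 + 0.04, "salinity": 0.6 * 1.2 + 0.04,
              "siderophore": 0.05 + 30.0 * (0.015 - 0.010),
              "c_glucose": 0.8 * 1.2 + 0.04, "c_alanine": 0.4 * 1.2 + 0.04},
        "B": {"lb_growth": 0.8 + 0.04, "salinity": 0.5 * 0.8 + 0.04,
              "siderophore": 0.05 + 30.0 * 0.015,
              "c_glucose": 0.2 * 0.8 + 0.04, "c_alanine": 0.2 * 0.8 + 0.04},
        "BLANK": {"lb_growth": 0.04, "salinity": 0.04,
                  "c_glucose": 0.04, "c_alanine": 0.04},
    }
    readings = [
        PlateReading(iso, assay, 1, value)
        for iso, per_assay in rows.items()
        for assay, value in per_assay.items()
    ]
    return isolates, readings, {"fecl3_cas": curve}


class TestBlankCorrect:
    def test_mean_blank_subtracted(self):
        readings = [
            PlateReading("S1", "salinity", 1, 0.80),
            PlateReading("S1", "lb_growth", 1, 1.0),
            PlateReading("BLANK", "salinity", 1, 0.10),
            PlateReading("BLANK", "lb_growth", 1, 0.0),
        ]
        matrix = blank_correct(readings, SMALL_PANEL[:2])
        assert matrix.values.loc["S1", "salinity"] == pytest.approx(0.70)
        assert matrix.state is MatrixState.BLANK_CORRECTED

    def test_negative_corrected_value_clipped_to_zero(self):
        readings = [
            PlateReading("S1", "salinity", 1, 0.05),
            PlateReading("BLANK", "salinity", 1, 0.10),
        ]
        matrix = blank_correct(readings, [SMALL_PANEL[1]])
        assert matrix.values.loc["S1", "salinity"] == 0.0

    def test_no_blank_policy_leaves_values_unchanged(self):
        readings = [PlateReading("S1", "siderophore", 1, 0.42)]
        matrix = blank_correct(readings, [SMALL_PANEL[2]])
        assert matrix.values.loc["S1", "siderophore"] == 0.42

    def test_missing_required_blank_raises(self):
        readings = [PlateReading("S1", "salinity", 1, 0.5)]
        with pytest.raises(IntegrityError, match="blank"):
            blank_correct(readings, [SMALL_PANEL[1]])

    def test_replicates_are_averaged(self):
        readings = [
            PlateReading("S1", "salinity", 1, 0.6),
            PlateReading("S1", "salinity", 2, 0.8),
            PlateReading("BLANK", "salinity", 1, 0.1),
        ]
        matrix = blank_correct(readings, [SMALL_PANEL[1]])
        assert matrix.values.loc["S1", "salinity"] == pytest.approx(0.6)


class TestGrowthNormalize:
    def _matrix(self, lb, salinity, siderophore=0.2):
        frame = pd.DataFrame(
            {"lb_growth": [lb], "salinity": [salinity], "siderophore": [siderophore]},
            index=["S1"],
        )
        from rhizotraits.core_io import TraitMatrix

        return TraitMatrix(frame, MatrixState.BLANK_CORRECTED, [])

    def test_fitness_divided_by_lb_od(self):
        out = growth_normalize(self._matrix(1.2, 0.6), SMALL_PANEL[:3])
        assert out.values.loc["S1", "salinity"] == pytest.approx(0.5)
        assert "lb_growth" not in out.values.columns

    def test_supernatant_trait_passes_through(self):
        out = growth_normalize(self._matrix(1.2, 0.6, siderophore=0.31), SMALL_PANEL[:3])
        assert out.values.loc["S1", "siderophore"] == 0.31

    def test_no_growth_raises(self):
        with pytest.raises(NoGrowthError, match="S1"):
            growth_normalize(self._matrix(0.01, 0.6), SMALL_PANEL[:3])


class TestRelativeAbundance:
    def test_counts_become_fractions(self):
        table = compute_relative_abundance([_isolate("A", 5), _isolate("B", 15)])
        assert table.abundance_of("A") == pytest.approx(0.25)
        assert table.abundance_of("B") == pytest.approx(0.75)

    def test_single_strain_gets_one(self):
        assert compute_relative_abundance([_isolate("A", 7)]).abundance_of("A") == 1.0

    def test_equal_counts_share_equally(self):
        isolates = [_isolate(x, 1) for x in "ABCD"]
        table = compute_relative_abundance(isolates)
        for x in "ABCD":
            assert table.abundance_of(x) == pytest.approx(0.25)

    def test_sums_to_one_within_each_treatment(self, tiny_study):
        table = compute_relative_abundance(tiny_study.isolates)
        sums = table.frame.groupby(["stage_years", "plant_species", "compartment"])[
            "relative_abundance"
        ].sum()
        np.testing.assert_allclose(sums.values, 1.0, atol=1e-9)


class TestWeighting:
    def _matrix(self, values):
        from rhizotraits.core_io import TraitMatrix

        return TraitMatrix(pd.DataFrame(values), MatrixState.NORMALIZED, [])

    def test_selected_categories_scaled_by_abundance(self):
        isolates = [_isolate("A", 1), _isolate("B", 3)]
        matrix = self._matrix(
            {"salinity": pd.Series({"A": 0.8, "B": 0.8}),
             "c_glucose": pd.Series({"A": 0.6, "B": 0.6})}
        )
        out = weight_by_abundance(matrix, compute_relative_abundance(isolates),
                                  SMALL_PANEL)
        assert out.values.loc["A", "salinity"] == pytest.approx(0.2)
        # metabolic columns excluded under the default category set
        assert out.values.loc["A", "c_glucose"] == pytest.approx(0.6)
        assert out.state is MatrixState.WEIGHTED

    def test_abundance_one_is_identity(self):
        matrix = self._matrix({"salinity": pd.Series({"A": 0.8})})
        out = weight_by_abundance(matrix, compute_relative_abundance([_isolate("A", 9)]),
                                  SMALL_PANEL)
        assert out.values.loc["A", "salinity"] == pytest.approx(0.8)

    def test_missing_abundance_is_integrity_error(self):
        matrix = self._matrix({"salinity": pd.Series({"A": 0.8, "Z": 0.1})})
        with pytest.raises(IntegrityError, match="Z"):
            weight_by_abundance(matrix, compute_relative_abundance([_isolate("A", 1)]),
                                SMALL_PANEL)

    def test_weighting_preserves_within_treatment_rank_order(self):
        isolates = [_isolate(x, c) for x, c in [("A", 1), ("B", 2), ("C", 5)]]
        vals = pd.Series({"A": 0.1, "B": 0.5, "C": 0.9})
        matrix = self._matrix({"salinity": vals})
        out = weight_by_abundance(matrix, compute_relative_abundance(isolates),
                                  SMALL_PANEL)
        # counts increase with trait value here, so ranks must be preserved
        assert list(out.values["salinity"].sort_values().index) == ["A", "B", "C"]


class TestStandardizeMetabolic:
    def _frame(self, *rows):
        return pd.DataFrame(list(rows), index=[f"S{i}" for i in range(len(rows))])

    def test_uniform_profile_has_maximal_breadth(self):
        res = standardize_metabolic(self._frame([0.3] * 14))[0]
        assert res.breadth == pytest.approx(14.0)

    def test_single_substrate_profile_has_breadth_one(self):
        res = standardize_metabolic(self._frame([0.0] * 13 + [0.9]))[0]
        assert res.breadth == pytest.approx(1.0)

    def test_hand_computed_profile(self):
        res = standardize_metabolic(self._frame([0.2, 0.4, 0.8] + [0.0] * 11))[0]
        assert res.standardized_profile[:3] == pytest.approx((0.25, 0.5, 1.0))
        assert res.breadth == pytest.approx(1.75)

    def test_all_zero_profile_has_breadth_zero(self):
        res = standardize_metabolic(self._frame([0.0] * 14))[0]
        assert res.breadth == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(RhizotraitsError):
            standardize_metabolic(self._frame([-0.1] + [0.2] * 13))

    def test_global_scope_uses_table_maximum(self):
        frame = self._frame([0.2] * 14, [0.4] * 14)
        res = standardize_metabolic(frame, scope="global")
        assert res[0].breadth == pytest.approx(7.0)
        assert res[1].breadth == pytest.approx(14.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_breadth_is_scale_invariant(self, k):
        base = np.array([0.1, 0.5, 0.9, 0.2] + [0.3] * 10)
        r1 = standardize_metabolic(pd.DataFrame([base], index=["S"]))[0]
        r2 = standardize_metabolic(pd.DataFrame([base * k], index=["S"]))[0]
        assert r1.breadth == pytest.approx(r2.breadth, rel=1e-9)


class TestAssembleChain:
    def test_matches_hand_composed_transformation(self):
        isolates, readings, curves = small_dataset()
        matrix = assemble_trait_matrix(readings, SMALL_PANEL, isolates, curves)
        # hand-composed: blank -> calibrate -> /LB -> max-standardize -> weight
        expect = {
            "A": {"salinity": 0.6 * 0.25, "siderophore": 0.010 * 0.25,
                  "c_glucose": 1.0, "c_alanine": 0.5, "niche_breadth": 1.5},
            "B": {"salinity": 0.5 * 0.75, "siderophore": 0.0,
                  "c_glucose": 1.0, "c_alanine": 1.0, "niche_breadth": 2.0},
        }
        for iso, traits in expect.items():
            for trait, value in traits.items():
                assert matrix.values.loc[iso, trait] == pytest.approx(value, abs=1e-9), (
                    iso, trait)
        assert matrix.state is MatrixState.WEIGHTED
        assert matrix.provenance_log == [
            "blank_correct", "apply_calibration", "growth_normalize",
            "standardize_metabolic(per_isolate)", "weight_by_abundance",
        ]

    def test_identity_fixture_returns_calibrated_raw_values(self):
        # blanks 0, LB OD 1, single strain (abundance 1): output = raw ratios
        panel = [a for a in SMALL_PANEL if a.assay_id != "siderophore"]
        readings = [
            PlateReading("A", "lb_growth", 1, 1.0),
            PlateReading("A", "salinity", 1, 0.37),
            PlateReading("A", "c_glucose", 1, 0.5),
            PlateReading("A", "c_alanine", 1, 0.25),
            PlateReading("BLANK", "lb_growth", 1, 0.0),
            PlateReading("BLANK", "salinity", 1, 0.0),
            PlateReading("BLANK", "c_glucose", 1, 0.0),
            PlateReading("BLANK", "c_alanine", 1, 0.0),
        ]
        matrix = assemble_trait_matrix(readings, panel, [_isolate("A", 4)], {})
        assert matrix.values.loc["A", "salinity"] == pytest.approx(0.37, abs=1e-12)
        assert matrix.values.loc["A", "c_glucose"] == pytest.approx(1.0)

    def test_row_order_invariance(self):
        isolates, readings, curves = small_dataset()
        shuffled = list(reversed(readings))
        m1 = assemble_trait_matrix(readings, SMALL_PANEL, isolates, curves)
        m2 = assemble_trait_matrix(shuffled, SMALL_PANEL, isolates, curves)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_every_state_is_nonnegative(self, tiny_matrix):
        assert (tiny_matrix.values.values >= 0).all()

    def test_unweighted_variant_stops_at_normalized(self):
        isolates, readings, curves = small_dataset()
        matrix = assemble_trait_matrix(readings, SMALL_PANEL, isolates, curves,
                                       weight=False)
        assert matrix.state is MatrixState.NORMALIZED
        assert matrix.values.loc["A", "salinity"] == pytest.approx(0.6, abs=1e-9)
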