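"""Library enumeration, complexity counting and compiled derivatives."""

import numpy as np
import pytest

from rabswitch.errors import InvalidSlotError, MissingParameterError
from rabswitch.model_space import (
    ROOT_PARAMS,
    SLOTS,
    KineticForm,
    ModelStructure,
    compile_rhs,
    complexity,
    enumerate_structures,
)


class TestEnumeration:
    def test_full_product_has_126_unique_members(self, all_structures):
        assert len(all_structures) == 126
        assert len({s.choices for s in all_structures}) == 126

    @pytest.mark.parametrize(
        "constraints, expected",
        [
            ({"gap7": [0]}, 63),
            ({"gef5": [0], "gap5": [1], "gef7": [2], "gap7": [1]}, 1),
            ({"gef7": [0, 3, 6]}, 3 * 3 * 3 * 2),
        ],
    )
    def test_constrained_product_counts(self, library, constraints, expected):
        structures = enumerate_structures(constraints, library=library)
        assert len(structures) == expected

    def test_count_is_product_of_slot_choices(self, library, rng):
        sizes = {s: library.n_alternatives(s) for s in SLOTS}
        for _ in range(10):
            constraints = {
                s: list(rng.choice(sizes[s], size=rng.integers(1, sizes[s] + 1), replace=False))
                for s in SLOTS
            }
            expected = int(np.prod([len(v) for v in constraints.values()]))
            assert len(enumerate_structures(constraints, library=library)) == expected

    def test_canonical_order_is_lexicographic(self, all_structures):
        choices = [s.choices for s in all_structures]
        assert choices == sorted(choices)
        assert [s.index for s in all_structures] == list(range(126))

    def test_invalid_slot_index_names_the_slot(self, library):
        with pytest.raises(InvalidSlotError, match="gap7"):
            enumerate_structures({"gap7": [5]}, library=library)
        with pytest.raises(InvalidSlotError):
            ModelStructure(gef5=3, gap5=0, gef7=0, gap7=0, library=library)


class TestComplexity:
    def test_counts_gdi_processes_plus_kinetic_components(self, library):
        # intrinsic GAP5 and GAP7, single-component GEF5 and GEF7
        simple = ModelStructure(gef5=0, gap5=0, gef7=0, gap7=0, library=library)
        assert complexity(simple) == 8
        # GEF7 alternative with both auto and cross components adds one
        two_part = ModelStructure(gef5=0, gap5=0, gef7=1, gap7=0, library=library)
        assert complexity(two_part) == 9

    def test_independent_of_which_single_component_form(self, library):
        a = ModelStructure(gef5=0, gap5=1, gef7=3, gap7=1, library=library)
        b = ModelStructure(gef5=2, gap5=1, gef7=3, gap7=1, library=library)
        assert complexity(a) == complexity(b)

    def test_library_spans_counts_8_and_9(self, all_structures):
        counts = {complexity(s) for s in all_structures}
        assert counts == {8, 9}


class TestKineticForms:
    @pytest.mark.parametrize(
        "kind, expected_at_zero",
        [
            ("michaelis_menten", 0.0),
            ("sigmoidal", 0.0),
            ("linear", 0.0),
            ("intrinsic", 0.7),
            ("exchange_inhibition", 0.7),
        ],
    )
    def test_value_at_zero_regulator(self, kind, expected_at_zero):
        km = None if kind in ("intrinsic", "linear") else (1e-3, 4.0)
        reg = "none" if kind == "intrinsic" else "R5"
        form = KineticForm(kind=kind, regulator=reg, rate_bounds=(1e-3, 4.0), km_bounds=km)
        assert form.rate(0.0, 0.7, 0.5 if km else None) == pytest.approx(expected_at_zero)

    def test_sigmoidal_needs_hill_at_least_one(self):
        with pytest.raises(ValueError):
            KineticForm(
                kind="sigmoidal", regulator="R5", rate_bounds=(0, 1), km_bounds=(0, 1), hill=0.5
            )

    def test_intrinsic_rejects_km(self):
        with pytest.raises(ValueError):
            KineticForm(kind="intrinsic", regulator="none", rate_bounds=(0, 1), km_bounds=(0, 1))


class TestCompiledRHS:
    def test_zero_rates_give_zero_derivatives(self, library, rng):
        s = ModelStructure(gef5=0, gap5=1, gef7=4, gap7=1, library=library)
        rhs = compile_rhs(s)
        params = {name: 0.0 for name in rhs.param_names}
        params.update({"K": 1.0, "td": 5.0})  # observation-only parameters
        for _ in range(5):
            state = rng.uniform(0, 2, size=4)
            assert np.allclose(rhs(state, params), 0.0)

    def test_hand_computed_example(self, library):
        # MM GEF5 (V=0.4, Km=1) at R5=1 gives 0.2; intrinsic GAP5 k=0.3;
        # dr5 = 0.2 - (0.1 + 0.2)*1 + 0.3*1 = 0.2, dR5 = 0.2 - 0.3 = -0.1
        s = ModelStructure(gef5=0, gap5=0, gef7=0, gap7=0, library=library)
        rhs = compile_rhs(s)
        params = {name: 0.0 for name in rhs.param_names}
        params.update(
            {"K1": 0.2, "k1": 0.1, "gef5_V": 0.4, "gef5_Km": 1.0, "gap5_k": 0.3,
             "K": 1.0, "td": 5.0}
        )
        d = rhs((1.0, 1.0, 1.0, 1.0), params)
        assert d[0] == pytest.approx(0.2)
        assert d[1] == pytest.approx(-0.1)

    def test_missing_parameter_is_named(self, library):
        s = ModelStructure(gef5=1, gap5=0, gef7=0, gap7=0, library=library)
        rhs = compile_rhs(s)
        params = {name: 0.5 for name in rhs.param_names if name != "gef5_Km"}
        with pytest.raises(MissingParameterError, match="gef5_Km"):
            rhs((1, 1, 1, 1), params)

    def test_exchange_cancellation_identity(self, all_structures, rng):
        """GEF/GAP terms cancel in dr + dR, leaving K - k*r for each protein."""
        for s in [all_structures[i] for i in rng.choice(126, size=15, replace=False)]:
            rhs = compile_rhs(s)
            theta = rng.uniform(rhs.bounds[:, 0], rhs.bounds[:, 1])
            f = rhs.bind(theta)
            y = rng.uniform(0, 2, size=4)
            d = f(y)
            K1, k1, K2, k2 = theta[:4]
            assert d[0] + d[1] == pytest.approx(K1 - k1 * y[0], rel=1e-12, abs=1e-12)
            assert d[2] + d[3] == pytest.approx(K2 - k2 * y[2], rel=1e-12, abs=1e-12)

    def test_every_structure_compiles_finite(self, all_structures, rng):
        for s in all_structures:
            rhs = compile_rhs(s)
            theta = rng.uniform(rhs.bounds[:, 0], rhs.bounds[:, 1])
            d = rhs.bind(theta)(rng.uniform(0.1, 1.9, size=4))
            assert np.all(np.isfinite(d))

    def test_parameter_space_has_root_params_and_no_duplicates(self, all_structures):
        for s in all_structures[::13]:
            names = s.param_names
            assert names[: len(ROOT_PARAMS)] == ROOT_PARAMS
            assert len(names) == len(set(names))
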