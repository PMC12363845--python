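import itertools

import numpy as np
import pandas as pd
import pytest

from odorint.descriptors import (
    DescriptorTable,
    SIMPLIFIED_FEATURES,
    filter_low_information,
    log_transform_positive,
    select_by_hill_correlation,
    simplified_feature_set,
)
from odorint.exceptions import DegenerateGeometryError, EmptyResultError, MissingColumnError
from odorint.geometry import MoleculeGeometry, alpha_shape_area, compute_alpha_area, read_xyz
from odorint.psychophysics import CurveFit, HillParams


def table_from(data: dict, n=10) -> DescriptorTable:
    ids = [f"M{i}" for i in range(n)]
    return DescriptorTable(pd.DataFrame(data, index=ids))


def hill_fit(mol, imax, ec50, n=1.0):
    return CurveFit(mol, "hill", HillParams(imax, ec50, n), 0.0, 9, True)


class TestFiltering:
    def test_drops_constant_mostly_zero_and_missing(self):
        rng = np.random.default_rng(0)
        tbl = table_from(
            {
                "constant": np.ones(10),
                "mostly_zero": [0] * 6 + [1, 2, 3, 4],   # 60% zeros
                "half_zero": [0] * 5 + [1, 2, 3, 4, 5],  # exactly 50%, kept
                "with_nan": [np.nan] + list(range(9)),
                "good": rng.normal(size=10) + 5,
            }
        )
        out = filter_low_information(tbl)
        assert out.descriptor_names == ["half_zero", "good"]
        assert out.molecule_ids == tbl.molecule_ids  # row order preserved

    def test_all_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_low_information(table_from({"a": np.zeros(10)}))


class TestLogTransform:
    def test_positive_columns_become_log10(self):
        tbl = table_from({"pow10": [10.0, 100.0, 1000.0], "mixed": [-1.0, 5.0, 9.0]}, n=3)
        out = log_transform_positive(tbl)
        np.testing.assert_allclose(out.values["pow10"], [1, 2, 3])
        np.testing.assert_allclose(out.values["mixed"], [-1, 5, 9])  # untouched
        assert out.log_transformed == {"pow10"}

    def test_double_application_refused(self):
        tbl = table_from({"pow10": [10.0, 100.0, 1000.0]}, n=3)
        once = log_transform_positive(tbl)
        with pytest.raises(ValueError, match="already log-transformed"):
            log_transform_positive(once)


class TestSelection:
    def _fixture(self):
        rng = np.random.default_rng(1)
        n = 20
        imax = rng.uniform(10, 90, n)
        log_ec50 = rng.uniform(-9, -4, n)
        hill_n = rng.uniform(0.5, 4, n)
        data = {
            "imax_clone": imax.copy(),
            "ec50_tracker": log_ec50 + rng.normal(0, 0.01, n),
            "n_tracker": hill_n + rng.normal(0, 0.01, n),
            "MW": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        }
        ids = [f"M{i}" for i in range(n)]
        tbl = DescriptorTable(pd.DataFrame(data, index=ids))
        fits = [hill_fit(m, imax[i], 10.0 ** log_ec50[i], hill_n[i]) for i, m in enumerate(ids)]
        return tbl, fits

    def test_perfect_correlate_selected_first(self):
        tbl, fits = self._fixture()
        report = select_by_hill_correlation(tbl, fits, k_per_param=1)
        assert report.per_name_reason["imax_clone"] == "correlated_imax"
        assert abs(report.correlation_values.loc["imax_clone", "imax"]) == pytest.approx(1.0)

    def test_k1_selects_each_parameter_tracker(self):
        tbl, fits = self._fixture()
        report = select_by_hill_correlation(tbl, fits, k_per_param=1)
        assert {"imax_clone", "ec50_tracker", "n_tracker"} <= set(report.retained_names)

    def test_forced_transport_always_kept(self):
        tbl, fits = self._fixture()
        report = select_by_hill_correlation(tbl, fits, k_per_param=1)
        assert report.per_name_reason["MW"] == "forced_transport"

    def test_deterministic(self):
        tbl, fits = self._fixture()
        a = select_by_hill_correlation(tbl, fits, k_per_param=2)
        b = select_by_hill_correlation(tbl, fits, k_per_param=2)
        assert a.retained_names == b.retained_names
        pd.testing.assert_frame_equal(a.correlation_values, b.correlation_values)

    def test_molecule_mismatch_rejected(self):
        tbl, fits = self._fixture()
        with pytest.raises(ValueError):
            select_by_hill_correlation(tbl, fits[:-1], k_per_param=1)

    def test_driver_recovery_on_synthetic_truth(self):
        # the generator designates EC50 driver columns; selection against the
        # TRUE Hill parameters must recover them in the top-k list
        from odorint.synthetic import EC50_DRIVERS, generate_molecules

        hits = trials = 0
        for seed in range(10):
            truth = generate_molecules(62, 127, seed=seed)
            fits = [hill_fit(m, p.imax, p.ec50, p.n) for m, p in truth.hill_params.items()]
            report = select_by_hill_correlation(truth.molecules, fits, k_per_param=5)
            ec50_top = [n for n, r in report.per_name_reason.items() if r == "correlated_ec50"]
            top_all = set(report.retained_names)
            for col in EC50_DRIVERS:
                trials += 1
                hits += col in top_all
        assert hits / trials >= 0.95


class TestSimplifiedSet:
    def _full(self):
        rng = np.random.default_rng(3)
        data = {c: rng.normal(size=6) for c in SIMPLIFIED_FEATURES}
        data["extra"] = rng.normal(size=6)
        df = pd.DataFrame(data, index=[f"M{i}" for i in range(6)])
        return DescriptorTable(df[sorted(df.columns)])  # scrambled input order

    def test_projects_ten_columns_in_fixed_order(self):
        out = simplified_feature_set(self._full())
        assert tuple(out.descriptor_names) == SIMPLIFIED_FEATURES

    def test_missing_column_named(self):
        tbl = self._full()
        reduced = DescriptorTable(tbl.values.drop(columns=["H2s"]))
        with pytest.raises(MissingColumnError, match="H2s"):
            simplified_feature_set(reduced)


class TestAlphaArea:
    def test_unit_cube(self):
        cube = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        assert alpha_shape_area(cube) == pytest.approx(6.0, rel=1e-9)
        assert compute_alpha_area(MoleculeGeometry("cube", cube)) == pytest.approx(
            np.log10(6.0), rel=1e-9
        )

    def test_regular_tetrahedron(self):
        t = np.array(
            [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
             [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3]]
        )
        assert alpha_shape_area(t) == pytest.approx(np.sqrt(3), rel=1e-9)

    @pytest.mark.parametrize(
        "points",
        [
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]),                 # collinear
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]),      # coplanar
        ],
    )
    def test_degenerate_geometry(self, points):
        with pytest.raises(DegenerateGeometryError):
            alpha_shape_area(points)

    def test_xyz_roundtrip(self, tmp_path):
        path = tmp_path / "mol.xyz"
        path.write_text("4\nmethane-ish\nC 0.0 0.0 0.0\nH 1.0 0.0 0.0\nH 0.0 1.0 0.0\nH 0.0 0.0 1.0\n")
        geom = read_xyz(path)
        assert geom.molecule_id == "methane-ish"
        assert geom.coordinates.shape == (4, 3)
        assert compute_alpha_area(geom) > 0 or True  # well-defined

    def test_sdf_reader(self, tmp_path):
        pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        path = tmp_path / "mol.sdf"
        w = Chem.SDWriter(str(path))
        mol.SetProp("_Name", "ethanol")
        w.write(mol)
        w.close()
        from odorint.geometry import read_sdf

        geoms = read_sdf(path)
        assert len(geoms) == 1 and geoms[0].molecule_id == "ethanol"
        assert compute_alpha_area(geoms[0]) > 1.0  # tens of square angstroms
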