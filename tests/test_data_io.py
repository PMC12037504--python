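"""Node atlas, time-series, clinical-table and ROI-extraction loaders."""

import numpy as np
import pandas as pd
import pytest

from avhnet import data_io
from avhnet.data_io import (Cohort, SubjectRecord, extract_roi_timeseries,
                            load_clinical, load_node_table, load_timeseries,
                            load_packaged_node_table, packaged_clinical_path,
                            write_matrix, load_matrix, write_node_table)
from avhnet.errors import DimensionError, FormatError, PairingError


class TestNodeTable:
    def test_packaged_atlas_has_35_ordered_rows(self, node_table):
        assert len(node_table) == 35
        assert node_table.frame["index"].tolist() == list(range(1, 36))

    def test_temporoparietal_junction_row(self, node_table):
        row = node_table.frame.iloc[25]
        assert row["abbrev"] == "TPJ.L"
        assert (row["x"], row["y"], row["z"]) == (-50, -40, 20)

    def test_duplicate_coordinates_flagged(self, node_table):
        dups = set(map(tuple, node_table.validation.duplicate_coordinates))
        assert (20, 33) in dups  # both posterior cingulate rows
        assert (8, 34) in dups   # inferior putamen / right putamen rows

    def test_duplicate_abbreviations_flagged(self, node_table):
        dups = set(map(tuple, node_table.validation.duplicate_abbreviations))
        assert (20, 33) in dups  # PCC twice
        assert any(a in dups for a in [(11, 34)])  # PUT.L twice

    def test_dedupe_collapses_exact_coordinate_duplicates(self):
        nt = load_packaged_node_table(dedupe=True)
        assert len(nt) == 33
        coords = list(map(tuple, nt.coords))
        assert len(coords) == len(set(coords))

    def test_single_row_table(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("index\tlabel\tabbrev\tx\ty\tz\n1\tSome region\tREG\t0\t1\t2\n")
        nt = load_node_table(p)
        assert nt.n == 1

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("index\tlabel\tx\ty\tz\n1\tr\t0\t1\t2\n")
        with pytest.raises(FormatError, match="abbrev"):
            load_node_table(p)

    def test_non_numeric_coordinate_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("index\tlabel\tabbrev\tx\ty\tz\n"
                     "1\tr\tA\t0\t1\t2\n2\tr2\tB\toops\t1\t2\n")
        with pytest.raises(FormatError, match="row 2"):
            load_node_table(p)

    def test_round_trip(self, node_table, tmp_path):
        p = tmp_path / "rt.tsv"
        write_node_table(node_table, p)
        again = load_node_table(p)
        pd.testing.assert_frame_equal(node_table.frame, again.frame)


class TestTimeseries:
    def test_shape_matches_node_table(self, node_table, tmp_path, rng):
        p = tmp_path / "s1_baseline.tsv"
        np.savetxt(p, rng.standard_normal((180, 35)), delimiter="\t")
        ts = load_timeseries(p, node_table)
        assert ts.shape == (180, 35)

    def test_short_series_warns_but_loads(self, node_table, tmp_path, rng):
        p = tmp_path / "short.tsv"
        np.savetxt(p, rng.standard_normal((10, 35)), delimiter="\t")
        with pytest.warns(UserWarning, match="timepoints"):
            ts = load_timeseries(p, node_table)
        assert ts.shape == (10, 35)

    def test_column_mismatch_names_expected_n(self, node_table, tmp_path, rng):
        p = tmp_path / "bad.tsv"
        np.savetxt(p, rng.standard_normal((180, 34)), delimiter="\t")
        with pytest.raises(DimensionError, match="35"):
            load_timeseries(p, node_table)

    def test_constant_column_flagged(self, node_table, tmp_path, rng):
        mat = rng.standard_normal((60, 35))
        mat[:, 3] = 2.5
        p = tmp_path / "const.tsv"
        np.savetxt(p, mat, delimiter="\t")
        with pytest.warns(UserWarning, match=r"\[3\]"):
            load_timeseries(p, node_table)

    def test_matrix_round_trip_full_precision(self, tmp_path, rng):
        m = rng.standard_normal((35, 35))
        p = tmp_path / "m.tsv"
        write_matrix(m, p)
        np.testing.assert_array_equal(load_matrix(p), m)


class TestClinical:
    def test_packaged_fixture_pairs(self):
        recs = load_clinical(packaged_clinical_path())
        assert len(recs) == 80
        base = {r.subject_id for r in recs if r.session == "baseline"}
        post = {r.subject_id for r in recs if r.session == "post"}
        assert base == post and len(base) == 40

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(",".join(data_io.CLINICAL_COLUMNS) + "\n")
        assert load_clinical(p) == []

    def test_duplicate_subject_session_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        row = "s1,SZ,baseline,25,male,0.2,20,20,20,40,80"
        p.write_text(",".join(data_io.CLINICAL_COLUMNS) + f"\n{row}\n{row}\n")
        with pytest.raises(FormatError, match="duplicate"):
            load_clinical(p)

    def test_post_without_baseline_is_pairing_error(self, tmp_path):
        p = tmp_path / "orphan.csv"
        p.write_text(",".join(data_io.CLINICAL_COLUMNS)
                     + "\ns1,SZ,post,25,male,0.2,10,18,20,40,80\n")
        with pytest.raises(PairingError, match="s1"):
            load_clinical(p)

    def test_hc_post_session_rejected(self):
        with pytest.raises(FormatError, match="baseline"):
            SubjectRecord(subject_id="h1", group="HC", session="post",
                          age=25, sex="female", fd=0.2)

    def test_cohort_dimension_check(self, node_table, rng):
        rec = SubjectRecord(subject_id="s1", group="SZ", session="baseline",
                            age=25, sex="male", fd=0.2,
                            timeseries=rng.standard_normal((50, 34)))
        with pytest.raises(DimensionError):
            Cohort(node_table=node_table, records=[rec])


class TestRoiExtraction:
    def _write_volume(self, tmp_path, data, affine):
        import nibabel as nib

        img = nib.Nifti1Image(data, affine)
        p = tmp_path / "vol.nii.gz"
        nib.save(img, p)
        return p

    def _small_table(self, tmp_path, coords):
        rows = "\n".join(f"{i+1}\tregion{i}\tR{i}\t{x}\t{y}\t{z}"
                         for i, (x, y, z) in enumerate(coords))
        p = tmp_path / "nodes.tsv"
        p.write_text("index\tlabel\tabbrev\tx\ty\tz\n" + rows + "\n")
        return load_node_table(p)

    def test_constant_field_gives_constant_columns(self, tmp_path):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        data = np.full((10, 10, 10, 4), 5.0)
        vol = self._write_volume(tmp_path, data, affine)
        nt = self._small_table(tmp_path, [(15, 15, 15), (6, 6, 6)])
        ts, counts = extract_roi_timeseries(vol, nt, radius=6.0)
        assert ts.shape == (4, 2)
        np.testing.assert_allclose(ts, 5.0)
        assert (counts > 0).all()

    def test_matches_brute_force_voxel_scan(self, tmp_path, rng):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-12, -12, -12]
        data = rng.random((9, 9, 9, 3))
        vol = self._write_volume(tmp_path, data, affine)
        center = (0.0, 0.0, 0.0)
        nt = self._small_table(tmp_path, [center])
        radius = 6.0
        ts, counts = extract_roi_timeseries(vol, nt, radius=radius)
        # independent oracle: explicit loop over all voxels
        acc, k = np.zeros(3), 0
        for i in range(9):
            for j in range(9):
                for l in range(9):
                    mm = affine @ np.array([i, j, l, 1.0])
                    if np.sum((mm[:3] - center) ** 2) <= radius ** 2:
                        acc += data[i, j, l]
                        k += 1
        assert counts[0] == k > 0
        np.testing.assert_allclose(ts[:, 0], acc / k, rtol=1e-12)

    def test_degenerate_radius_warns_and_zeroes(self, tmp_path, rng):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        data = rng.random((5, 5, 5, 2))
        vol = self._write_volume(tmp_path, data, affine)
        nt = self._small_table(tmp_path, [(1.5, 1.5, 1.5)])  # between voxels
        with pytest.warns(UserWarning, match="no voxel"):
            ts, counts = extract_roi_timeseries(vol, nt, radius=0.1)
        assert counts[0] == 0
        np.testing.assert_array_equal(ts[:, 0], 0.0)
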