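"""Data-model validation, CSV round-trips, pooling and temporal binning."""

from __future__ import annotations

import pytest

from drillcore import (
    AlignmentError,
    CoreDataset,
    Group,
    PairingError,
    SchemaError,
    TaxonIncrementCount,
    TemporalUnit,
    ValidationError,
    assign_temporal_units,
    pool_replicate_cores,
    pool_surface_increments,
    read_core_table,
    write_core_table,
)
from drillcore.core_model import total_specimen_count

from conftest import bivalve_row, gastropod_row, make_increment


class TestRecordInvariants:
    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            bivalve_row("i0", n_left=-1)

    def test_bivalve_whole_shell_rejected(self):
        with pytest.raises(ValidationError, match="n_whole"):
            bivalve_row("i0", n_whole=3)

    def test_univalved_valve_counts_rejected(self):
        with pytest.raises(ValidationError):
            gastropod_row("i0", n_left=2)

    def test_drilled_exceeding_valves_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            bivalve_row("i0", n_left=1, n_right=1, n_drilled=3)

    def test_drilled_exceeding_whole_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            gastropod_row("i0", n_whole=2, n_drilled=3)

    def test_unknown_increment_reference_rejected(self):
        with pytest.raises(ValidationError, match="unknown increment"):
            CoreDataset(
                increments=[make_increment("i0", 0, 2)],
                counts=[gastropod_row("nope", n_whole=5)],
            )

    def test_overlapping_increments_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            CoreDataset(
                increments=[
                    make_increment("i0", 0, 5),
                    make_increment("i1", 3, 8),
                ],
                counts=[],
            )

    def test_age_increasing_upward_rejected(self):
        with pytest.raises(ValidationError, match="age"):
            CoreDataset(
                increments=[
                    make_increment("i0", 0, 2, age=1900.0),
                    make_increment("i1", 2, 4, age=1950.0),
                ],
                counts=[],
            )


class TestCsvIO:
    def test_round_trip_is_identity(self, two_increment_dataset, tmp_path):
        """Writer output read back and rewritten is byte-identical."""
        c1, i1 = tmp_path / "c1.csv", tmp_path / "i1.csv"
        c2, i2 = tmp_path / "c2.csv", tmp_path / "i2.csv"
        write_core_table(two_increment_dataset, c1, i1)
        again = read_core_table(c1, i1)
        write_core_table(again, c2, i2)
        assert c1.read_bytes() == c2.read_bytes()
        assert i1.read_bytes() == i2.read_bytes()
        assert len(again.counts) == len(two_increment_dataset.counts)

    def test_three_row_fixture_reads(self, two_increment_dataset, tmp_path):
        write_core_table(two_increment_dataset, tmp_path / "c.csv", tmp_path / "i.csv")
        ds = read_core_table(tmp_path / "c.csv", tmp_path / "i.csv")
        assert len(ds.counts) == 3
        assert len(ds.increments) == 2

    def test_missing_column_names_it(self, two_increment_dataset, tmp_path):
        write_core_table(two_increment_dataset, tmp_path / "c.csv", tmp_path / "i.csv")
        text = (tmp_path / "c.csv").read_text().replace("n_left", "nleft")
        (tmp_path / "c.csv").write_text(text)
        with pytest.raises(SchemaError, match="n_left"):
            read_core_table(tmp_path / "c.csv", tmp_path / "i.csv")

    def test_negative_count_in_csv_rejected(self, two_increment_dataset, tmp_path):
        write_core_table(two_increment_dataset, tmp_path / "c.csv", tmp_path / "i.csv")
        text = (tmp_path / "c.csv").read_text().replace(",30,6", ",-1,6")
        (tmp_path / "c.csv").write_text(text)
        with pytest.raises(ValidationError):
            read_core_table(tmp_path / "c.csv", tmp_path / "i.csv")

    def test_unknown_increment_in_csv_rejected(self, two_increment_dataset, tmp_path):
        write_core_table(two_increment_dataset, tmp_path / "c.csv", tmp_path / "i.csv")
        text = (tmp_path / "c.csv").read_text().replace("c1,i0", "c1,ghost", 1)
        (tmp_path / "c.csv").write_text(text)
        with pytest.raises(ValidationError, match="unknown increment"):
            read_core_table(tmp_path / "c.csv", tmp_path / "i.csv")

    def test_bp_ages_converted_to_ce(self, tmp_path):
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2, age=1950.0 - 3000.0)],
            counts=[],
        )
        write_core_table(ds, tmp_path / "c.csv", tmp_path / "i.csv")
        text = (tmp_path / "i.csv").read_text().replace("-1050.0,CE", "3000,BP")
        (tmp_path / "i.csv").write_text(text)
        again = read_core_table(tmp_path / "c.csv", tmp_path / "i.csv")
        assert again.increments[0].age_estimate == pytest.approx(-1050.0)


class TestReplicatePooling:
    def _single(self, value, core_id):
        return CoreDataset(
            increments=[make_increment("i0", 0, 2, core_id=core_id)],
            counts=[gastropod_row("i0", n_whole=value, core_id=core_id)],
        )

    def test_counts_sum(self):
        pooled = pool_replicate_cores([self._single(5, "a"), self._single(7, "b")])
        assert pooled.counts[0].n_whole == 12

    def test_self_pooling_doubles(self, two_increment_dataset):
        pooled = pool_replicate_cores([two_increment_dataset, two_increment_dataset])
        assert total_specimen_count(pooled) == 2 * total_specimen_count(
            two_increment_dataset
        )

    def test_missing_taxon_treated_as_zero(self):
        a = self._single(5, "a")
        b = CoreDataset(
            increments=[make_increment("i0", 0, 2, core_id="b")],
            counts=[gastropod_row("i0", taxon="Bittium reticulatum", n_whole=3, core_id="b")],
        )
        pooled = pool_replicate_cores([a, b])
        by_taxon = {row.taxon: row.n_whole for row in pooled.counts}
        assert by_taxon["Tritia varicosa"] == 5
        assert by_taxon["Bittium reticulatum"] == 3

    def test_commutative(self):
        a, b = self._single(5, "a"), self._single(7, "b")
        ab = pool_replicate_cores([a, b], pooled_core_id="p")
        ba = pool_replicate_cores([b, a], pooled_core_id="p")
        assert [r.n_whole for r in ab.counts] == [r.n_whole for r in ba.counts]

    def test_mismatched_grid_rejected(self):
        a = self._single(5, "a")
        b = CoreDataset(
            increments=[make_increment("i0", 0, 5, core_id="b")],
            counts=[gastropod_row("i0", n_whole=5, core_id="b")],
        )
        with pytest.raises(AlignmentError):
            pool_replicate_cores([a, b])


class TestSurfacePooling:
    def _ten_thin(self):
        increments = [make_increment(f"i{k}", 2.0 * k, 2.0 * (k + 1)) for k in range(10)]
        counts = [gastropod_row(f"i{k}", n_whole=k + 1) for k in range(10)]
        return CoreDataset(increments=increments, counts=counts)

    def test_ten_2cm_become_five_4cm(self):
        pooled = pool_surface_increments(self._ten_thin())
        assert len(pooled.increments) == 5
        assert all(inc.thickness_cm == pytest.approx(4.0) for inc in pooled.increments)

    def test_counts_sum_within_pairs(self):
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2), make_increment("i1", 2, 4)],
            counts=[gastropod_row("i0", n_whole=3), gastropod_row("i1", n_whole=4)],
        )
        pooled = pool_surface_increments(ds)
        assert pooled.counts[0].n_whole == 7

    def test_nothing_above_boundary_is_identity(self):
        ds = CoreDataset(
            increments=[make_increment("i0", 25, 30)],
            counts=[gastropod_row("i0", n_whole=9)],
        )
        pooled = pool_surface_increments(ds)
        assert [inc.increment_id for inc in pooled.increments] == ["i0"]
        assert pooled.counts[0].n_whole == 9

    def test_odd_count_needs_flag(self):
        ds = CoreDataset(
            increments=[make_increment(f"i{k}", 2.0 * k, 2.0 * (k + 1)) for k in range(3)],
            counts=[],
        )
        with pytest.raises(PairingError):
            pool_surface_increments(ds)
        pooled = pool_surface_increments(ds, allow_unpaired=True)
        assert len(pooled.increments) == 2

    def test_specimens_conserved(self):
        ds = self._ten_thin()
        assert total_specimen_count(pool_surface_increments(ds)) == total_specimen_count(ds)


class TestTemporalUnits:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (1700.0, TemporalUnit.C17_EARLY_C19),
            (2000.0, TemporalUnit.LATE_C20_C21),
            (1950.0 - 3000.0, TemporalUnit.HOLOCENE),  # 3000 yr BP
            (1900.0, TemporalUnit.LATE_C19_EARLY_C20),
        ],
    )
    def test_default_boundaries(self, age, expected):
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2, age=age)], counts=[]
        )
        out = assign_temporal_units(ds)
        assert out.increments[0].temporal_unit is expected

    def test_missing_age_lists_increments(self):
        ds = CoreDataset(increments=[make_increment("iX", 0, 2)], counts=[])
        with pytest.raises(ValidationError, match="iX"):
            assign_temporal_units(ds)

    def test_custom_boundaries(self):
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2, age=1700.0)], counts=[]
        )
        out = assign_temporal_units(ds, boundaries=(1500, 1650, 1800))
        assert out.increments[0].temporal_unit is TemporalUnit.LATE_C19_EARLY_C20
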