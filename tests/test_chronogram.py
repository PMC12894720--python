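import math

import pytest
from hypothesis import given, settings, strategies as st

from fertkin import (
    Chronogram,
    ChronogramError,
    Fate,
    OocyteRecord,
    SpermCategory,
    SpermRecord,
    TimeWindow,
    classify_sperm,
    read_chronogram,
    summarize,
    write_chronogram,
)


class TestTimeWindow:
    def test_invariants(self):
        with pytest.raises(ChronogramError):
            TimeWindow(30, 20)
        with pytest.raises(ChronogramError):
            TimeWindow(-1, 5)
        assert TimeWindow(30, 30).width == 0  # degenerate = directly observed

    def test_intersect(self):
        assert TimeWindow(0, 10).intersect(TimeWindow(5, 20)) == TimeWindow(5, 10)
        assert TimeWindow(0, 10).intersect(TimeWindow(11, 20)) is None
        assert TimeWindow(0, 10).intersect(TimeWindow(10, 20)) == TimeWindow(10, 10)


class TestRecords:
    def test_fusion_cannot_certainly_precede_penetration(self):
        with pytest.raises(ChronogramError):
            SpermRecord("s", "o", TimeWindow(50, 60), TimeWindow(10, 40))

    def test_fate_derivation(self, toy_chronogram):
        fates = [o.fate for o in toy_chronogram.oocytes]
        assert fates == [Fate.FERTILIZED, Fate.PENETRATED_UNFERTILIZED, Fate.UNPENETRATED]

    def test_duplicate_ids_rejected(self):
        s = SpermRecord("sp1", "oo1", TimeWindow(0, 5))
        with pytest.raises(ChronogramError):
            OocyteRecord("oo1", [s, s])
        o = OocyteRecord("oo1", [])
        with pytest.raises(ChronogramError):
            Chronogram([o, OocyteRecord("oo1", [])])


class TestIO:
    def test_round_trip(self, toy_chronogram, tmp_path):
        path = tmp_path / "c.csv"
        write_chronogram(toy_chronogram, path)
        back = read_chronogram(path)
        assert back.condition_label == "toy"
        assert [o.oocyte_id for o in back.oocytes] == ["oo1", "oo2", "oo3"]
        for a, b in zip(toy_chronogram.oocytes, back.oocytes):
            assert a.fate == b.fate and a.horizon == b.horizon
            assert [(s.sperm_id, s.penetration, s.fusion) for s in a.sperm] == [
                (s.sperm_id, s.penetration, s.fusion) for s in b.sperm
            ]

    def test_empty_chronogram_round_trip(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_chronogram(Chronogram([]), path)
        assert read_chronogram(path).n_oocytes == 0

    def test_write_is_deterministic(self, toy_chronogram, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_chronogram(toy_chronogram, p1)
        write_chronogram(toy_chronogram, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_reversed_bounds_name_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "oocyte_id,sperm_id,pen_lower_min,pen_upper_min,fus_lower_min,"
            "fus_upper_min,horizon_min,condition\n"
            "oo1,sp1,30,20,,,240,x\n"
        )
        with pytest.raises(ChronogramError, match="row 0"):
            read_chronogram(path)

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("oocyte_id,sperm_id\noo1,sp1\n")
        with pytest.raises(ChronogramError, match="missing columns"):
            read_chronogram(path)


class TestClassify:
    @pytest.mark.parametrize(
        "pen, expected",
        [
            ((0, 5), SpermCategory.PRE_FERTILIZATION),     # certainly before pen [10,20]
            ((40, 50), SpermCategory.POST_FERTILIZATION),  # certainly after fusion [30,32]
            ((15, 31), SpermCategory.AMBIGUOUS),           # overlaps both references
            ((5, 10), SpermCategory.PRE_FERTILIZATION),    # boundary equality is certain
            ((32, 40), SpermCategory.POST_FERTILIZATION),
        ],
    )
    def test_category_rules(self, pen, expected):
        o = OocyteRecord(
            "oo1",
            [
                SpermRecord("sp1", "oo1", TimeWindow(10, 20), TimeWindow(30, 32)),
                SpermRecord("sp2", "oo1", TimeWindow(*pen)),
            ],
        )
        cats = classify_sperm(o)
        assert cats["sp1"] is SpermCategory.FERTILIZING
        assert cats["sp2"] is expected

    def test_requires_fertilized(self):
        o = OocyteRecord("oo1", [SpermRecord("sp1", "oo1", TimeWindow(0, 5))])
        with pytest.raises(ChronogramError):
            classify_sperm(o)

    @settings(max_examples=50, derandomize=True)
    @given(
        pens=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)).map(
                lambda ab: (min(ab), max(ab))
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_partitions_and_relabeling_invariance(self, pens):
        """Every sperm of a fertilized oocyte gets exactly one category, and
        categories do not depend on sperm labels."""
        sperm = [SpermRecord("a0", "oo", TimeWindow(10, 20), TimeWindow(30, 32))]
        sperm += [
            SpermRecord(f"a{i+1}", "oo", TimeWindow(*p)) for i, p in enumerate(pens)
        ]
        cats = classify_sperm(OocyteRecord("oo", sperm))
        assert set(cats) == {s.sperm_id for s in sperm}
        relabeled = [
            SpermRecord("z" + s.sperm_id, "oo", s.penetration, s.fusion) for s in sperm
        ]
        cats2 = classify_sperm(OocyteRecord("oo", relabeled))
        assert all(cats2["z" + k] == v for k, v in cats.items())


class TestSummarize:
    def test_toy_counts(self, toy_chronogram):
        rec = summarize(toy_chronogram)
        assert rec["fate_counts"] == {
            "fertilized": 1,
            "penetrated_unfertilized": 1,
            "unpenetrated": 1,
        }
        assert rec["penetrations_per_oocyte"] == {0: 1, 1: 1, 2: 1}
        # sp2 pen [0,5] certainly precedes sp1 pen [10,20] and fusion [30,32]
        assert rec["first_penetrant_counts"] == {"fertilized": 0, "failed": 1, "ambiguous": 0}
        # sp2 (failed) and the fertilizing sp1 both certainly penetrated
        # before the first fusion; only sp1 fused
        assert rec["pre_fertilization_penetrants"] == 2
        assert rec["pre_fertilization_fused_fraction"] == 0.5
        assert rec["dispermic_oocytes"] == 0

    def test_single_fused_sperm_first_penetrant_fraction(self):
        c = Chronogram(
            [
                OocyteRecord(
                    "oo1",
                    [SpermRecord("sp1", "oo1", TimeWindow(10, 20), TimeWindow(30, 32))],
                )
            ]
        )
        rec = summarize(c)
        assert rec["first_penetrant_fractions"]["fertilized"] == 1.0

    def test_first_penetrant_fractions_sum_to_one(self, toy_chronogram):
        rec = summarize(toy_chronogram)
        total = sum(rec["first_penetrant_fractions"].values())
        assert math.isclose(total, 1.0)

    def test_dispermic_count(self):
        c = Chronogram(
            [
                OocyteRecord(
                    "oo1",
                    [
                        SpermRecord("sp1", "oo1", TimeWindow(10, 20), TimeWindow(30, 32)),
                        SpermRecord("sp2", "oo1", TimeWindow(15, 25), TimeWindow(33, 40)),
                    ],
                )
            ]
        )
        assert summarize(c)["dispermic_oocytes"] == 1
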