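import pytest

from fertkin import Chronogram, OocyteRecord, SpermRecord, TimeWindow


@pytest.fixture
def fertilized_oocyte() -> OocyteRecord:
    """One fertilized oocyte: fertilizing sperm pen [10,20] fusion [30,32],
    plus one non-fused sperm pen [50,70]."""
    return OocyteRecord(
        "oo1",
        [
            SpermRecord("sp1", "oo1", TimeWindow(10, 20), TimeWindow(30, 32)),
            SpermRecord("sp2", "oo1", TimeWindow(50, 70)),
        ],
    )


@pytest.fixture
def toy_chronogram() -> Chronogram:
    """Three oocytes: fertilized (2 sperm), penetrated-unfertilized, unpenetrated."""
    return Chronogram(
        [
            OocyteRecord(
                "oo1",
                [
                    SpermRecord("sp1", "oo1", TimeWindow(10, 20), TimeWindow(30, 32)),
                    SpermRecord("sp2", "oo1", TimeWindow(0, 5)),
                ],
            ),
            OocyteRecord("oo2", [SpermRecord("sp1", "oo2", TimeWindow(40, 90))]),
            OocyteRecord("oo3", []),
        ],
        condition_label="toy",
    )
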