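import numpy as np
import pytest

from pparscreen.plate import Role, ScreeningPlate, WellAddress, WellRecord


def build_plate(
    neg_ratios,
    pos_ratios,
    sample_ratios=None,
    renilla=10000.0,
    sample_renilla=None,
    plate_id="T01",
):
    """Construct a 96-well plate from control/sample ratio lists.

    Controls go in columns 1 (negative) and 12 (positive); samples fill
    columns 2.. row-major.  ``sample_ratios`` maps sample_id -> ratio;
    ``sample_renilla`` optionally overrides Renilla per sample_id.
    """
    plate = ScreeningPlate(plate_id, 96)
    for i, r in enumerate(neg_ratios):
        plate.add(
            WellRecord(
                address=WellAddress("ABCDEFGH"[i], 1),
                role=Role.negative_control,
                firefly=r * renilla,
                renilla=renilla,
            )
        )
    for i, r in enumerate(pos_ratios):
        plate.add(
            WellRecord(
                address=WellAddress("ABCDEFGH"[i], 12),
                role=Role.positive_control,
                firefly=r * renilla,
                renilla=renilla,
            )
        )
    if sample_ratios:
        from pparscreen.plate import sample_positions

        positions = sample_positions(96)
        for j, (sid, r) in enumerate(sample_ratios.items()):
            ren = (sample_renilla or {}).get(sid, renilla)
            plate.add(
                WellRecord(
                    address=WellAddress.parse(positions[j]),
                    role=Role.sample,
                    sample_id=sid,
                    firefly=r * ren,
                    renilla=ren,
                )
            )
    return plate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
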