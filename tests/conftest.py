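import numpy as np
import pandas as pd
import pytest

from raredex.gpr_io import SlideAssay


def make_slide(
    slide_id="s1",
    orientation="forward",
    f635=(2000, 3000, 4000),
    b635=None,
    f532=None,
    b532=None,
    genes=None,
    flags=None,
):
    n = len(f635)
    if b635 is None:
        b635 = (100,) * n
    if f532 is None:
        f532 = (1000,) * n
    if b532 is None:
        b532 = (100,) * n
    return SlideAssay(
        slide_id=slide_id,
        orientation=orientation,
        spots=pd.DataFrame(
            {
                "spot_id": [f"s{i}" for i in range(1, n + 1)],
                "gene_id": list(genes) if genes is not None else [f"g{i}" for i in range(1, n + 1)],
                "f635_median": list(f635),
                "b635_median": list(b635),
                "f532_median": list(f532),
                "b532_median": list(b532),
                "flag": list(flags) if flags is not None else [0] * n,
                "qc_status": "retained",
            }
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def slide3():
    return make_slide()
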