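import numpy as np
import pandas as pd
import pytest

from stopnet.race import TRIAL_COLUMNS, TrialLog


def make_log(go_rts, stop_ssds, stop_responded, stop_rts=None, go_responded=None):
    """Build a hand-specified trial log (test trials only)."""
    rows = []
    go_responded = go_responded if go_responded is not None else [True] * len(go_rts)
    for rt, responded in zip(go_rts, go_responded):
        rows.append(
            dict(
                block=0,
                trial_type="go",
                ssd_ms=np.nan,
                responded=responded,
                rt_ms=rt if responded else np.nan,
                correct=responded,
                is_practice=False,
                go_finish_ms=rt,
                stop_finish_ms=np.nan,
            )
        )
    stop_rts = stop_rts if stop_rts is not None else [np.nan] * len(stop_ssds)
    for ssd, responded, rt in zip(stop_ssds, stop_responded, stop_rts):
        rows.append(
            dict(
                block=0,
                trial_type="stop",
                ssd_ms=ssd,
                responded=responded,
                rt_ms=rt if responded else np.nan,
                correct=False,
                is_practice=False,
                go_finish_ms=np.nan,
                stop_finish_ms=np.nan,
            )
        )
    return TrialLog(trials=pd.DataFrame(rows, columns=TRIAL_COLUMNS))


@pytest.fixture
def ten_rt_log():
    """10 go trials (RTs 400..490), 4 stop trials, 2 responded, mean SSD 200."""
    return make_log(
        go_rts=list(range(400, 500, 10)),
        stop_ssds=[200.0] * 4,
        stop_responded=[True, True, False, False],
        stop_rts=[380.0, 390.0, np.nan, np.nan],
    )
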