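import numpy as np
import pytest

from fogbench.core_io import LabelSeries, ScoreSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_labels(turn=None, walking=None, start_hesitation=None, notype=None,
                valid=None, task=None, n=None):
    """Build a LabelSeries from any subset of channels (rest all-false)."""
    channels = dict(turn=turn, walking=walking, start_hesitation=start_hesitation,
                    notype=notype)
    lengths = [len(v) for v in channels.values() if v is not None]
    if n is None:
        n = lengths[0] if lengths else (len(valid) if valid is not None else 4)
    out = {}
    for name, v in channels.items():
        out[name] = np.asarray(v, bool) if v is not None else np.zeros(n, bool)
    out["valid"] = np.asarray(valid, bool) if valid is not None else np.ones(n, bool)
    out["task"] = np.asarray(task, bool) if task is not None else np.ones(n, bool)
    return LabelSeries(**out)


def make_scores(values, n=None):
    """ScoreSeries with the same values on all three class channels."""
    v = np.asarray(values, float)
    return ScoreSeries(start_hesitation=v.copy(), turn=v.copy(), walking=v.copy())


@pytest.fixture
def tdcsfog_csv(tmp_path):
    """4-row lab-dialect fixture with all-zero labels."""
    path = tmp_path / "s1_t1.csv"
    path.write_text(
        "Time,AccV,AccML,AccAP,StartHesitation,Turn,Walking\n"
        "0,9.8,0.1,0.2,0,0,0\n"
        "1,9.7,0.0,0.1,0,0,0\n"
        "2,9.9,0.2,0.3,0,0,0\n"
        "3,9.8,0.1,0.2,0,0,0\n")
    return path


@pytest.fixture
def defog_csv(tmp_path):
    """3-row home-dialect fixture with Valid=[1,1,0], Task=[1,0,1]."""
    path = tmp_path / "s2_t1.csv"
    path.write_text(
        "Time,AccV,AccML,AccAP,StartHesitation,Turn,Walking,Valid,Task\n"
        "0,1.0,0.0,0.0,0,1,0,1,1\n"
        "1,1.0,0.0,0.0,0,1,0,1,0\n"
        "2,1.0,0.0,0.0,0,0,0,0,1\n")
    return path
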