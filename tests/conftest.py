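import numpy as np
import pytest

from eventseg import graph_sequences as gs
from eventseg import preprocessing as pp
from eventseg import synthetic as syn


@pytest.fixture(scope="session")
def graph():
    return gs.build_graph()


@pytest.fixture(scope="session")
def parsing_trials(graph):
    return gs.build_parsing_sequence(graph, seed=7)


@pytest.fixture(scope="session")
def small_session(graph):
    """150-trial parsing-phase recording with default planted effects."""
    trials = gs.build_parsing_sequence(graph, n_trials=150, seed=3)
    spec = syn.GenerativeSpec()
    return syn.simulate_session(trials, spec, seed=9, graph=graph)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    sess = small_session
    ep = pp.epoch_and_baseline(
        sess.data, sess.sfreq, sess.onsets, sess.ch_names, metadata=sess.trials
    )
    pp.reject_artifacts(ep)
    return ep


def make_epochs(data, sfreq=250.0, ch_names=None, tmin=-0.1):
    """Wrap a (n_ep, n_ch, n_t) array as an EpochArray without baselining."""
    import pandas as pd

    n_ep, n_ch, n_t = data.shape
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(n_ch)]
    times = np.arange(n_t) / sfreq + tmin
    return pp.EpochArray(
        data=np.asarray(data, float),
        times=times,
        sfreq=sfreq,
        ch_names=list(ch_names),
        metadata=pd.DataFrame({"epoch": np.arange(n_ep)}),
    )
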