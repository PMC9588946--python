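"""Exhaustive all-pairs STDP oracle shared by the plasticity tests."""

import numpy as np


def all_pairs_totals(times, ids, synapses, kernels):
    """Sum the pair rule over every pre/post spike pair of every edge.

    Coincident spikes pair on the potentiation branch (dt = 0)."""
    delta = np.zeros(synapses.n_edges)
    times = np.asarray(times)
    ids = np.asarray(ids)
    NE = synapses.N_exc
    for e in range(synapses.n_edges):
        j, i = synapses.pre[e], synapses.post[e]
        ker = kernels["E" if j < NE else "I"]
        tp = times[ids == j]
        ti = times[ids == i]
        if tp.size == 0 or ti.size == 0:
            continue
        dt = ti[None, :] - tp[:, None]  # t_post - t_pre
        pot = np.exp(-dt[dt >= 0] / ker.tau_plus).sum() * ker.A_plus
        dep = np.exp(dt[dt < 0] / ker.tau_minus).sum() * ker.A_minus
        delta[e] = pot - dep
    return delta
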